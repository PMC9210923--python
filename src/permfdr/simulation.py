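"""Coverage validation study on block-correlated Gaussian data.

The study design: n observations of 100 Gaussian predictors organised in L =
20 independent blocks of 5 with exchangeable within-block correlation rho
(compound-symmetric covariance sigma^2[(1-rho)I + rho J]), and one outcome per
block, Y_l = X_l beta_l + eps, eps ~ N(0, sigma^2).  Every predictor-outcome
pair is tested marginally (simple-linear-regression slope t-test, equivalently
the Pearson correlation test on n-2 df), giving m = 100 x 20 = 2000 tests.
Null pairs are every cross-block pair and every pair in a block with beta = 0;
in a non-null block all five predictors are marginally associated with the
block's outcome (directly through their own beta or through rho).

Permutation replicates re-analyse the same data after one shared row
permutation of the outcome matrix, preserving all dependence within the
predictor set and within the outcome set while breaking the association
between them.

Five scenarios: A (5 non-null blocks, beta = 0.05), B (10, 0.05), C (5,
0.075), D (10, 0.075) and E (the global null, all beta = 0).  Coverage of the
selected FDR intervals is judged against the true pFDR curve E[F/S | S > 0],
estimated per scenario by an independent Monte-Carlo oracle; under the global
null the truth is exactly 1 at every threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import EstimationConfig, ThresholdGrid, fdr_table_from_counts
from .selection import SelectionResult, apply_all_selections

__all__ = [
    "ScenarioSpec",
    "scenario",
    "SCENARIO_BETAS",
    "simulate_dataset",
    "marginal_pvalues",
    "permute_outcomes",
    "true_fdr_curve",
    "run_replicate",
    "ReplicateResult",
    "run_coverage_experiment",
    "CoverageSummary",
    "conditional_coverage",
]

METHODS = ("UCB", "M.2", "BY")

#: per-scenario (number of non-null blocks, within-block coefficient)
SCENARIO_BETAS: dict[str, tuple[int, float]] = {
    "A": (5, 0.05),
    "B": (10, 0.05),
    "C": (5, 0.075),
    "D": (10, 0.075),
    "E": (0, 0.0),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulation scenario.

    Defaults are the validation-study conditions: n = 200 samples, 20 blocks
    of 5 predictors correlated at rho = 0.3, unit scales, 20 permutations,
    2000 replicates, threshold grid -log10(p) = 2.0 ... 6.0 in steps of 0.1.
    """

    name: str = "E"
    n: int = 200
    block_size: int = 5
    n_blocks: int = 20
    rho: float = 0.3
    sigma: float = 1.0
    n_nonnull_blocks: int = 0
    beta: float = 0.0
    n_perm: int = 20
    n_rep: int = 2000
    alpha: float = 0.05
    cl: float = 0.95
    m2_cut: float = 0.2
    grid: ThresholdGrid = field(default_factory=ThresholdGrid.from_neg_log10)

    def __post_init__(self) -> None:
        if not -1.0 / (self.block_size - 1) < self.rho < 1.0:
            raise ValueError("rho outside the positive-definite range for this block size")
        if not 0 <= self.n_nonnull_blocks <= self.n_blocks:
            raise ValueError("n_nonnull_blocks must lie in [0, n_blocks]")

    @property
    def n_predictors(self) -> int:
        return self.n_blocks * self.block_size

    @property
    def m(self) -> int:
        return self.n_predictors * self.n_blocks

    @property
    def is_global_null(self) -> bool:
        return self.n_nonnull_blocks == 0 or self.beta == 0.0

    def null_pair_mask(self) -> np.ndarray:
        """Boolean mask over the m tests (outcome-major order): True = null pair.

        Non-null pairs are the block_size predictors of each of the first
        n_nonnull_blocks blocks, tested against their own block's outcome.
        """
        mask = np.ones((self.n_blocks, self.n_predictors), dtype=bool)
        if not self.is_global_null:
            for l in range(self.n_nonnull_blocks):
                mask[l, l * self.block_size : (l + 1) * self.block_size] = False
        return mask.ravel()

    def block_chol(self) -> np.ndarray:
        cov = self.sigma**2 * (
            (1.0 - self.rho) * np.eye(self.block_size) + self.rho * np.ones((self.block_size,) * 2)
        )
        return np.linalg.cholesky(cov)


def scenario(name: str, **overrides) -> ScenarioSpec:
    """Named study scenario A-E, with optional field overrides."""
    key = name.upper()
    if key not in SCENARIO_BETAS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {sorted(SCENARIO_BETAS)}")
    n_nonnull, beta = SCENARIO_BETAS[key]
    fields = {"name": key, "n_nonnull_blocks": n_nonnull, "beta": beta}
    fields.update(overrides)
    return ScenarioSpec(**fields)


def simulate_dataset(spec: ScenarioSpec, rng: np.random.Generator):
    """Draw one replicate: predictors X (n x 100) and outcomes Y (n x 20)."""
    L = spec.block_chol()
    z = rng.standard_normal((spec.n, spec.n_blocks, spec.block_size))
    xb = z @ L.T  # (n, n_blocks, block_size); blocks mutually independent
    X = xb.reshape(spec.n, spec.n_predictors)
    eps = rng.standard_normal((spec.n, spec.n_blocks)) * spec.sigma
    beta_vec = np.zeros((spec.n_blocks, spec.block_size))
    if not spec.is_global_null:
        beta_vec[: spec.n_nonnull_blocks, :] = spec.beta
    signal = np.einsum("nlb,lb->nl", xb, beta_vec)
    Y = signal + eps
    return X, Y


def _abs_corr(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """|Pearson r| for every predictor-outcome pair, outcome-major, shape (m,)."""
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    xn = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    yn = np.sqrt(np.einsum("ij,ij->j", yc, yc))
    if np.any(xn == 0.0) or np.any(yn == 0.0):
        raise ValueError("constant column: correlation undefined")
    r = (xc.T @ yc) / np.outer(xn, yn)  # (n_predictors, n_outcomes)
    return np.abs(r).T.ravel()


def marginal_pvalues(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Two-sided slope-test p-values for all predictor-outcome pairs.

    Equivalent to the Pearson correlation t-test with n-2 df; returned
    outcome-major (all predictors for outcome 1, then outcome 2, ...).
    """
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n = X.shape[0]
    absr = _abs_corr(X, Y)
    absr = np.minimum(absr, 1.0)
    with np.errstate(divide="ignore"):
        tstat = absr * np.sqrt((n - 2) / (1.0 - absr**2))
    return 2.0 * stats.t.sf(tstat, df=n - 2)


def permute_outcomes(Y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One shared row permutation of the whole outcome matrix.

    All outcome columns move together, so dependence among outcomes (and
    among predictors, untouched) is preserved; only the predictor-outcome
    pairing is broken.
    """
    return Y[rng.permutation(Y.shape[0]), :]


def _critical_abs_r(grid: ThresholdGrid, n: int) -> np.ndarray:
    """|r| cutoffs equivalent to the grid's p-value cutoffs (p < t iff |r| > r_crit)."""
    tcrit = stats.t.isf(grid.thresholds / 2.0, df=n - 2)
    return tcrit / np.sqrt(n - 2 + tcrit**2)


def _counts_above(sorted_vals: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    return sorted_vals.size - np.searchsorted(sorted_vals, cutoffs, side="right")


def true_fdr_curve(
    spec: ScenarioSpec,
    n_mc: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Monte-Carlo oracle for the true pFDR, E[F/S | S > 0], per grid threshold.

    F is the count of rejected null pairs, known from the design.  Thresholds
    at which S = 0 in every Monte-Carlo draw come back NaN (unavailable).
    Under the global null every rejection is false, so the curve is exactly 1.
    """
    grid = spec.grid
    if spec.is_global_null:
        return np.ones(len(grid))
    rng = np.random.default_rng(rng)
    rcrit = _critical_abs_r(grid, spec.n)
    null_mask = spec.null_pair_mask()
    fdp_sum = np.zeros(len(grid))
    n_pos = np.zeros(len(grid))
    for _ in range(n_mc):
        X, Y = simulate_dataset(spec, rng)
        absr = _abs_corr(X, Y)
        s = _counts_above(np.sort(absr), rcrit)
        f = _counts_above(np.sort(absr[null_mask]), rcrit)
        pos = s > 0
        fdp_sum[pos] += f[pos] / s[pos]
        n_pos += pos
    with np.errstate(invalid="ignore"):
        return np.where(n_pos > 0, fdp_sum / np.maximum(n_pos, 1), np.nan)


@dataclass
class ReplicateResult:
    """One replicate's table, per-method selections and coverage outcomes.

    For each method: ``q`` is the fraction of its selected intervals that fail
    to cover the true FDR (0 when nothing is selected), ``any_upper_lt1``
    whether any selected interval (adjusted for BY) has upper bound < 1, and
    ``records`` a list of (true_fdr, covered) pairs for the selected rows.
    """

    table: pd.DataFrame
    S: np.ndarray
    F: np.ndarray
    selections: Mapping[str, SelectionResult]
    q: dict[str, float]
    any_upper_lt1: dict[str, bool]
    records: dict[str, list[tuple[float, bool]]]


def _coverage_of(sel_mask, lower, upper, truth):
    idx = np.flatnonzero(sel_mask)
    recs, miss, usable = [], 0, 0
    any_lt1 = False
    for i in idx:
        if upper[i] < 1.0:
            any_lt1 = True
        if not np.isfinite(truth[i]):
            continue  # oracle unavailable here; drop from the Q denominator
        usable += 1
        covered = lower[i] <= truth[i] <= upper[i]
        miss += not covered
        recs.append((float(truth[i]), bool(covered)))
    q = miss / usable if usable else 0.0
    return q, any_lt1, recs


def run_replicate(
    spec: ScenarioSpec,
    rng: np.random.Generator | int | None,
    true_fdr: np.ndarray | None = None,
    keep_table: bool = True,
) -> ReplicateResult:
    """Simulate one study, run the permutation FDR analysis and all selectors.

    ``true_fdr`` is the per-threshold oracle curve used for coverage scoring
    (defaults to the exact all-ones curve under the global null).
    """
    rng = np.random.default_rng(rng)
    grid = spec.grid
    rcrit = _critical_abs_r(grid, spec.n)
    null_mask = spec.null_pair_mask()

    X, Y = simulate_dataset(spec, rng)
    absr = _abs_corr(X, Y)
    S = _counts_above(np.sort(absr), rcrit)
    F = _counts_above(np.sort(absr[null_mask]), rcrit)

    C = np.empty((len(grid), spec.n_perm))
    for j in range(spec.n_perm):
        absr_p = _abs_corr(X, permute_outcomes(Y, rng))
        C[:, j] = _counts_above(np.sort(absr_p), rcrit)

    cfg = EstimationConfig(cl=spec.cl)
    table = fdr_table_from_counts(S.astype(float), C, spec.m, grid, cfg)
    table, sels = apply_all_selections(table, alpha=spec.alpha, m2_cut=spec.m2_cut)

    if true_fdr is None:
        if not spec.is_global_null:
            raise ValueError("a true-FDR oracle curve is required outside the global null")
        true_fdr = np.ones(len(grid))

    lo = table["ci_lower"].to_numpy()
    hi = table["ci_upper"].to_numpy()
    alo = table["adj_ci_lower"].to_numpy()
    ahi = table["adj_ci_upper"].to_numpy()

    q, any_lt1, records = {}, {}, {}
    for method, sel in sels.items():
        if method == "BY":
            q[method], any_lt1[method], records[method] = _coverage_of(sel.selected, alo, ahi, true_fdr)
        else:
            q[method], any_lt1[method], records[method] = _coverage_of(sel.selected, lo, hi, true_fdr)

    return ReplicateResult(
        table=table if keep_table else None,
        S=S,
        F=F,
        selections=sels,
        q=q,
        any_upper_lt1=any_lt1,
        records=records,
    )


@dataclass
class CoverageSummary:
    """Replicate-averaged coverage accounting for one scenario.

    ``coverage`` maps method -> 1 - mean(Q); ``frac_any_upper_lt1`` maps
    method -> fraction of replicates with at least one selected interval whose
    (method-appropriate) upper bound is below 1.
    """

    scenario: str
    n_rep: int
    coverage: dict[str, float]
    mean_q: dict[str, float]
    q_se: dict[str, float]
    frac_any_upper_lt1: dict[str, float]
    records: dict[str, list[tuple[float, bool]]]
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scenario": self.scenario,
                "method": m,
                "coverage": self.coverage[m],
                "mean_q": self.mean_q[m],
                "q_se": self.q_se[m],
                "frac_any_upper_lt1": self.frac_any_upper_lt1[m],
                "n_rep": self.n_rep,
            }
            for m in METHODS
        ]
        return pd.DataFrame(rows)


def run_coverage_experiment(
    spec: ScenarioSpec,
    seed: int | np.random.SeedSequence | None = None,
    true_fdr: np.ndarray | None = None,
    n_rep: int | None = None,
) -> CoverageSummary:
    """FCR / coverage accounting over ``n_rep`` independent replicates.

    One master seed spawns an independent substream per replicate, so results
    are bit-reproducible and independent of execution order.
    """
    n_rep = spec.n_rep if n_rep is None else int(n_rep)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_rep)
    if true_fdr is None and spec.is_global_null:
        true_fdr = np.ones(len(spec.grid))
    if true_fdr is None:
        raise ValueError("supply the oracle true-FDR curve for non-null scenarios")

    q_sum = {m: 0.0 for m in METHODS}
    q_sumsq = {m: 0.0 for m in METHODS}
    any_sum = {m: 0 for m in METHODS}
    records: dict[str, list[tuple[float, bool]]] = {m: [] for m in METHODS}
    for child in children:
        rep = run_replicate(spec, np.random.default_rng(child), true_fdr, keep_table=False)
        for m in METHODS:
            q_sum[m] += rep.q[m]
            q_sumsq[m] += rep.q[m] ** 2
            any_sum[m] += rep.any_upper_lt1[m]
            records[m].extend(rep.records[m])

    mean_q = {m: q_sum[m] / n_rep for m in METHODS}
    q_var = {m: max(q_sumsq[m] / n_rep - mean_q[m] ** 2, 0.0) for m in METHODS}
    return CoverageSummary(
        scenario=spec.name,
        n_rep=n_rep,
        coverage={m: 1.0 - mean_q[m] for m in METHODS},
        mean_q=mean_q,
        q_se={m: float(np.sqrt(q_var[m] / n_rep)) for m in METHODS},
        frac_any_upper_lt1={m: any_sum[m] / n_rep for m in METHODS},
        records=records,
        seed=ss.entropy if isinstance(ss.entropy, int) else None,
    )


def conditional_coverage(
    records: Mapping[str, Iterable[tuple[float, bool]]],
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Coverage of selected intervals binned by their threshold's true FDR.

    Pools per-interval (true_fdr, covered) records, typically across the
    non-null scenarios; empty bins are reported as NaN, not zero.
    """
    if bins is None:
        bins = np.linspace(0.0, 0.5, 11)
    bins = np.asarray(bins, dtype=float)
    rows = []
    for method, recs in records.items():
        recs = list(recs)
        truth = np.array([t for t, _ in recs])
        cov = np.array([c for _, c in recs], dtype=float)
        which = np.digitize(truth, bins) - 1
        for b in range(bins.size - 1):
            in_bin = which == b
            rows.append(
                {
                    "method": method,
                    "bin_low": bins[b],
                    "bin_high": bins[b + 1],
                    "n_intervals": int(in_bin.sum()),
                    "coverage": float(cov[in_bin].mean()) if in_bin.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)
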