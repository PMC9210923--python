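"""Permutation-based FDR point estimates, standard errors and confidence intervals.

The estimator is the permutation (positive) FDR, pFDR = E[F/S | S > 0]: for a
p-value threshold ``t`` the observed data yield ``S`` rejections, while an
ensemble of ``P`` permutation replicates — which preserve the dependence among
the m tests but break the association under study — yield a mean null rejection
count ``Vbar``.  The point estimate is

    FDR_hat(t) = pi0_hat * Vbar / S,      pi0_hat = (m - S) / (m - Vbar),

truncated at 1.  A delta-method variance on the log scale combines a
binomial-style term for the observed count with a permutation-ensemble term
scaled by 1/P and an over-dispersion factor c1 (>= 1, estimated from the
spread of the per-permutation counts):

    sigma^2 = (m - S) / (m S) + c1 (m - Vbar) / (P m Vbar).

Everything here is a function of (m, S, per-permutation counts) only: rejection
counts are sufficient, so a pre-reduced counts table gives bit-identical
results to raw p-value vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PValueVector",
    "PermutationEnsemble",
    "ThresholdGrid",
    "EstimationConfig",
    "count_rejections",
    "summarize_permutations",
    "estimate_pi0",
    "mv_fdr_point",
    "se_log_fdr",
    "confidence_interval",
    "fdr_table",
    "fdr_table_from_counts",
]

#: sentinel meaning "estimate the over-dispersion factor from the data"
C1_AUTO = None


def _as_pvalues(values, name: str = "p-values") -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"empty {name} vector")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must be finite and in (0, 1]")
    return arr


@dataclass(frozen=True)
class PValueVector:
    """Observed p-values for m exchangeable tests."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_pvalues(self.values))

    @property
    def m(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PermutationEnsemble:
    """P permutation-replicate null results for the same m tests.

    Stored either as raw p-value vectors (``pvalues`` with shape (P, m)) or,
    losslessly for every operation in this module, as per-threshold rejection
    counts (``counts`` with shape (T, P) aligned to a ThresholdGrid).
    """

    m: int
    pvalues: np.ndarray | None = None
    counts: np.ndarray | None = None
    thresholds: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.pvalues is None) == (self.counts is None):
            raise ValueError("provide exactly one of pvalues or counts")
        if self.pvalues is not None:
            pv = np.atleast_2d(np.asarray(self.pvalues, dtype=float))
            if pv.shape[1] != self.m:
                raise ValueError(f"permutation vectors have {pv.shape[1]} tests, expected m={self.m}")
            _as_pvalues(pv, "permutation p-values")
            object.__setattr__(self, "pvalues", pv)
        else:
            ct = np.atleast_2d(np.asarray(self.counts, dtype=float))
            if np.any(ct < 0) or np.any(ct > self.m):
                raise ValueError("permutation rejection counts must lie in [0, m]")
            if self.thresholds is None:
                raise ValueError("a counts ensemble requires its threshold grid")
            thr = np.asarray(self.thresholds, dtype=float)
            if thr.size != ct.shape[0]:
                raise ValueError("counts rows must align with thresholds")
            object.__setattr__(self, "counts", ct)
            object.__setattr__(self, "thresholds", thr)

    @classmethod
    def from_pvalues(cls, pvalues, m: int | None = None) -> "PermutationEnsemble":
        pv = np.atleast_2d(np.asarray(pvalues, dtype=float))
        return cls(m=pv.shape[1] if m is None else m, pvalues=pv)

    @classmethod
    def from_counts(cls, counts, m: int, thresholds) -> "PermutationEnsemble":
        return cls(m=m, counts=counts, thresholds=thresholds)

    @property
    def n_perm(self) -> int:
        src = self.pvalues if self.pvalues is not None else self.counts.T
        return src.shape[0]

    def counts_at(self, thresholds: np.ndarray, strict: bool = True) -> np.ndarray:
        """Per-threshold, per-permutation rejection counts, shape (T, P)."""
        thresholds = np.asarray(thresholds, dtype=float)
        if self.pvalues is not None:
            side = "left" if strict else "right"
            sorted_p = np.sort(self.pvalues, axis=1)
            out = np.empty((thresholds.size, self.n_perm), dtype=float)
            for j in range(self.n_perm):
                out[:, j] = np.searchsorted(sorted_p[j], thresholds, side=side)
            return out
        if thresholds.shape != self.thresholds.shape or not np.allclose(thresholds, self.thresholds):
            raise ValueError("counts ensemble was built on a different threshold grid")
        return self.counts


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly monotone series of nested p-value cutoffs.

    Stored loose-to-strict (descending t, ascending -log10 t), the order in
    which discovery tables are reported.
    """

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        thr = np.asarray(self.thresholds, dtype=float).ravel()
        if thr.size == 0:
            raise ValueError("empty threshold grid")
        if np.any(thr <= 0.0) or np.any(thr >= 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        if thr.size > 1:
            d = np.diff(thr)
            if np.all(d < 0):
                pass
            elif np.all(d > 0):
                thr = thr[::-1]
            else:
                raise ValueError("thresholds must be strictly monotone")
        object.__setattr__(self, "thresholds", thr)

    @classmethod
    def from_neg_log10(cls, start: float = 2.0, stop: float = 6.0, step: float = 0.1) -> "ThresholdGrid":
        if step <= 0:
            raise ValueError("grid step must be positive")
        n = int(round((stop - start) / step)) + 1
        expo = start + step * np.arange(n)
        return cls(10.0 ** (-expo))

    @property
    def neg_log10(self) -> np.ndarray:
        return -np.log10(self.thresholds)

    def __len__(self) -> int:
        return self.thresholds.size


@dataclass(frozen=True)
class EstimationConfig:
    """Settings for interval estimation.

    cl          confidence level of the (unadjusted) intervals.
    c1          over-dispersion factor for the permutation-count variance term;
                None (default) estimates it from the per-permutation counts,
                floored at 1 (never less dispersed than binomial).
    strict      rejection rule p < t (True, default) versus p <= t.
    cap_at_one  truncate the point estimate at 1 (pFDR <= 1 by definition).
    """

    cl: float = 0.95
    c1: float | None = C1_AUTO
    strict: bool = True
    cap_at_one: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.cl < 1.0:
            raise ValueError("confidence level must be in (0, 1)")
        if self.c1 is not None and self.c1 <= 0:
            raise ValueError("c1 must be positive")


def count_rejections(pvals, t: float, strict: bool = True) -> int:
    """Number of tests rejected at threshold ``t`` (default rule: p < t)."""
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    values = pvals.values if isinstance(pvals, PValueVector) else _as_pvalues(pvals)
    return int(np.sum(values < t) if strict else np.sum(values <= t))


def summarize_permutations(ens: PermutationEnsemble, t: float, strict: bool = True):
    """Mean and unbiased sample variance of per-permutation rejection counts at ``t``.

    Returns ``(vbar, var_counts, n_perm)``; ``var_counts`` is NaN when only one
    permutation is available (which forces the default over-dispersion c1 = 1).
    """
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    counts = ens.counts_at(np.array([t]), strict=strict)[0]
    vbar = float(np.mean(counts))
    var = float(np.var(counts, ddof=1)) if counts.size >= 2 else float("nan")
    return vbar, var, counts.size


def estimate_pi0(m: int, s: int, vbar: float) -> float:
    """Null-proportion estimate pi0 = ((m-S)/m) / ((m-Vbar)/m), truncated to [0, 1]."""
    if vbar >= m:
        raise ValueError("mean permuted rejection count must be < m")
    return float(np.clip((m - s) / (m - vbar), 0.0, 1.0))


def mv_fdr_point(m: int, s: int, vbar: float, pi0: float, cap_at_one: bool = True) -> float:
    """Permutation pFDR point estimate pi0 * Vbar / S (S > 0 required)."""
    if s <= 0:
        raise ValueError("FDR estimate undefined when S = 0")
    fdr = pi0 * vbar / s
    return float(min(fdr, 1.0)) if cap_at_one else float(fdr)


def _c1_from_dispersion(var_counts: float, vbar: float, m: int) -> float:
    # over-dispersion of permutation counts relative to Binomial(m, Vbar/m), floored at 1
    if not np.isfinite(var_counts) or vbar <= 0 or vbar >= m:
        return 1.0
    binom_var = vbar * (1.0 - vbar / m)
    return max(1.0, var_counts / binom_var)


def se_log_fdr(
    m: int,
    s: int,
    vbar: float,
    var_counts: float = float("nan"),
    n_perm: int = 1,
    c1: float | None = C1_AUTO,
) -> float:
    """Delta-method standard error of log(FDR_hat).

    sigma^2 = (m - S)/(m S) + c1 (m - Vbar)/(P m Vbar); the first term is the
    observed-count (binomial-style) contribution, the second the permutation
    ensemble's, shrinking as 1/P.  Degenerate S = m or Vbar = m contributions
    clamp at zero.
    """
    if s <= 0 or vbar <= 0:
        raise ValueError("se of log FDR requires S > 0 and Vbar > 0")
    if c1 is C1_AUTO:
        c1 = _c1_from_dispersion(var_counts, vbar, m)
    obs_term = max(m - s, 0) / (m * s)
    perm_term = c1 * max(m - vbar, 0.0) / (n_perm * m * vbar)
    return float(np.sqrt(obs_term + perm_term))


def confidence_interval(fdr_hat: float, se_log: float, cl: float = 0.95):
    """Log-normal Wald interval exp(log(FDR_hat) +/- z_{(1-cl)/2} * se_log).

    The upper bound deliberately may exceed 1 — selection by "upper bound < 1"
    needs the unclipped value.
    """
    if not 0.0 < cl < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    if fdr_hat <= 0 or se_log <= 0:
        raise ValueError("interval requires fdr_hat > 0 and se_log > 0")
    z = stats.norm.isf((1.0 - cl) / 2.0)
    half = z * se_log
    return float(fdr_hat * np.exp(-half)), float(fdr_hat * np.exp(half))


def fdr_table_from_counts(
    s_obs,
    perm_counts,
    m: int,
    grid: ThresholdGrid,
    config: EstimationConfig | None = None,
) -> pd.DataFrame:
    """Vectorized FDR table straight from sufficient statistics.

    Parameters
    ----------
    s_obs : (T,) observed rejection counts per grid threshold.
    perm_counts : (T, P) per-permutation rejection counts.
    m : total number of tests.
    """
    cfg = config or EstimationConfig()
    S = np.asarray(s_obs, dtype=float)
    C = np.atleast_2d(np.asarray(perm_counts, dtype=float))
    T = len(grid)
    if S.shape != (T,) or C.shape[0] != T:
        raise ValueError("counts must align with the threshold grid")
    if np.any(S < 0) or np.any(S > m) or np.any(C < 0) or np.any(C > m):
        raise ValueError("rejection counts must lie in [0, m]")
    P = C.shape[1]

    vbar = C.mean(axis=1)
    var_counts = C.var(axis=1, ddof=1) if P >= 2 else np.full(T, np.nan)
    defined = S > 0
    continuity = defined & (vbar == 0.0)
    vb = np.where(continuity, 0.5 / P, vbar)  # conservative continuity substitution

    with np.errstate(divide="ignore", invalid="ignore"):
        pi0 = np.where(vb < m, np.clip((m - S) / (m - vb), 0.0, 1.0), 1.0)
        fdr = np.where(defined, pi0 * vb / np.where(defined, S, 1.0), np.nan)
        if cfg.cap_at_one:
            fdr = np.where(defined, np.minimum(fdr, 1.0), np.nan)
        if cfg.c1 is C1_AUTO:
            binom_var = vb * (1.0 - vb / m)
            c1 = np.where(binom_var > 0, np.maximum(1.0, var_counts / binom_var), 1.0)
            c1 = np.where(np.isfinite(c1), c1, 1.0)
        else:
            c1 = np.full(T, float(cfg.c1))
        se2 = np.clip(m - S, 0.0, None) / (m * np.where(defined, S, 1.0)) + c1 * np.clip(
            m - vb, 0.0, None
        ) / (P * m * np.where(vb > 0, vb, 1.0))
        usable = defined & (vb > 0) & (fdr > 0)
        se = np.where(usable, np.sqrt(se2), np.nan)
        z = stats.norm.isf((1.0 - cfg.cl) / 2.0)
        ci_lower = np.where(usable, fdr * np.exp(-z * se), np.nan)
        ci_upper = np.where(usable, fdr * np.exp(z * se), np.nan)
        wald_p = np.where(usable, stats.norm.cdf(np.log(np.where(usable, fdr, 1.0)) / se), np.nan)

    table = pd.DataFrame(
        {
            "threshold": grid.thresholds,
            "neg_log10_t": grid.neg_log10,
            "S": S.astype(int),
            "Vbar": vbar,
            "var_perm_counts": var_counts,
            "pi0": np.where(defined, pi0, np.nan),
            "fdr": fdr,
            "se_log": se,
            "ci_lower": ci_lower,
            "ci_upper": ci_upper,
            "wald_p": wald_p,
            "defined": defined,
            "continuity": continuity,
        }
    )
    table.attrs["m"] = int(m)
    table.attrs["n_perm"] = int(P)
    table.attrs["cl"] = float(cfg.cl)
    return table


def fdr_table(
    obs,
    ens: PermutationEnsemble,
    grid: ThresholdGrid,
    config: EstimationConfig | None = None,
) -> pd.DataFrame:
    """FDR estimates, standard errors, CIs and Wald p-values over a threshold grid.

    One row per threshold, loose to strict.  Rows with S = 0 are flagged
    undefined (no estimate, never selectable); rows with S > 0 but zero
    permuted rejections receive the continuity substitution Vbar_eff = 0.5/P
    and are flagged ``continuity``.
    """
    cfg = config or EstimationConfig()
    obs = obs if isinstance(obs, PValueVector) else PValueVector(np.asarray(obs))
    if obs.m != ens.m:
        raise ValueError(f"observed vector has m={obs.m} but ensemble has m={ens.m}")
    side = "left" if cfg.strict else "right"
    s_obs = np.searchsorted(np.sort(obs.values), grid.thresholds, side=side).astype(float)
    perm_counts = ens.counts_at(grid.thresholds, strict=cfg.strict)
    return fdr_table_from_counts(s_obs, perm_counts, obs.m, grid, cfg)
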