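"""Post hoc selection of discovery thresholds and FCR adjustment of their intervals.

Each candidate threshold t carries a one-sided Wald test of H0: log(FDR_t) = 0
against Ha: log(FDR_t) < 0,

    P_t = Phi( log(FDR_hat_t) / se_log_t ),

small P_t meaning strong evidence that some discoveries at t are true.  The
step-up (BH) rule over the |T| threshold p-values picks R = max{i : P_(i) <
i*alpha/|T|}; the intervals of the selected thresholds are then re-issued at
the adjusted level alpha* = R*alpha/|T|, which keeps the false
coverage-statement rate (the expected fraction of selected intervals missing
their parameter, 0 when nothing is selected) at alpha under PRDS-type positive
dependence.  Two naive comparators are also provided: select thresholds whose
unadjusted CI upper bound is below 1 ("UCB"), or whose point estimate is below
a cut, 0.2 by default ("M.2").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionResult",
    "wald_pvalue",
    "bh_select",
    "fcr_adjust",
    "select_ucb",
    "select_point",
    "apply_all_selections",
]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selection rule over an FDR table.

    ``selected`` is a boolean mask aligned to the table rows.  For the BY
    (step-up + adjustment) method, ``n_selected`` is the step-up count R and
    ``alpha_star`` = R*alpha/|T| is the adjusted interval level.
    """

    method: str
    selected: np.ndarray
    alpha: float | None = None
    alpha_star: float | None = None

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.selected))

    @property
    def any_selected(self) -> bool:
        return bool(np.any(self.selected))


def wald_pvalue(fdr_hat: float, se_log: float) -> float:
    """One-sided Wald p-value P_t = Phi(log(FDR_hat)/se_log)."""
    if se_log <= 0 or not np.isfinite(se_log):
        raise ValueError("Wald p-value requires a positive finite se_log")
    if fdr_hat <= 0:
        raise ValueError("Wald p-value requires fdr_hat > 0")
    return float(stats.norm.cdf(np.log(fdr_hat) / se_log))


def bh_select(pvals, alpha: float = 0.05, n_tests: int | None = None) -> SelectionResult:
    """Step-up selection over the threshold p-values.

    R = max{i : P_(i) < i*alpha/n_tests} (strict inequality); the selected set
    is every row with P_t <= P_(R), so ties at the critical p-value are all
    included.  NaN p-values (undefined thresholds) are never selected but, by
    default, still count in ``n_tests``: the candidate family is the full
    grid the investigator proposed.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("no p-values to select from")
    n = p.size if n_tests is None else int(n_tests)
    finite = np.isfinite(p)
    sorted_p = np.sort(p[finite])
    i = np.arange(1, sorted_p.size + 1)
    passing = sorted_p < i * alpha / n
    r = int(i[passing].max()) if np.any(passing) else 0
    if r == 0:
        selected = np.zeros(p.size, dtype=bool)
    else:
        selected = finite & (p <= sorted_p[r - 1])
    return SelectionResult(
        method="BY", selected=selected, alpha=alpha, alpha_star=r * alpha / n
    )


def fcr_adjust(table: pd.DataFrame, sel: SelectionResult) -> pd.DataFrame:
    """Re-issue the selected rows' intervals at the FCR-adjusted level.

    Adds ``selected_by``, ``adj_ci_lower`` and ``adj_ci_upper`` columns; the
    adjusted interval exp{log(FDR_hat) +/- z_{alpha*/2} se_log} with alpha* =
    R*alpha/|T| is at least as wide as the unadjusted one whenever
    alpha* <= 1 - cl, and only selected rows carry one.
    """
    out = table.copy()
    out["selected_by"] = sel.selected
    out["adj_ci_lower"] = np.nan
    out["adj_ci_upper"] = np.nan
    if sel.n_selected == 0:
        return out
    z = stats.norm.isf(sel.alpha_star / 2.0)
    rows = sel.selected
    half = z * out.loc[rows, "se_log"]
    out.loc[rows, "adj_ci_lower"] = out.loc[rows, "fdr"] * np.exp(-half)
    out.loc[rows, "adj_ci_upper"] = out.loc[rows, "fdr"] * np.exp(half)
    return out


def select_ucb(table: pd.DataFrame) -> SelectionResult:
    """Select every defined threshold whose unadjusted CI upper bound is < 1."""
    mask = table["defined"].to_numpy() & (table["ci_upper"].to_numpy() < 1.0)
    mask &= np.isfinite(table["ci_upper"].to_numpy())
    return SelectionResult(method="UCB", selected=mask)


def select_point(table: pd.DataFrame, cut: float = 0.2) -> SelectionResult:
    """Select every defined threshold whose FDR point estimate is < ``cut``."""
    fdr = table["fdr"].to_numpy()
    mask = table["defined"].to_numpy() & np.isfinite(fdr) & (fdr < cut)
    return SelectionResult(method="M.2", selected=mask)


def apply_all_selections(
    table: pd.DataFrame, alpha: float = 0.05, m2_cut: float = 0.2
) -> tuple[pd.DataFrame, dict[str, SelectionResult]]:
    """Run UCB, M.2 and the step-up/FCR procedure; return the annotated table.

    The step-up family size is the full grid length; undefined rows contribute
    no p-value and are unselectable.
    """
    by = bh_select(table["wald_p"].to_numpy(), alpha=alpha, n_tests=len(table))
    ucb = select_ucb(table)
    m2 = select_point(table, cut=m2_cut)
    out = fcr_adjust(table, by)
    out["selected_ucb"] = ucb.selected
    out["selected_m2"] = m2.selected
    return out, {"BY": by, "UCB": ucb, "M.2": m2}
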