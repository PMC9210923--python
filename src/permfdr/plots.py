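"""Discovery and conditional-coverage figures.

The discovery plot shows the FDR point estimate over the -log10 threshold
grid with a shaded unadjusted CI band, a lighter band for the FCR-adjusted
intervals where thresholds were selected, the number of discoveries annotated
at each threshold, and a dashed FDR = 0.05 reference line.
"""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["discovery_plot", "conditional_coverage_plot"]


def discovery_plot(table: pd.DataFrame, out=None, ax=None, annotate: bool = True):
    """Render the FDR-vs-threshold discovery plot; returns the axes.

    Rows with no estimate (S = 0) are simply gaps in the curve.  If no row
    carries an adjusted interval, only the unadjusted band is drawn.
    """
    if table.empty:
        raise ValueError("empty FDR table")
    if ax is None:
        _, ax = plt.subplots(figsize=(7.5, 4.5))
    defined = table["defined"].to_numpy().astype(bool)
    if not defined.any():
        warnings.warn("no defined rows: nothing to plot", stacklevel=2)
    x = table["neg_log10_t"].to_numpy()
    fdr = np.where(defined, table["fdr"].to_numpy(), np.nan)

    ax.fill_between(
        x,
        table["ci_lower"].to_numpy(),
        np.minimum(table["ci_upper"].to_numpy(), 1.05),
        color="0.55",
        alpha=0.55,
        linewidth=0,
        label="95% CI" if table.attrs.get("cl", 0.95) == 0.95 else "CI",
    )
    if "adj_ci_lower" in table.columns and table["adj_ci_lower"].notna().any():
        ax.fill_between(
            x,
            table["adj_ci_lower"].to_numpy(),
            np.minimum(table["adj_ci_upper"].to_numpy(), 1.05),
            color="0.8",
            alpha=0.7,
            linewidth=0,
            label="FCR-adjusted CI",
        )
    ax.plot(x, fdr, color="black", lw=1.2, label="FDR estimate")
    ax.axhline(0.05, ls="--", color="black", lw=0.8)
    if annotate:
        for xi, fi, si in zip(x, fdr, table["S"]):
            if np.isfinite(fi):
                ax.annotate(str(int(si)), (xi, fi), textcoords="offset points",
                            xytext=(0, 4), ha="center", fontsize=7)
    ax.set_xlabel(r"$-\log_{10}$ p-value threshold")
    ax.set_ylabel("FDR")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper right", frameon=False, fontsize=8)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def conditional_coverage_plot(cond: pd.DataFrame, out=None, ax=None, cl: float = 0.95):
    """Per-bin conditional coverage curves, one line per selection method."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6.5, 4.0))
    mid = (cond["bin_low"] + cond["bin_high"]) / 2.0
    for method, sub in cond.assign(mid=mid).groupby("method"):
        ok = sub["coverage"].notna()
        ax.plot(sub.loc[ok, "mid"], sub.loc[ok, "coverage"], marker="o", ms=3, label=method)
    ax.axhline(cl, ls="--", color="black", lw=0.8)
    ax.set_xlabel("true FDR")
    ax.set_ylabel("conditional coverage")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
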