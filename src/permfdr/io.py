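"""Delimited-text readers and writers for p-value tables and FDR results.

All files are plain delimited text (tab-separated by default, '.' decimal,
mandatory header row) so every table round-trips losslessly.  Three input
layouts are accepted for permutation results:

wide    one column of observed p-values (``observed``) followed by one column
        per permutation replicate (any names).
long    columns ``perm_id`` and ``p``; observed p-values come from a separate
        single-column file.
counts  columns ``threshold``, ``perm_id``, ``count`` — the sufficient
        per-threshold rejection counts; observed counts use perm_id = "obs".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import PermutationEnsemble, PValueVector, ThresholdGrid

__all__ = [
    "read_pvalues",
    "read_pvalue_tables",
    "read_counts_table",
    "write_fdr_table",
    "read_fdr_table",
    "read_config",
]

_SEP = {"\t": "\t", ",": ","}


def _read(path, sep="\t") -> pd.DataFrame:
    # round_trip parser: 17-significant-digit text must reproduce float64 exactly
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_pvalues(path, column: str | None = None, sep: str = "\t") -> PValueVector:
    """Read a single observed p-value column (default: first column)."""
    df = _read(path, sep)
    col = column or df.columns[0]
    values = df[col].to_numpy(dtype=float)
    bad = np.flatnonzero(~(np.isfinite(values) & (values > 0) & (values <= 1)))
    if bad.size:
        raise ValueError(f"{path}: p-values outside (0, 1] at rows {bad[:10].tolist()}")
    return PValueVector(values)


def read_pvalue_tables(
    obs_path,
    perm_path=None,
    layout: str = "wide",
    sep: str = "\t",
) -> tuple[PValueVector, PermutationEnsemble]:
    """Load observed p-values plus a permutation ensemble.

    With ``layout='wide'``, ``obs_path`` alone holds an ``observed`` column
    (or first column) and the remaining columns are permutation replicates.
    With ``layout='long'``, ``perm_path`` holds (perm_id, p) rows.
    """
    if layout == "wide":
        df = _read(obs_path, sep)
        obs_col = "observed" if "observed" in df.columns else df.columns[0]
        perm_cols = [c for c in df.columns if c != obs_col]
        if not perm_cols:
            raise ValueError(f"{obs_path}: wide layout needs at least one permutation column")
        obs = PValueVector(df[obs_col].to_numpy(dtype=float))
        ens = PermutationEnsemble.from_pvalues(df[perm_cols].to_numpy(dtype=float).T)
    elif layout == "long":
        if perm_path is None:
            raise ValueError("long layout needs a separate permutation file")
        obs = read_pvalues(obs_path, sep=sep)
        df = _read(perm_path, sep)
        for c in ("perm_id", "p"):
            if c not in df.columns:
                raise ValueError(f"{perm_path}: long layout needs columns perm_id and p")
        groups = df.groupby("perm_id", sort=True)["p"]
        sizes = groups.size()
        if sizes.nunique() != 1:
            raise ValueError(f"{perm_path}: permutation replicates have unequal lengths")
        ens = PermutationEnsemble.from_pvalues(np.stack([g.to_numpy() for _, g in groups]))
    else:
        raise ValueError(f"unknown layout {layout!r} (expected wide or long)")
    if obs.m != ens.m:
        raise ValueError(f"observed vector has m={obs.m}, permutations have m={ens.m}")
    return obs, ens


def read_counts_table(path, m: int, sep: str = "\t"):
    """Load the sufficient-statistics layout: (threshold, perm_id, count) rows.

    Observed counts carry ``perm_id == 'obs'``.  Returns ``(s_obs, ensemble,
    grid)`` ready for :func:`permfdr.core.fdr_table_from_counts`.
    """
    df = _read(path, sep)
    for c in ("threshold", "perm_id", "count"):
        if c not in df.columns:
            raise ValueError(f"{path}: counts layout needs threshold, perm_id, count columns")
    df = df.copy()
    df["perm_id"] = df["perm_id"].astype(str)
    thresholds = np.sort(df["threshold"].unique())[::-1]
    grid = ThresholdGrid(thresholds)
    obs = df[df["perm_id"] == "obs"].set_index("threshold")["count"]
    if len(obs) != len(grid):
        raise ValueError(f"{path}: need one observed count per threshold")
    s_obs = obs.loc[thresholds].to_numpy(dtype=float)
    perms = df[df["perm_id"] != "obs"]
    wide = perms.pivot(index="threshold", columns="perm_id", values="count")
    if wide.isna().any().any():
        raise ValueError(f"{path}: missing permutation counts for some thresholds")
    counts = wide.loc[thresholds].to_numpy(dtype=float)
    ens = PermutationEnsemble.from_counts(counts, m=m, thresholds=thresholds)
    return s_obs, ens, grid


def write_fdr_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write an FDR table as delimited text at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_fdr_table(path, sep: str = "\t") -> pd.DataFrame:
    return _read(path, sep)


def read_config(path) -> dict[str, str]:
    """Flat key = value config file mirroring the CLI flags; '#' comments."""
    out: dict[str, str] = {}
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{line_no}: expected key = value, got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
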