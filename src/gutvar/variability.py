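"""Variability statistics: CV tables, signed-rank comparisons, heterogeneity.

The central quantity is the coefficient of variation (CV = sd/mean) of a
variable across replicate vessels at one timepoint.  Building one CV table
per measurement method (HPLC, cytometry classification, each 16S technical
replicate) and comparing paired cells with the Wilcoxon signed-rank test
quantifies whether technical variability exceeds biological (vessel-to-
vessel) variability.

The signed-rank test uses an exact null (full sign-flip distribution,
computed by subset-sum dynamic programming over midranks, so ties are
handled exactly) for up to 25 pairs, and the normal approximation with tie
and continuity corrections beyond that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import EventTable, SampleTable

__all__ = [
    "CVTable",
    "HeterogeneityValue",
    "coefficient_of_variation",
    "cv_table",
    "aggregate_cv",
    "paired_wilcoxon",
    "compare_methods_cv",
    "heterogeneity",
    "method_correlation",
]


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """CV = sd/mean.  Returns NaN (missing) for n < 2 or zero mean."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    m = x.mean()
    if m == 0:
        warnings.warn("zero mean; CV undefined, returning missing")
        return float("nan")
    return float(x.std(ddof=ddof) / m)


@dataclass
class CVTable:
    """Timepoints x variables matrix of CVs for one measurement method."""

    values: pd.DataFrame  # index: timepoint (h); columns: variables
    method: str = ""
    ddof: int = 1

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("CVs cannot be negative")


def cv_table(
    data: SampleTable,
    ddof: int = 1,
    method: str = "",
    group_by: str = "timepoint",
    across: str = "vessel",
) -> CVTable:
    """One CV per (timepoint, variable), taken across vessels.

    ``data.meta`` must provide the grouping and replication columns.  Cells
    backed by fewer than two vessel values come out missing (NaN).
    """
    if data.meta is None or group_by not in data.meta.columns:
        raise ValueError(f"sample metadata with a {group_by!r} column is required")
    groups = data.meta[group_by]
    timepoints = sorted(groups.dropna().unique())
    rows = {}
    for tp in timepoints:
        block = data.data.loc[groups == tp]
        rows[tp] = {
            var: coefficient_of_variation(block[var], ddof=ddof)
            for var in data.variables
        }
    values = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=data.variables
    )
    values.index.name = group_by
    return CVTable(values, method=method, ddof=ddof)


def aggregate_cv(table: CVTable | pd.DataFrame, exclude: list[str] = ()) -> dict:
    """Row, column, and grand means of a CV table, ignoring missing cells.

    ``exclude`` removes variables (e.g. contaminants) before the row means —
    the "average per timepoint without X" style of summary.
    """
    df = table.values if isinstance(table, CVTable) else table
    if df.size == 0:
        raise ValueError("empty CV table")
    kept = df.drop(columns=list(exclude), errors="ignore")
    return {
        "row_means": kept.mean(axis=1, skipna=True),
        "column_means": df.mean(axis=0, skipna=True),
        "grand_mean": float(np.nanmean(kept.to_numpy(dtype=float))),
    }


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 25


def _signed_rank_null(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of subset sums of ``doubled_ranks`` (the exact W+ null, x2 scale)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def paired_wilcoxon(
    a,
    b,
    alternative: str = "two-sided",
    zero_method: str = "wilcox",
) -> dict:
    """Paired Wilcoxon signed-rank test of ``a`` versus ``b``.

    ``alternative='greater'`` tests for a located above b.  Zero differences
    are dropped by default (``wilcox``); ``pratt`` ranks them first and then
    discards their ranks.  Exact p for up to 25 informative pairs, normal
    approximation with tie/continuity correction beyond.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[~np.isnan(d)]
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            warnings.warn("all differences are zero; p = 1")
            return {"w_plus": 0.0, "w_minus": 0.0, "statistic": 0.0,
                    "p": 1.0, "n": 0, "method": "degenerate"}
        ranks = stats.rankdata(np.abs(d))
    else:
        if not np.any(d != 0):
            warnings.warn("all differences are zero; p = 1")
            return {"w_plus": 0.0, "w_minus": 0.0, "statistic": 0.0,
                    "p": 1.0, "n": 0, "method": "degenerate"}
        ranks_all = stats.rankdata(np.abs(d))
        ranks = ranks_all[d != 0]
        d = d[d != 0]
    n = d.size
    if n < 5:
        warnings.warn(f"only {n} informative pairs; test has little power")
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    if n <= _EXACT_LIMIT:
        doubled = np.round(2 * ranks).astype(int)
        counts = _signed_rank_null(doubled)
        denom = counts.sum()
        w2 = int(round(2 * w_plus))
        p_ge = counts[w2:].sum() / denom
        p_le = counts[: w2 + 1].sum() / denom
        method = "exact"
    else:
        mu = ranks.sum() / 2.0
        sigma = np.sqrt((ranks**2).sum() / 4.0)
        # continuity correction of half the smallest rank step
        cc = 0.5
        p_ge = stats.norm.sf((w_plus - mu - cc) / sigma)
        p_le = stats.norm.cdf((w_plus - mu + cc) / sigma)
        method = "normal-approx"
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return {
        "w_plus": w_plus,
        "w_minus": w_minus,
        "statistic": min(w_plus, w_minus),
        "p": float(p),
        "n": n,
        "method": method,
    }


def compare_methods_cv(cv_a: CVTable, cv_b: CVTable) -> dict:
    """Paired comparison of two CV tables on their shared non-missing cells.

    Pairs are (timepoint, variable) cells present in both tables.  Reports
    the one-sided test that method a's CVs exceed method b's, the two-sided
    test, and the ratio of mean CVs.
    """
    rows = cv_a.values.index.intersection(cv_b.values.index)
    cols = cv_a.values.columns.intersection(cv_b.values.columns)
    va = cv_a.values.loc[rows, cols].to_numpy(dtype=float).ravel()
    vb = cv_b.values.loc[rows, cols].to_numpy(dtype=float).ravel()
    ok = ~(np.isnan(va) | np.isnan(vb))
    va, vb = va[ok], vb[ok]
    if va.size < 5:
        raise ValueError(
            f"only {va.size} shared (timepoint, variable) cells; need >= 5"
        )
    greater = paired_wilcoxon(va, vb, alternative="greater")
    two_sided = paired_wilcoxon(va, vb, alternative="two-sided")
    return {
        "n_cells": int(va.size),
        "p_greater": greater["p"],
        "p_two_sided": two_sided["p"],
        "w_plus": greater["w_plus"],
        "w_minus": greater["w_minus"],
        "mean_cv_a": float(va.mean()),
        "mean_cv_b": float(vb.mean()),
        "mean_cv_ratio": float(va.mean() / vb.mean()) if vb.mean() else float("inf"),
        "shared_variables": list(cols),
        "shared_timepoints": list(rows),
    }


# ---------------------------------------------------------------------------
# Population heterogeneity
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneityValue:
    sample_id: str
    value: float
    aggregation: str = "mean"


def heterogeneity(
    events: EventTable, aggregation: str = "mean"
) -> HeterogeneityValue:
    """Population heterogeneity of a gated sample.

    Per channel, the range (max - min) over all events; aggregated across the
    channels by mean (default) or sum.  Larger values indicate a wider spread
    of optical phenotypes, e.g. mixtures of live and dead cells.
    """
    if aggregation not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if events.n_events == 0:
        warnings.warn("no events; heterogeneity is missing")
        return HeterogeneityValue(events.meta.sample_id, float("nan"), aggregation)
    ranges = events.values.max(axis=0) - events.values.min(axis=0)
    value = float(ranges.mean() if aggregation == "mean" else ranges.sum())
    return HeterogeneityValue(events.meta.sample_id, value, aggregation)


def method_correlation(x, y, method: str = "pearson") -> dict:
    """Correlation between two abundance series (method agreement)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series; correlation undefined")
        return {"r": float("nan"), "p": float("nan"), "n": int(x.size)}
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "p": float(p), "n": int(x.size)}
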