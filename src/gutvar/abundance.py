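"""From raw counts to comparable abundances.

Covers the quantitative-profiling arithmetic: volumetric cell densities from
event counts, contaminant exclusion for a defined community, 16S copy-number
correction, and scaling of relative compositions to absolute abundances
(cells/ml) using flow-cytometry totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifiedCounts
from .io import SampleTable

__all__ = [
    "CellDensity",
    "load_copy_numbers",
    "volumetric_count",
    "filter_contaminants",
    "correct_copy_number",
    "to_absolute",
    "classified_to_abundance",
]


@dataclass
class CellDensity:
    sample_id: str
    cells_per_ml: float

    def __post_init__(self) -> None:
        if self.cells_per_ml < 0:
            raise ValueError("cells_per_ml must be >= 0")


def load_copy_numbers(path: str | Path) -> dict[str, float]:
    """Read a species -> 16S copy-number TSV (columns: species, copy_number)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    copies = dict(zip(df["species"], df["copy_number"].astype(float)))
    bad = [sp for sp, v in copies.items() if not v > 0]
    if bad:
        raise ValueError(f"non-positive copy numbers for {bad}")
    return copies


def volumetric_count(
    n_events: int, acquired_volume_ul: float, dilution_factor: float = 1.0
) -> float:
    """Cell density in cells/ml from events, acquired volume (ul) and dilution.

    density = events/ul * dilution * 1000 ul/ml
    """
    if acquired_volume_ul <= 0:
        raise ValueError(f"acquired volume must be > 0, got {acquired_volume_ul}")
    if dilution_factor < 1:
        raise ValueError(f"dilution factor must be >= 1, got {dilution_factor}")
    if n_events < 0:
        raise ValueError("event count must be >= 0")
    return n_events / acquired_volume_ul * dilution_factor * 1000.0


def filter_contaminants(
    counts: SampleTable, members: list[str]
) -> SampleTable:
    """Drop non-member taxa detected in at most one sample.

    In a defined community, a taxon outside the inoculated membership that
    shows up in a single sample is treated as a sequencing-pipeline
    contaminant and removed; one seen in two or more samples is kept as a
    genuine (if unwanted) community resident.  Member taxa are always kept,
    even when entirely absent.
    """
    if counts.kind != "counts":
        raise ValueError(f"expected a counts table, got kind={counts.kind!r}")
    keep = []
    for taxon in counts.variables:
        if taxon in members:
            keep.append(taxon)
        elif int((counts.data[taxon] > 0).sum()) > 1:
            keep.append(taxon)
    return counts.with_data(counts.data[keep])


def correct_copy_number(
    counts: SampleTable, copies: dict[str, float]
) -> SampleTable:
    """Divide taxon counts by 16S copy number and renormalise per sample.

    Samples with zero total count carry no compositional information and are
    excluded from the relative output (their ids are recorded on the returned
    table as ``dropped_samples``).
    """
    missing = [t for t in counts.variables if t not in copies]
    if missing:
        raise ValueError(f"no 16S copy number for taxa: {missing}")
    cp = np.array([copies[t] for t in counts.variables], dtype=float)
    if (cp <= 0).any():
        raise ValueError("copy numbers must be positive")
    corrected = counts.data.to_numpy() / cp
    totals = corrected.sum(axis=1)
    nonzero = totals > 0
    if not nonzero.all():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} all-zero sample(s) from relative output"
        )
    rel = pd.DataFrame(
        corrected[nonzero] / totals[nonzero, None],
        index=counts.data.index[nonzero],
        columns=counts.variables,
    )
    out = counts.with_data(rel, kind="relative")
    out.dropped_samples = list(counts.data.index[~nonzero])
    return out


def to_absolute(
    rel: SampleTable, totals: dict[str, float] | pd.Series
) -> SampleTable:
    """Scale relative abundances by per-sample total cell densities (cells/ml)."""
    if rel.kind != "relative":
        raise ValueError(f"expected a relative table, got kind={rel.kind!r}")
    totals = pd.Series(totals, dtype=float)
    missing = [s for s in rel.samples if s not in totals.index]
    if missing:
        raise ValueError(f"no total cell density for samples: {missing}")
    scale = totals.loc[rel.samples].to_numpy()
    data = rel.data.mul(scale, axis=0)
    return rel.with_data(data, kind="absolute")


def classified_to_abundance(
    results: list[ClassifiedCounts],
    totals: dict[str, float] | pd.Series | None = None,
) -> dict[str, SampleTable]:
    """Turn per-sample classifier counts into abundance tables.

    Returns relative abundances both with the unknown class as a category
    (``rel_with_unknown``; this is what absolute scaling uses) and without it,
    renormalised over the named species (``rel_without_unknown``).  Samples
    whose every event was unknown carry no species information and are
    excluded from the without-unknown table; samples with zero gated events
    are excluded everywhere and reported under ``"missing"``.
    """
    species = sorted({sp for r in results for sp in r.counts})
    rows_with, rows_without, meta_rows = {}, {}, {}
    missing = []
    for r in results:
        sid = r.meta.sample_id
        total = r.total
        if total == 0:
            missing.append(sid)
            continue
        vec = np.array([r.counts.get(sp, 0) for sp in species], dtype=float)
        rows_with[sid] = np.append(vec, r.unknown) / total
        known = vec.sum()
        if known > 0:
            rows_without[sid] = vec / known
        else:
            missing.append(sid)
        meta_rows[sid] = {"vessel": r.meta.vessel, "timepoint": r.meta.timepoint}
    cols_with = species + ["unknown"]
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    with_unknown = SampleTable(
        pd.DataFrame.from_dict(rows_with, orient="index", columns=cols_with),
        "relative",
        meta.loc[list(rows_with)] if len(rows_with) else None,
    )
    without_unknown = SampleTable(
        pd.DataFrame.from_dict(rows_without, orient="index", columns=species),
        "relative",
        meta.loc[list(rows_without)] if len(rows_without) else None,
    )
    out = {
        "rel_with_unknown": with_unknown,
        "rel_without_unknown": without_unknown,
        "missing": missing,
    }
    if totals is not None:
        out["absolute"] = to_absolute(with_unknown, totals)
    return out
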