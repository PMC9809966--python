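"""Readers and writers for flow-cytometry events and tabular sample data.

Event data come either from FCS 3.0/3.1 list-mode files (the instrument's
native format) or from plain TSV matrices with one header row of channel
names.  All sample-by-variable matrices (16S counts, abundances, metabolite
concentrations) travel as TSV with sample metadata in leading columns.

The FCS codec here is deliberately small: list-mode data, float/double or
fixed-width integer events, both byte orders, no compensation or analysis
segments.  Spillover keywords are ignored because downstream classifiers
operate on raw channel values.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .channels import ChannelSet, DEFAULT_CHANNELS

__all__ = [
    "SampleMeta",
    "EventTable",
    "SampleTable",
    "read_events",
    "write_events",
    "read_fcs",
    "write_fcs",
    "read_table",
    "write_table",
]

Role = Literal["monoculture", "blank", "community"]

META_COLUMNS = ("sample_id", "vessel", "timepoint", "replicate")


@dataclass
class SampleMeta:
    """Identity and acquisition metadata for one cytometry sample."""

    sample_id: str = ""
    vessel: str | None = None
    timepoint: float | None = None  # hours post inoculation
    dilution_factor: float = 1.0  # dimensionless, >= 1
    acquired_volume_ul: float | None = None  # microlitres acquired, > 0
    role: Role = "community"
    species: str | None = None  # set for monocultures

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError(
                f"dilution_factor must be >= 1, got {self.dilution_factor}"
            )
        if self.acquired_volume_ul is not None and self.acquired_volume_ul <= 0:
            raise ValueError(
                f"acquired_volume_ul must be > 0, got {self.acquired_volume_ul}"
            )


@dataclass
class EventTable:
    """Events x channels matrix with acquisition metadata.

    ``values`` holds one row per recorded event in acquisition order;
    columns follow ``channels``.
    """

    channels: ChannelSet
    values: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            values = values.reshape(-1, len(self.channels))
        if values.shape[1] != len(self.channels):
            raise ValueError(
                f"event matrix has {values.shape[1]} columns but "
                f"{len(self.channels)} channels are declared"
            )
        if values.size and not np.isfinite(values).all():
            raise ValueError("event matrix contains non-finite values")
        self.values = values

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def channel_values(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]

    def take(self, index: np.ndarray) -> "EventTable":
        """Row-subset preserving metadata and channel order."""
        return EventTable(self.channels, self.values[index], replace(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.channels))


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 list-mode codec
# ---------------------------------------------------------------------------

_DTYPES = {"F": "f4", "D": "f8"}


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ValueError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    return {
        k.decode("ascii", "replace").strip(): v.decode("ascii", "replace")
        for k, v in zip(parts[::2], parts[1::2])
    }


def read_fcs(path: str | Path) -> tuple[ChannelSet, np.ndarray, dict[str, str]]:
    """Read a list-mode FCS 3.0/3.1 file.

    Returns the channel set (short names, ``$PnN``), the events x channels
    float matrix, and the raw TEXT keywords (for ``$VOL`` etc.).
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise IOError(f"cannot read FCS file {path}: {exc}") from exc
    if len(raw) < 58 or raw[:3] != b"FCS":
        raise IOError(f"{path} is not an FCS file")
    version = raw[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise IOError(f"unsupported FCS version {version!r} in {path}")

    def _offset(a: int, b: int) -> int:
        text = raw[a:b].strip() or b"0"
        return int(text)

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    keywords = _parse_text_segment(raw[text_start : text_end + 1])

    if data_start == 0:
        data_start = int(keywords.get("$BEGINDATA", 0))
        data_end = int(keywords.get("$ENDDATA", 0))
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    datatype = keywords.get("$DATATYPE", "F").strip().upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"

    names = []
    for i in range(1, n_par + 1):
        names.append(keywords.get(f"$P{i}N", f"P{i}").strip())
    channels = ChannelSet(tuple(names))

    blob = raw[data_start : data_end + 1]
    if datatype in _DTYPES:
        dtype = np.dtype(endian + _DTYPES[datatype])
    elif datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise IOError("only uniform 16- or 32-bit integer FCS data supported")
        width = int(keywords.get("$P1B", 32)) // 8
        dtype = np.dtype(f"{endian}u{width}")
    else:
        raise IOError(f"unsupported $DATATYPE {datatype!r}")
    need = n_par * n_tot * dtype.itemsize
    if len(blob) < need:
        raise IOError(f"FCS data segment truncated in {path}")
    values = (
        np.frombuffer(blob[:need], dtype=dtype)
        .astype(float)
        .reshape(n_tot, n_par)
    )
    return channels, values, keywords


def write_fcs(path: str | Path, events: EventTable) -> None:
    """Write an FCS 3.1 file (float32 list-mode, little-endian)."""
    path = Path(path)
    values = np.asarray(events.values, dtype="<f4")
    n_tot, n_par = values.shape
    keywords: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
    ]
    if events.meta.acquired_volume_ul is not None:
        # $VOL is expressed in nanolitres by convention
        keywords.append(("$VOL", f"{events.meta.acquired_volume_ul * 1000:.6g}"))
    rng_max = int(max(1.0, np.ceil(values.max()))) if values.size else 1024
    for i, name in enumerate(events.channels, start=1):
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(rng_max)),
        ]
    # fixed-width data offsets so the TEXT length is stable across the fill-in
    keywords += [("$BEGINDATA", "%012d" % 0), ("$ENDDATA", "%012d" % 0)]

    delim = "/"

    def _render(kws: list[tuple[str, str]]) -> bytes:
        out = delim
        for k, v in kws:
            out += f"{k}{delim}{v}{delim}"
        return out.encode("ascii")

    header_len = 58
    text = _render(keywords)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + values.nbytes - 1
    keywords[-2] = ("$BEGINDATA", "%012d" % data_start)
    keywords[-1] = ("$ENDDATA", "%012d" % data_end)
    text = _render(keywords)

    header = b"FCS3.1    " + b"".join(
        b"%8d" % off
        for off in (text_start, text_end, data_start, data_end, 0, 0)
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())


def read_events(
    path: str | Path,
    format: Literal["fcs", "tsv"] | None = None,
    *,
    meta: SampleMeta | None = None,
    expected_channels: ChannelSet | None = None,
    alias_map: dict[str, str] | None = None,
) -> EventTable:
    """Read cytometry events from an FCS or TSV file.

    For FCS files the acquisition volume is taken from the ``$VOL`` keyword
    (nanolitres) when present and not overridden in ``meta``.  For TSV the
    header row names the channels; metadata must be supplied separately.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "fcs" if path.suffix.lower() in (".fcs", ".lmd") else "tsv"
    meta = replace(meta) if meta is not None else SampleMeta(sample_id=path.stem)

    if format == "fcs":
        channels, values, keywords = read_fcs(path)
        if meta.acquired_volume_ul is None and "$VOL" in keywords:
            meta.acquired_volume_ul = float(keywords["$VOL"]) / 1000.0
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t")
        channels = ChannelSet(tuple(df.columns))
        values = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown event format {format!r}")

    if alias_map:
        channels = channels.rename(alias_map)
    if expected_channels is not None:
        channels.validate_against(expected_channels)
    return EventTable(channels, values, meta)


def write_events(path: str | Path, events: EventTable) -> None:
    """Write events as FCS (``.fcs`` suffix) or TSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        write_fcs(path, events)
    else:
        events.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Sample x variable tables
# ---------------------------------------------------------------------------

TableKind = Literal["counts", "relative", "absolute", "concentration"]

_REL_TOL = 1e-9


@dataclass
class SampleTable:
    """Samples x variables matrix (counts, abundances, or concentrations).

    ``data`` is indexed by sample id; ``meta`` carries vessel / timepoint /
    replicate columns aligned on the same index.  ``kind`` determines the
    validation applied: counts must be non-negative integers and relative
    abundances must sum to one per row (all-zero rows are tolerated and
    treated as missing samples downstream).
    """

    data: pd.DataFrame
    kind: TableKind = "counts"
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        data = self.data.astype(float)
        arr = data.to_numpy()
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at sample {data.index[r]!r}, "
                f"variable {data.columns[c]!r}"
            )
        neg = arr < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValueError(
                f"negative value {arr[r, c]} at sample {data.index[r]!r}, "
                f"variable {data.columns[c]!r}"
            )
        if self.kind == "counts":
            frac = np.abs(arr - np.round(arr))
            if (frac > 1e-6).any():
                r, c = np.argwhere(frac > 1e-6)[0]
                raise ValueError(
                    f"non-integer count {arr[r, c]} at sample "
                    f"{data.index[r]!r}, variable {data.columns[c]!r}"
                )
            data = data.round()
        elif self.kind == "relative":
            sums = arr.sum(axis=1)
            bad = (np.abs(sums - 1.0) > 1e-6) & (sums > 0)
            if bad.any():
                r = int(np.argwhere(bad)[0][0])
                raise ValueError(
                    f"relative abundances of sample {data.index[r]!r} sum to "
                    f"{sums[r]:.6g}, expected 1"
                )
        data.index = data.index.rename("sample_id")
        self.data = data
        if self.meta is not None and not self.meta.index.equals(data.index):
            raise ValueError("meta index does not match data index")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def variables(self) -> pd.Index:
        return self.data.columns

    def with_data(self, data: pd.DataFrame, kind: TableKind | None = None) -> "SampleTable":
        meta = None
        if self.meta is not None:
            meta = self.meta.loc[self.meta.index.intersection(data.index)]
            meta = meta.reindex(data.index)
        return SampleTable(data, kind or self.kind, meta)


def write_table(table: SampleTable, path: str | Path) -> None:
    """Write a SampleTable as TSV with metadata in leading columns."""
    df = table.data.copy()
    if table.meta is not None:
        for col in reversed([c for c in META_COLUMNS[1:] if c in table.meta.columns]):
            df.insert(0, col, table.meta[col])
    df.insert(0, "sample_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_table(path: str | Path, kind: TableKind = "counts") -> SampleTable:
    """Read a TSV written by :func:`write_table` (or hand-made in its layout)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path} lacks a sample_id column")
    df = df.set_index("sample_id")
    meta_cols = [c for c in META_COLUMNS[1:] if c in df.columns]
    meta = df[meta_cols] if meta_cols else None
    data = df.drop(columns=meta_cols)
    return SampleTable(data, kind, meta)
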