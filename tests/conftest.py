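"""Shared fixtures: the separable synthetic panel and derived event data."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from gutvar.io import SampleTable
from gutvar.synthetic import (
    blank_event_table,
    make_species_panel,
    monoculture_event_tables,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def panel():
    """Four species at pairwise Mahalanobis separation 4 (separable fixture)."""
    return make_species_panel(4, 4.0, seed=20260920)


@pytest.fixture(scope="session")
def monocultures(panel):
    """Gated monoculture event tables, 3000 events per species."""
    return monoculture_event_tables(panel, 3000, seed=11)


@pytest.fixture(scope="session")
def blank(panel):
    return blank_event_table(panel, 3000, seed=12)


@pytest.fixture(scope="session")
def counts_table():
    """Small counts table: 6 samples x 3 taxa with vessel/timepoint metadata."""
    rng = np.random.default_rng(5)
    idx = pd.Index([f"V{v}_t{t}" for v in (1, 2, 3) for t in (12, 25)],
                   name="sample_id")
    data = pd.DataFrame(
        rng.integers(10, 500, size=(6, 3)), index=idx, columns=["A", "B", "C"]
    )
    meta = pd.DataFrame(
        {"vessel": [s.split("_")[0] for s in idx],
         "timepoint": [int(s.split("_t")[1]) for s in idx]},
        index=idx,
    )
    return SampleTable(data, "counts", meta)


def load_published_cv(name: str) -> pd.DataFrame:
    """One of the published CV tables (cells only), timepoint-indexed."""
    return pd.read_csv(DATA_DIR / name, sep="\t", index_col="timepoint")
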