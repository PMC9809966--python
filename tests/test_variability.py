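"""CV computation, table aggregation, the signed-rank test, heterogeneity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import load_published_cv
from gutvar.channels import ChannelSet, DEFAULT_CHANNELS
from gutvar.io import EventTable, SampleMeta, SampleTable
from gutvar.variability import (
    CVTable,
    aggregate_cv,
    coefficient_of_variation,
    compare_methods_cv,
    cv_table,
    heterogeneity,
    method_correlation,
    paired_wilcoxon,
)


def enumerate_wilcoxon(d, alternative):
    """Oracle: full 2^n sign-flip distribution of W+ with midranks."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestCV:
    def test_basic_values(self):
        assert coefficient_of_variation([2, 4, 6]) == pytest.approx(0.5)
        assert coefficient_of_variation([5, 5, 5, 5]) == 0.0

    def test_single_nonzero_among_five_is_sqrt5(self):
        # the value repeatedly printed for species detected in one vessel
        for x in (1.0, 17.3, 2.5e6):
            cv = coefficient_of_variation([x, 0, 0, 0, 0])
            assert cv == pytest.approx(np.sqrt(5), abs=1e-12)
            assert cv == pytest.approx(2.236067977, abs=1e-9)

    def test_zero_mean_and_short_input_are_missing(self):
        with pytest.warns(UserWarning, match="zero mean"):
            assert np.isnan(coefficient_of_variation([1.0, -1.0]))
        assert np.isnan(coefficient_of_variation([3.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(1e-6, 1e6))
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(0, 0.5, size=8)
        assert coefficient_of_variation(c * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-9
        )


class TestCVTable:
    def _table(self, values, vessels, timepoints):
        idx = [f"{v}_t{t}" for v in vessels for t in timepoints]
        meta = pd.DataFrame(
            {"vessel": [v for v in vessels for _ in timepoints],
             "timepoint": [t for _ in vessels for t in timepoints]},
            index=pd.Index(idx, name="sample_id"),
        )
        return SampleTable(
            pd.DataFrame(values, index=meta.index, columns=["x", "y"]),
            "concentration", meta,
        )

    def test_equal_vessels_give_zero_cv(self):
        table = self._table(np.tile([[2.0, 3.0], [4.0, 5.0]], (6, 1)),
                            [f"V{i}" for i in range(6)], [12, 25])
        cvt = cv_table(table)
        assert (cvt.values.to_numpy() == 0).all()

    def test_single_vessel_gives_all_missing(self):
        table = self._table([[2.0, 3.0], [4.0, 5.0]], ["V1"], [12, 25])
        cvt = cv_table(table)
        assert cvt.values.isna().all().all()

    def test_lognormal_cv_matches_closed_form(self):
        # CV of a lognormal with log-sd sigma is sqrt(exp(sigma^2) - 1)
        rng = np.random.default_rng(7)
        sigma, n_vessels = 0.4, 200
        vessels = [f"V{i}" for i in range(n_vessels)]
        values = np.exp(rng.normal(np.log(5.0), sigma, size=(2 * n_vessels, 2)))
        table = self._table(values, vessels, [12, 25])
        cvt = cv_table(table)
        expected = np.sqrt(np.exp(sigma**2) - 1)
        np.testing.assert_allclose(cvt.values.to_numpy(), expected, rtol=0.2)

    def test_missing_metadata_rejected(self):
        table = SampleTable(pd.DataFrame([[1.0]], columns=["x"]), "concentration")
        with pytest.raises(ValueError, match="timepoint"):
            cv_table(table)


class TestAggregateCV:
    def test_published_metabolite_row_and_column_means(self):
        cells = load_published_cv("cv_metabolites.tsv")
        agg = aggregate_cv(CVTable(cells, "HPLC"))
        assert agg["row_means"][12] == pytest.approx(0.240554143, abs=1e-5)
        assert agg["column_means"]["GLUCOSE"] == pytest.approx(0.240954, abs=1e-5)

    def test_published_cytometry_column_means(self):
        cells = load_published_cv("cv_cellscanner_rel.tsv")
        agg = aggregate_cv(CVTable(cells, "cellscanner_rel"))
        assert agg["column_means"]["RI"] == pytest.approx(0.149513, abs=1e-5)

    def test_exclusion_list_reproduces_reduced_averages(self):
        cells = load_published_cv("cv_seq_rel.tsv")
        agg = aggregate_cv(CVTable(cells, "seq"), exclude=["PC", "Pseudomonas"])
        assert agg["row_means"][12] == pytest.approx(0.256702699, abs=1e-5)
        assert agg["row_means"][61] == pytest.approx(0.098539223, abs=1e-5)

    def test_single_cell_table(self):
        table = CVTable(pd.DataFrame([[0.3]], index=[12], columns=["x"]))
        agg = aggregate_cv(table)
        assert agg["row_means"][12] == 0.3
        assert agg["column_means"]["x"] == 0.3
        assert agg["grand_mean"] == 0.3


class TestPairedWilcoxon:
    def test_six_positive_pairs_exact(self):
        res = paired_wilcoxon([2, 3, 4, 5, 6, 7], [1, 1, 1, 1, 1, 1])
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(2 / 64)

    def test_identical_vectors_give_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            res = paired_wilcoxon([1.0, 2.0], [1.0, 2.0])
        assert res["p"] == 1.0

    def test_tied_magnitudes_match_enumeration(self):
        # d = (+1, +2, +3, +4, -1): |d| ties at 1 -> midranks 1.5, 1.5
        a = np.array([2.0, 3.0, 4.0, 5.0, 1.0])
        b = np.array([1.0, 1.0, 1.0, 1.0, 2.0])
        res = paired_wilcoxon(a, b)
        assert res["w_minus"] == pytest.approx(1.5)
        assert res["p"] == pytest.approx(enumerate_wilcoxon(a - b, "two-sided"))
        assert res["p"] == pytest.approx(6 / 32)

    def test_tie_free_low_rank_case(self):
        # d with distinct magnitudes and a single smallest negative: p = 0.125
        a = np.array([2.0, 3.0, 4.0, 5.0, 1.0])
        b = np.array([1.0, 1.0, 1.0, 1.0, 1.5])
        res = paired_wilcoxon(a, b)
        assert res["w_minus"] == 1.0
        assert res["p"] == pytest.approx(0.125)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_exact_p_equals_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d = np.round(rng.normal(0.3, 1.0, size=n), 1)
        a, b = d, np.zeros(n)
        for alt in ("two-sided", "greater", "less"):
            res = paired_wilcoxon(a, b, alternative=alt)
            if res["method"] == "exact":
                assert res["p"] == pytest.approx(enumerate_wilcoxon(d, alt))

    def test_pratt_keeps_zero_ranks(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 5.0])
        b = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 5.0])
        res_w = paired_wilcoxon(a, b, zero_method="wilcox")
        res_p = paired_wilcoxon(a, b, zero_method="pratt")
        assert res_p["w_plus"] > res_w["w_plus"]  # zeros occupy the low ranks

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 1.0, size=40)
        b = rng.normal(0.0, 1.0, size=40)
        res = paired_wilcoxon(a, b, alternative="greater")
        assert res["method"] == "normal-approx"
        assert res["p"] < 0.01


class TestCompareMethods:
    def _cv(self, values, method):
        return CVTable(
            pd.DataFrame(values, index=[12, 25, 37, 49], columns=list("abcdef")),
            method,
        )

    def test_doubled_cvs_are_detected_one_sided(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.05, 0.5, size=(4, 6))
        res = compare_methods_cv(self._cv(2 * base, "a"), self._cv(base, "b"))
        assert res["n_cells"] == 24
        assert res["p_greater"] < 1e-4
        assert res["mean_cv_ratio"] == pytest.approx(2.0)

    def test_equal_tables_give_p_one(self):
        base = np.full((4, 6), 0.2)
        with pytest.warns(UserWarning, match="zero"):
            res = compare_methods_cv(self._cv(base, "a"), self._cv(base, "b"))
        assert res["p_two_sided"] == 1.0

    def test_too_few_shared_cells_rejected(self):
        a = CVTable(pd.DataFrame([[0.1]], index=[12], columns=["x"]))
        with pytest.raises(ValueError, match=">= 5"):
            compare_methods_cv(a, a)


class TestHeterogeneity:
    def test_identical_events_give_zero(self):
        ev = EventTable(DEFAULT_CHANNELS, np.ones((10, 23)))
        assert heterogeneity(ev).value == 0.0

    def test_single_varying_channel(self):
        values = np.ones((5, 23))
        values[:, 3] = [1, 2, 3, 4, 5]
        ev = EventTable(DEFAULT_CHANNELS, values)
        assert heterogeneity(ev, "mean").value == pytest.approx(4 / 23)
        assert heterogeneity(ev, "sum").value == pytest.approx(4.0)

    def test_sum_is_mean_times_channel_count(self):
        rng = np.random.default_rng(2)
        ev = EventTable(DEFAULT_CHANNELS, rng.uniform(0, 10, size=(50, 23)))
        assert heterogeneity(ev, "sum").value == pytest.approx(
            23 * heterogeneity(ev, "mean").value
        )

    def test_translation_invariant_and_scales_linearly(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(1, 10, size=(30, 23))
        ev = EventTable(DEFAULT_CHANNELS, base)
        shifted = EventTable(DEFAULT_CHANNELS, base + 100.0)
        scaled = EventTable(DEFAULT_CHANNELS, base * 3.0)
        h0 = heterogeneity(ev).value
        assert heterogeneity(shifted).value == pytest.approx(h0)
        assert heterogeneity(scaled).value == pytest.approx(3 * h0)

    def test_empty_is_missing(self):
        ev = EventTable(DEFAULT_CHANNELS, np.empty((0, 23)))
        with pytest.warns(UserWarning, match="no events"):
            assert np.isnan(heterogeneity(ev).value)


class TestMethodCorrelation:
    def test_proportional_series(self):
        x = np.arange(1.0, 11.0)
        assert method_correlation(x, 2 * x)["r"] == pytest.approx(1.0)
        assert method_correlation(x, -x)["r"] == pytest.approx(-1.0)

    def test_constant_series_is_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            res = method_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res["r"])

    def test_null_rejection_rate_matches_alpha(self):
        # critical |r| at alpha = 0.05, n = 36 is about 0.329
        rng = np.random.default_rng(8)
        n, reps, hits = 36, 1000, 0
        for _ in range(reps):
            res = method_correlation(
                rng.normal(size=n), rng.normal(size=n), "pearson"
            )
            hits += res["p"] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)
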