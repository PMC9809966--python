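"""Gating, the vote-threshold ensemble, and in-silico community evaluation."""

import numpy as np
import pytest

from gutvar.channels import ChannelSet
from gutvar.classify import (
    UNKNOWN_LABEL,
    apply_gate,
    assemble_in_silico_community,
    classify_events,
    evaluate_ensemble,
    fit_gate,
    fit_species_ensemble,
    labels_from_votes,
    split_train_test,
    threshold_gate,
)
from gutvar.io import EventTable, SampleMeta
from gutvar.synthetic import simulate_events


def brute_force_votes(votes_row, classes, threshold):
    """Reference vote rule: count votes per species, apply the >= rule."""
    best = max(votes_row)
    winners = [c for c, v in zip(classes, votes_row) if v == best]
    if best >= threshold and len(winners) == 1:
        return winners[0]
    return UNKNOWN_LABEL


class TestThresholdGate:
    def test_keeps_events_strictly_above_threshold(self):
        cs = ChannelSet(("FL1-A", "FSC-A"))
        ev = EventTable(cs, np.array([[4000.0, 1], [3000.0, 1], [5000.0, 1]]))
        gated = threshold_gate(ev, "FL1-A", 3.5e3)
        assert gated.n_events == 2
        np.testing.assert_array_equal(gated.channel_values("FL1-A"), [4000, 5000])

    def test_empty_and_zero_threshold(self):
        cs = ChannelSet(("FL1-A",))
        empty = EventTable(cs, np.empty((0, 1)))
        assert threshold_gate(empty).n_events == 0
        ev = EventTable(cs, np.array([[1.0], [2.0]]))
        assert threshold_gate(ev, "FL1-A", 0.0).n_events == 2

    def test_unknown_channel_raises(self):
        ev = EventTable(ChannelSet(("FSC-A",)), np.ones((3, 1)))
        with pytest.raises(KeyError, match="FL1-A"):
            threshold_gate(ev, "FL1-A")


class TestSplitRule:
    @pytest.mark.parametrize(
        "n,expected",
        [(5000, (4286, 714)), (7, (6, 1)), (14, (12, 2)), (6, (5, 1))],
    )
    def test_one_seventh_held_out(self, n, expected):
        assert split_train_test(n) == expected

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(1)


class TestMachineGate:
    def test_separable_fixture_gates_cleanly(self, monocultures, blank):
        gate = fit_gate(monocultures["RI"], blank, seed=7, n_estimators=20)
        assert len(gate.members_) == 6
        assert (gate.member_accuracy_ > 0.99).all()
        kept_cells = apply_gate(gate, monocultures["RI"]).n_events
        kept_blank = apply_gate(gate, blank).n_events
        assert kept_cells >= 0.95 * monocultures["RI"].n_events
        assert kept_blank <= 0.05 * blank.n_events

    def test_identical_distributions_are_chance_level(self, panel):
        a, _ = simulate_events(panel, {"RI": 1e8}, 0.0, 2000, seed=1)
        b, _ = simulate_events(panel, {"RI": 1e8}, 0.0, 2000, seed=2)
        gate = fit_gate(a, b, seed=3, n_estimators=20)
        assert gate.member_accuracy_.mean() == pytest.approx(0.5, abs=0.05)

    def test_single_member_gate(self, monocultures, blank):
        gate = fit_gate(monocultures["BH"], blank, n_members=1, seed=1,
                        n_estimators=10)
        assert len(gate.members_) == 1
        assert apply_gate(gate, blank, min_votes=1).n_events <= 0.05 * blank.n_events

    def test_channel_mismatch_rejected(self, monocultures, blank):
        gate = fit_gate(monocultures["RI"], blank, seed=1, n_estimators=5)
        other = EventTable(ChannelSet(("X", "Y")), np.ones((2, 2)))
        with pytest.raises(ValueError, match="channel"):
            apply_gate(gate, other)

    def test_empty_input_passes_through(self, monocultures, blank):
        gate = fit_gate(monocultures["RI"], blank, seed=1, n_estimators=5)
        empty = EventTable(monocultures["RI"].channels,
                           np.empty((0, len(monocultures["RI"].channels))))
        assert apply_gate(gate, empty).n_events == 0


@pytest.fixture(scope="module")
def small_ensemble(monocultures):
    return fit_species_ensemble(
        monocultures, n_members=10, n_events=1000, seed=42, n_estimators=20
    )


class TestSpeciesEnsemble:
    def test_members_and_heldout_accuracy(self, small_ensemble):
        assert len(small_ensemble.members_) == 10
        assert small_ensemble.train_size_per_species_ == 858
        assert small_ensemble.test_size_per_species_ == 142
        assert (small_ensemble.member_accuracy_ > 0.95).all()

    def test_single_species_rejected(self, monocultures):
        with pytest.raises(ValueError, match="2 species"):
            fit_species_ensemble({"RI": monocultures["RI"]}, seed=1)

    def test_identical_species_distributions_confuse_members(self, panel):
        a, _ = simulate_events(panel, {"RI": 1e8}, 0.0, 1500, seed=1)
        b, _ = simulate_events(panel, {"RI": 1e8}, 0.0, 1500, seed=2)
        monos = {
            "X": EventTable(a.channels, a.values, SampleMeta(sample_id="X")),
            "Y": EventTable(b.channels, b.values, SampleMeta(sample_id="Y")),
        }
        ens = fit_species_ensemble(monos, n_members=4, vote_threshold=3,
                                   n_events=800, seed=3, n_estimators=10)
        assert ens.member_accuracy_.mean() == pytest.approx(0.5, abs=0.07)

    def test_fixed_seed_is_bit_reproducible(self, monocultures):
        kwargs = dict(n_members=3, vote_threshold=2, n_events=500, seed=9,
                      n_estimators=10)
        e1 = fit_species_ensemble(monocultures, **kwargs)
        e2 = fit_species_ensemble(monocultures, **kwargs)
        X = monocultures["BT"].values[:200]
        np.testing.assert_array_equal(e1.predict(X), e2.predict(X))
        np.testing.assert_array_equal(e1.member_accuracy_, e2.member_accuracy_)


class TestVoteRule:
    @pytest.mark.parametrize(
        "votes,expected",
        [({"BH": 7, "BT": 3}, "BH"), ({"BH": 6, "BT": 4}, UNKNOWN_LABEL),
         ({"RI": 10}, "RI")],
    )
    def test_agreement_rule_examples(self, votes, expected):
        classes = np.array(["BH", "BT", "CA", "RI"])
        row = np.array([[votes.get(c, 0) for c in classes]])
        assert labels_from_votes(row, classes, 7)[0] == expected

    def test_matches_brute_force_on_random_multisets(self):
        rng = np.random.default_rng(0)
        classes = np.array(["A", "B", "C", "D"])
        for threshold in (3, 5, 7, 10):
            votes = rng.multinomial(10, np.full(4, 0.25), size=500)
            got = labels_from_votes(votes, classes, threshold)
            want = [brute_force_votes(v, classes, threshold) for v in votes]
            np.testing.assert_array_equal(got, np.array(want, dtype=object))

    def test_low_threshold_tie_abstains(self):
        classes = np.array(["A", "B"])
        row = np.array([[5, 5]])
        assert labels_from_votes(row, classes, 5)[0] == UNKNOWN_LABEL

    def test_raising_threshold_never_decreases_unknowns(self, small_ensemble,
                                                        monocultures):
        comm, _ = assemble_in_silico_community(
            monocultures, {"RI": 0.25, "BH": 0.25, "BT": 0.25, "CA": 0.25},
            800, seed=5,
        )
        votes = small_ensemble.vote_matrix(comm.values)
        unknowns = [
            (labels_from_votes(votes, small_ensemble.classes_, t)
             == UNKNOWN_LABEL).sum()
            for t in range(1, 11)
        ]
        assert all(b >= a for a, b in zip(unknowns, unknowns[1:]))


class TestInSilicoCommunity:
    def test_single_species(self, monocultures):
        ev, truth = assemble_in_silico_community(
            monocultures, {"RI": 1.0}, 300, seed=1
        )
        assert ev.n_events == 300
        assert set(truth) == {"RI"}

    @pytest.mark.parametrize(
        "props,n,expected",
        [({"RI": 0.5, "BH": 0.5}, 1000, {"RI": 500, "BH": 500}),
         ({"RI": 0.4, "BH": 0.35, "BT": 0.25}, 1000,
          {"RI": 400, "BH": 350, "BT": 250})],
    )
    def test_quota_rounding(self, monocultures, props, n, expected):
        _, truth = assemble_in_silico_community(monocultures, props, n, seed=2)
        for sp, k in expected.items():
            assert (truth == sp).sum() == k

    def test_bad_proportions_rejected(self, monocultures):
        with pytest.raises(ValueError, match="sum"):
            assemble_in_silico_community(monocultures, {"RI": 0.7}, 100, seed=1)


class TestClassifyAndEvaluate:
    def test_counts_conserve_total(self, small_ensemble, monocultures):
        comm, _ = assemble_in_silico_community(
            monocultures, {"RI": 0.5, "BT": 0.5}, 600, seed=3
        )
        result = classify_events(small_ensemble, comm)
        assert sum(result.counts.values()) + result.unknown == 600

    def test_separable_community_recovered(self, small_ensemble, monocultures):
        props = {"RI": 0.25, "BH": 0.25, "BT": 0.25, "CA": 0.25}
        comm, truth = assemble_in_silico_community(monocultures, props, 1200, seed=4)
        res = evaluate_ensemble(small_ensemble, comm, truth)
        assert res["accuracy"] > 0.95
        assert res["confusion"].sum() == 1200
        # confusion rows sum to per-species truth counts
        for i, sp in enumerate(res["true_classes"]):
            assert res["confusion"][i].sum() == (truth == sp).sum()

    def test_untrained_species_is_not_silently_assigned_correctly(
        self, panel, monocultures
    ):
        trained = {sp: monocultures[sp] for sp in ("RI", "BH", "BT")}
        ens = fit_species_ensemble(trained, n_members=10, n_events=800, seed=6,
                                   n_estimators=15)
        ca, _ = simulate_events(panel, {"CA": 1e8}, 0.0, 400, seed=7)
        truth = np.repeat("CA", 400)
        res = evaluate_ensemble(ens, ca, truth)
        assert res["strict_accuracy"] == 0.0

    def test_truth_length_mismatch(self, small_ensemble, monocultures):
        comm, truth = assemble_in_silico_community(
            monocultures, {"RI": 1.0}, 100, seed=8
        )
        with pytest.raises(ValueError, match="labels"):
            evaluate_ensemble(small_ensemble, comm, truth[:50])
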