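"""Supervised classification of flow-cytometry events.

Two estimator families reproduce the classifier-based workflow for defined
communities:

* :class:`CellGateClassifier` — an ensemble of binary random forests trained
  on monoculture (cell) versus blank-vessel (debris) events; applied to raw
  data it replaces manual threshold gating.
* :class:`SpeciesVoteClassifier` — an ensemble of multiclass random forests
  trained on gated monocultures.  A community event is assigned to a species
  only when at least ``vote_threshold`` of the members agree; otherwise it is
  reported as ``"unknown"``.  The unknown class is the ensemble's abstention
  mechanism and is carried through all downstream abundance tables.

Both follow scikit-learn conventions (``fit``/``predict``, ``get_params``,
fitted attributes with trailing underscores) and compose with sklearn
model-selection tools.  The module-level functions (``fit_gate``,
``classify_events`` ...) are thin wrappers over the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .io import EventTable, SampleMeta

__all__ = [
    "CellGateClassifier",
    "SpeciesVoteClassifier",
    "ClassifiedCounts",
    "UNKNOWN_LABEL",
    "threshold_gate",
    "fit_gate",
    "apply_gate",
    "split_train_test",
    "fit_species_ensemble",
    "classify_events",
    "assemble_in_silico_community",
    "evaluate_ensemble",
]

UNKNOWN_LABEL = "unknown"

#: FL1-A gate separating SYBR-positive cells from medium background.
DEFAULT_GATE_CHANNEL = "FL1-A"
DEFAULT_GATE_THRESHOLD = 3.5e3


def threshold_gate(
    events: EventTable,
    channel: str = DEFAULT_GATE_CHANNEL,
    threshold: float = DEFAULT_GATE_THRESHOLD,
) -> EventTable:
    """Manual gating: keep events whose ``channel`` value exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    col = events.channel_values(channel)  # KeyError for unknown channel
    return events.take(col > threshold)


def split_train_test(n_events: int = 5000) -> tuple[int, int]:
    """Train/test partition rule: one seventh of the events held out.

    For the canonical 5000 events per gated monoculture this yields the
    4286-train / 714-test partition.
    """
    if n_events < 2:
        raise ValueError(f"need at least 2 events to split, got {n_events}")
    n_test = n_events // 7
    if n_test == 0:
        n_test = 1
    return n_events - n_test, n_test


def _member_seeds(random_state, n: int) -> list[int]:
    ss = np.random.SeedSequence(random_state)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


class CellGateClassifier(ClassifierMixin, BaseEstimator):
    """Ensemble gate: random forests voting cell vs. debris.

    Parameters
    ----------
    n_members : number of forests; members differ only by their
        resampling/held-out-split seed.
    min_votes : votes required to call an event a cell when predicting;
        ``None`` means majority (``ceil(n_members / 2)``).
    n_estimators, max_depth : forwarded to each random forest.
    """

    def __init__(
        self,
        n_members: int = 6,
        min_votes: int | None = None,
        n_estimators: int = 100,
        max_depth: int | None = None,
        random_state: int | None = None,
    ):
        self.n_members = n_members
        self.min_votes = min_votes
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(f"gate expects 2 classes, got {list(self.classes_)}")
        n = X.shape[0]
        n_train, _ = split_train_test(n)
        members, accuracies = [], []
        for seed in _member_seeds(self.random_state, self.n_members):
            rng = np.random.default_rng(seed)
            order = rng.permutation(n)
            tr, te = order[:n_train], order[n_train:]
            clf = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=seed,
            ).fit(X[tr], y[tr])
            members.append(clf)
            accuracies.append(float(clf.score(X[te], y[te])))
        self.members_ = members
        self.member_accuracy_ = np.asarray(accuracies)
        self.n_features_in_ = X.shape[1]
        self.training_counts_ = {
            str(c): int((y == c).sum()) for c in self.classes_
        }
        return self

    def vote_counts(self, X) -> np.ndarray:
        """Number of members voting 'cell' (the positive class) per event."""
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        positive = self.positive_class_
        votes = np.zeros(X.shape[0], dtype=int)
        for clf in self.members_:
            votes += clf.predict(X) == positive
        return votes

    @property
    def positive_class_(self):
        # 'cell' if labelled so, else the lexicographically first class
        check_is_fitted(self, "classes_")
        return "cell" if "cell" in self.classes_ else self.classes_[0]

    def predict(self, X):
        min_votes = self.min_votes
        if min_votes is None:
            min_votes = -(-self.n_members // 2)
        votes = self.vote_counts(X)
        positive = self.positive_class_
        negative = [c for c in self.classes_ if c != positive][0]
        return np.where(votes >= min_votes, positive, negative)


def fit_gate(
    monoculture: EventTable,
    blank: EventTable,
    n_members: int = 6,
    seed: int | None = None,
    **forest_kwargs,
) -> CellGateClassifier:
    """Train a machine gate from one monoculture and one blank acquisition."""
    if monoculture.n_events == 0 or blank.n_events == 0:
        raise ValueError("monoculture and blank must both contain events")
    if tuple(monoculture.channels) != tuple(blank.channels):
        raise ValueError("monoculture and blank channel sets differ")
    X = np.vstack([monoculture.values, blank.values])
    y = np.array(["cell"] * monoculture.n_events + ["debris"] * blank.n_events)
    gate = CellGateClassifier(n_members=n_members, random_state=seed, **forest_kwargs)
    gate.fit(X, y)
    gate.channels_ = tuple(monoculture.channels)
    return gate


def apply_gate(
    gate: CellGateClassifier, events: EventTable, min_votes: int | None = None
) -> EventTable:
    """Retain events voted 'cell' by at least ``min_votes`` members (default majority)."""
    if hasattr(gate, "channels_") and tuple(events.channels) != gate.channels_:
        raise ValueError("event channels do not match the gate's training channels")
    if events.n_events == 0:
        return events
    if min_votes is None:
        min_votes = -(-gate.n_members // 2)
    votes = gate.vote_counts(events.values)
    return events.take(votes >= min_votes)


@dataclass
class ClassifiedCounts:
    """Per-species event counts for one community sample, plus unknowns."""

    counts: dict[str, int]
    unknown: int
    meta: SampleMeta = field(default_factory=SampleMeta)
    labels: np.ndarray | None = None  # optional per-event label vector

    def __post_init__(self) -> None:
        if self.unknown < 0 or any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unknown


class SpeciesVoteClassifier(ClassifierMixin, BaseEstimator):
    """Vote-threshold species ensemble with an unknown class.

    Each member is a multiclass random forest trained on its own random
    sample of ``n_events`` events per species (drawn from the gated
    monoculture pool handed to :meth:`fit`), split into train and held-out
    test portions by the one-seventh rule.  Prediction assigns the modal
    species when it gathers at least ``vote_threshold`` of the
    ``n_members`` votes and abstains (``"unknown"``) otherwise.  For
    thresholds at or below half the membership a tie between two modal
    species also abstains.
    """

    def __init__(
        self,
        n_members: int = 10,
        vote_threshold: int = 7,
        n_events: int = 5000,
        n_estimators: int = 100,
        max_depth: int | None = None,
        random_state: int | None = None,
    ):
        self.n_members = n_members
        self.vote_threshold = vote_threshold
        self.n_events = n_events
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def _check_params(self):
        if not 1 <= self.vote_threshold <= self.n_members:
            raise ValueError(
                f"vote_threshold must be in [1, {self.n_members}], "
                f"got {self.vote_threshold}"
            )

    def fit(self, X, y):
        self._check_params()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("species classification needs at least 2 species")
        pools = {c: np.flatnonzero(y == c) for c in classes}
        n_train, n_test = split_train_test(self.n_events)
        members, accuracies = [], []
        for seed in _member_seeds(self.random_state, self.n_members):
            rng = np.random.default_rng(seed)
            tr_idx, te_idx = [], []
            for c in classes:
                pool = pools[c]
                # sample without replacement when the pool allows it
                chosen = rng.choice(
                    pool, size=self.n_events, replace=pool.size < self.n_events
                )
                tr_idx.append(chosen[:n_train])
                te_idx.append(chosen[n_train:])
            tr = np.concatenate(tr_idx)
            te = np.concatenate(te_idx)
            clf = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=seed,
            ).fit(X[tr], y[tr])
            members.append(clf)
            accuracies.append(float(clf.score(X[te], y[te])))
        self.classes_ = classes
        self.members_ = members
        self.member_accuracy_ = np.asarray(accuracies)
        self.n_features_in_ = X.shape[1]
        self.train_size_per_species_ = n_train
        self.test_size_per_species_ = n_test
        return self

    def vote_matrix(self, X) -> np.ndarray:
        """Events x species matrix of member votes (rows sum to n_members)."""
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        index = {c: j for j, c in enumerate(self.classes_)}
        votes = np.zeros((X.shape[0], self.classes_.size), dtype=int)
        rows = np.arange(X.shape[0])
        for clf in self.members_:
            pred = clf.predict(X)
            cols = np.fromiter((index[p] for p in pred), dtype=int, count=pred.size)
            votes[rows, cols] += 1
        return votes

    def predict(self, X):
        votes = self.vote_matrix(X)
        return labels_from_votes(votes, self.classes_, self.vote_threshold)


def labels_from_votes(
    votes: np.ndarray, classes: np.ndarray, vote_threshold: int
) -> np.ndarray:
    """Apply the agreement rule to a precomputed events x species vote matrix."""
    top = votes.max(axis=1)
    winner = votes.argmax(axis=1)
    tied = (votes == top[:, None]).sum(axis=1) > 1
    labels = np.asarray(classes, dtype=object)[winner]
    labels[(top < vote_threshold) | tied] = UNKNOWN_LABEL
    return labels.astype(object)


def fit_species_ensemble(
    gated_monocultures: dict[str, EventTable],
    n_members: int = 10,
    n_events: int = 5000,
    seed: int | None = None,
    vote_threshold: int = 7,
    **forest_kwargs,
) -> SpeciesVoteClassifier:
    """Train the vote ensemble from per-species gated monoculture events."""
    if len(gated_monocultures) < 2:
        raise ValueError("need monocultures for at least 2 species")
    channel_sets = {tuple(ev.channels) for ev in gated_monocultures.values()}
    if len(channel_sets) != 1:
        raise ValueError("monocultures have inconsistent channel sets")
    X = np.vstack([ev.values for ev in gated_monocultures.values()])
    y = np.concatenate(
        [np.repeat(sp, ev.n_events) for sp, ev in gated_monocultures.items()]
    )
    ens = SpeciesVoteClassifier(
        n_members=n_members,
        vote_threshold=vote_threshold,
        n_events=n_events,
        random_state=seed,
        **forest_kwargs,
    ).fit(X, y)
    ens.channels_ = channel_sets.pop()
    return ens


def classify_events(
    ensemble: SpeciesVoteClassifier,
    community: EventTable,
    keep_labels: bool = True,
) -> ClassifiedCounts:
    """Classify community events; non-agreeing events become ``unknown``."""
    if hasattr(ensemble, "channels_") and tuple(community.channels) != ensemble.channels_:
        raise ValueError("community channels do not match the ensemble's")
    if community.n_events == 0:
        counts = {str(c): 0 for c in ensemble.classes_}
        return ClassifiedCounts(counts, 0, replace(community.meta))
    labels = ensemble.predict(community.values)
    counts = {str(c): int((labels == c).sum()) for c in ensemble.classes_}
    unknown = int((labels == UNKNOWN_LABEL).sum())
    return ClassifiedCounts(
        counts, unknown, replace(community.meta), labels if keep_labels else None
    )


def assemble_in_silico_community(
    gated_monocultures: dict[str, EventTable],
    proportions: dict[str, float],
    n_events: int,
    seed: int | None = None,
) -> tuple[EventTable, np.ndarray]:
    """Mix monoculture events at known proportions; return events and truth.

    Each species contributes ``floor(p_s * n_events)`` events, with the
    remainder assigned to the species of largest proportion; events are then
    shuffled so ordering carries no label information.
    """
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total:.12g}, expected 1")
    missing = set(proportions) - set(gated_monocultures)
    if missing:
        raise ValueError(f"no monoculture events for {sorted(missing)}")
    rng = np.random.default_rng(seed)
    quotas = {sp: int(np.floor(p * n_events)) for sp, p in proportions.items()}
    leftover = n_events - sum(quotas.values())
    if leftover:
        largest = max(proportions, key=lambda sp: (proportions[sp], sp))
        quotas[largest] += leftover
    chunks, labels = [], []
    channels = None
    for sp in sorted(quotas):
        ev = gated_monocultures[sp]
        channels = channels or ev.channels
        k = quotas[sp]
        idx = rng.choice(ev.n_events, size=k, replace=ev.n_events < k)
        chunks.append(ev.values[idx])
        labels.append(np.repeat(sp, k))
    values = np.vstack(chunks)
    truth = np.concatenate(labels)
    order = rng.permutation(n_events)
    meta = SampleMeta(sample_id="in_silico", role="community")
    return EventTable(channels, values[order], meta), truth[order]


def evaluate_ensemble(
    ensemble: SpeciesVoteClassifier,
    community: EventTable,
    truth: np.ndarray,
) -> dict:
    """Score an ensemble against hidden truth labels.

    ``accuracy`` excludes abstentions from the denominator; ``strict_accuracy``
    counts every unknown as an error.  The confusion matrix has one row per
    true species and one column per predicted species plus ``unknown``.
    """
    truth = np.asarray(truth)
    if truth.shape[0] != community.n_events:
        raise ValueError(
            f"truth has {truth.shape[0]} labels for {community.n_events} events"
        )
    labels = classify_events(ensemble, community).labels
    known = labels != UNKNOWN_LABEL
    correct = (labels == truth) & known
    n_known = int(known.sum())
    accuracy = float(correct.sum() / n_known) if n_known else float("nan")
    strict = float(correct.sum() / truth.shape[0])
    species = list(dict.fromkeys(list(ensemble.classes_) + sorted(set(truth))))
    pred_classes = species + [UNKNOWN_LABEL]
    confusion = np.zeros((len(species), len(pred_classes)), dtype=int)
    for i, t in enumerate(species):
        mask = truth == t
        for j, p in enumerate(pred_classes):
            confusion[i, j] = int((labels[mask] == p).sum())
    return {
        "accuracy": accuracy,
        "strict_accuracy": strict,
        "unknown_fraction": float((~known).sum() / truth.shape[0]),
        "confusion": confusion,
        "true_classes": species,
        "predicted_classes": pred_classes,
    }
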