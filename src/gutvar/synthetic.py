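"""Synthetic data with the statistical structure of the bioreactor study.

The generator emulates a defined gut bacterial community grown in six
parallel emulated-chemostat vessels: 12 h of batch growth, then continuous
feed at dilution rate D = 1/24 h⁻¹, sampled at 12, 25, 37, 49, 61 and 67 h.
It produces

* per-species multivariate log-normal event clouds over the 23 cytometry
  channels, plus a debris/blank population (``make_species_panel``,
  ``simulate_events``);
* vessel time series of true cell densities with per-vessel biological
  noise, including washout (exponential decay at rate D) of species that do
  not grow in chemostat mode (``simulate_timeseries``);
* triplicate 16S count tables with multiplicative technical noise larger
  than the vessel-to-vessel noise, the second and third replicate sharing a
  batch-effect component (``simulate_16s``);
* two-phase metabolite trajectories (``simulate_metabolites``).

Every function is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .channels import ChannelSet, DEFAULT_CHANNELS
from .io import EventTable, SampleMeta, SampleTable

__all__ = [
    "SpeciesPanel",
    "SpeciesTrajectory",
    "TrajectoryConfig",
    "GroundTruth",
    "make_species_panel",
    "simulate_events",
    "simulate_timeseries",
    "simulate_16s",
    "simulate_metabolites",
    "monoculture_event_tables",
    "blank_event_table",
    "community_event_tables",
    "default_trajectory_config",
    "DEFAULT_SPECIES",
]

DEBRIS_LABEL = "debris"

#: Abbreviated names of the study's community members (panel default order).
DEFAULT_SPECIES = ("RI", "BH", "BT", "CA")

DEFAULT_TIMEPOINTS = (12.0, 25.0, 37.0, 49.0, 61.0, 67.0)

_FL_CHANNELS = tuple(
    n for n in DEFAULT_CHANNELS if n.startswith(("FL", "APC", "KO", "mCherry", "PI"))
)


@dataclass
class SpeciesPanel:
    """Log-normal event-cloud parameters for each species and for debris.

    Channel values are ``exp(N(mu, sigma))`` per channel (diagonal covariance
    on the log scale), so they are strictly positive and right-skewed like
    real cytometry data.  ``separation`` is the pairwise Mahalanobis distance
    between species means in the log space whitened by the base covariance;
    species additionally differ in spread (per-species sigma vectors).
    """

    channels: ChannelSet
    means: dict[str, np.ndarray]  # species -> log-scale mean vector
    sigmas: dict[str, np.ndarray]  # species -> log-scale SD per channel
    debris_mean: np.ndarray
    debris_sigma: np.ndarray
    separation: float

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.means)

    def sample(self, label: str, n: int, rng: np.random.Generator) -> np.ndarray:
        if label == DEBRIS_LABEL:
            mu, sd = self.debris_mean, self.debris_sigma
        else:
            mu, sd = self.means[label], self.sigmas[label]
        return np.exp(rng.normal(mu, sd, size=(n, len(self.channels))))


def make_species_panel(
    n_species: int = 4,
    separation: float = 4.0,
    seed: int | None = None,
    species_names: tuple[str, ...] | None = None,
    channels: ChannelSet = DEFAULT_CHANNELS,
    sigma: float = 0.35,
    anchor_tightening: float = 0.6,
) -> SpeciesPanel:
    """Place species event clouds at a controlled pairwise separation.

    Species log-means sit at the vertices of a regular simplex spanned by
    the first ``n_species`` channel axes, so every pair of species is at
    Mahalanobis distance ``separation`` with respect to the base covariance.
    Species also differ in spread: each is tighter (factor
    ``anchor_tightening`` at separation 4, interpolating to 1 at separation
    0) on its own anchor channel, the way real species differ in the width
    of particular scatter/fluorescence parameters.  The default separation
    of 4 gives a two-class Bayes error of about Phi(-2) = 0.023 (the
    "separable fixture" used by the classifier tests).

    The stained-cell base cloud keeps FL1-A well above the 3.5e3 manual
    gate while debris sits well below it.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be positive (non-degenerate covariance)")
    if not 0 < anchor_tightening <= 1:
        raise ValueError("anchor_tightening must be in (0, 1]")
    if species_names is None:
        if n_species <= len(DEFAULT_SPECIES):
            species_names = DEFAULT_SPECIES[:n_species]
        else:
            species_names = tuple(f"S{i + 1}" for i in range(n_species))
    if len(species_names) != n_species:
        raise ValueError("species_names length must equal n_species")
    rng = np.random.default_rng(seed)  # reserved for future stochastic layout
    del rng
    p = len(channels)
    k = n_species
    if k > p:
        raise ValueError(f"at most {p} species fit on {p} channels")
    # base log-means: bright stained cells; ln(5e4) ~ 10.8 on FL channels
    base = np.full(p, np.log(2.0e4))
    fl_idx = [channels.index(c) for c in _FL_CHANNELS if c in channels]
    base[fl_idx] = np.log(5.0e4)
    base_sigma = np.full(p, sigma)

    # regular simplex with pairwise distance `separation`, on channel axes
    verts = np.eye(k) * (separation / np.sqrt(2.0))
    verts -= verts.mean(axis=0)
    means, sigmas = {}, {}
    tighten = 1.0 - (1.0 - anchor_tightening) * min(separation / 4.0, 1.0)
    for i, name in enumerate(species_names):
        mu = base.copy()
        mu[:k] += base_sigma[:k] * verts[i]
        sd = base_sigma.copy()
        sd[i] *= tighten  # species-specific spread on its anchor channel
        means[name] = mu
        sigmas[name] = sd
    debris_mean = base.copy()
    debris_mean[fl_idx] = np.log(4.0e2)  # unstained background, below the gate
    debris_mean[~np.isin(np.arange(p), fl_idx)] = np.log(2.0e3)
    debris_sigma = np.full(p, 0.6)
    return SpeciesPanel(
        channels, means, sigmas, debris_mean, debris_sigma, separation
    )


def simulate_events(
    panel: SpeciesPanel,
    composition: dict[str, float],
    debris_fraction: float = 0.0,
    n_events: int = 10_000,
    dilution_factor: float = 100.0,
    volume_ul: float | None = None,
    seed: int | None = None,
    meta: SampleMeta | None = None,
) -> tuple[EventTable, np.ndarray]:
    """Draw one acquisition: events from species clouds plus debris.

    ``composition`` maps species to true densities (cells/ml); event labels
    are drawn with probability proportional to density.  When ``volume_ul``
    is not given it is derived so that the volumetric count of the cell
    events recovers the total density in expectation.
    """
    densities = {sp: float(v) for sp, v in composition.items()}
    if any(v < 0 for v in densities.values()):
        raise ValueError("densities must be >= 0")
    total = sum(densities.values())
    if not 0 <= debris_fraction < 1:
        raise ValueError("debris_fraction must be in [0, 1)")
    if total == 0 and debris_fraction == 0:
        raise ValueError("nothing to sample: all densities zero and no debris")
    rng = np.random.default_rng(seed)
    species = [sp for sp in panel.species if densities.get(sp, 0) > 0]
    probs = np.array([densities[sp] for sp in species], dtype=float)
    labels_pool = species + [DEBRIS_LABEL]
    if total > 0:
        p_vec = np.append(probs / probs.sum() * (1 - debris_fraction), debris_fraction)
    else:
        p_vec = np.append(np.zeros(len(species)), 1.0)
    counts = rng.multinomial(n_events, p_vec)
    chunks, labels = [], []
    for lab, k in zip(labels_pool, counts):
        if k:
            chunks.append(panel.sample(lab, int(k), rng))
            labels.append(np.repeat(lab, k))
    values = np.vstack(chunks) if chunks else np.empty((0, len(panel.channels)))
    truth = np.concatenate(labels) if labels else np.empty(0, dtype=object)
    order = rng.permutation(n_events)
    values, truth = values[order], truth[order]

    n_cells_expected = n_events * (1 - debris_fraction)
    if volume_ul is None:
        if total > 0:
            volume_ul = n_cells_expected * dilution_factor * 1000.0 / total
        else:
            volume_ul = 20.0
    meta = replace(meta) if meta is not None else SampleMeta(sample_id="sim")
    meta.dilution_factor = dilution_factor
    meta.acquired_volume_ul = volume_ul
    return EventTable(panel.channels, values, meta), truth.astype(object)


@dataclass
class SpeciesTrajectory:
    """Phenomenological growth parameters for one species.

    ``initial_density`` (cells/ml) grows exponentially at ``batch_rate``
    (1/h) until the feed starts; in chemostat mode the density relaxes
    exponentially, at the dilution rate, toward ``steady_state``.  A species
    that cannot grow under the feed has ``steady_state = 0`` and washes out
    as exp(-D (t - t_batch)).
    """

    initial_density: float
    batch_rate: float
    steady_state: float


@dataclass
class TrajectoryConfig:
    """All generator parameters for one simulated experiment."""

    species: dict[str, SpeciesTrajectory]
    dilution_rate: float = 1.0 / 24.0  # h^-1; full medium changeover in 24 h
    batch_hours: float = 12.0
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_vessels: int = 6
    sigma_bio: float = 0.15  # log-scale vessel-to-vessel noise
    sigma_tech: float = 0.5  # log-scale per-replicate 16S technical noise
    n_tech: int = 3
    depth: int = 10_000  # reads per 16S library
    copy_numbers: dict[str, float] = field(default_factory=dict)
    contaminant: str | None = None  # optional taxon spiked into >= 2 samples
    contaminant_reads: int = 25
    metabolite_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate must be > 0")
        if self.sigma_bio < 0 or self.sigma_tech < 0:
            raise ValueError("noise scales must be >= 0")
        if self.depth < 1000:
            raise ValueError("sequencing depth must be >= 1000")
        if not self.copy_numbers:
            self.copy_numbers = {sp: c for sp, c in
                                 zip(self.species, (6.0, 4.0, 5.0, 3.0, 2.0, 7.0))}


def default_trajectory_config(**overrides) -> TrajectoryConfig:
    """The study conditions: 6 vessels, 6 timepoints, 4 species.

    BT dominates the batch phase then declines in chemostat mode, BH rises,
    RI and CA stay comparatively level — the qualitative succession the
    community showed.
    """
    species = {
        "RI": SpeciesTrajectory(2.0e6, 0.30, 1.0e8),
        "BH": SpeciesTrajectory(2.0e6, 0.25, 3.0e8),
        "BT": SpeciesTrajectory(4.0e6, 0.45, 1.0e8),
        "CA": SpeciesTrajectory(2.0e6, 0.30, 8.0e7),
    }
    cfg = TrajectoryConfig(species=species)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class GroundTruth:
    """True per-vessel, per-timepoint state of a simulated experiment."""

    densities: pd.DataFrame  # index: (vessel, timepoint); columns: species
    config: TrajectoryConfig

    @property
    def sample_ids(self) -> list[str]:
        return [sample_id(v, t) for v, t in self.densities.index]

    def totals(self) -> pd.Series:
        """Total community density (cells/ml) per sample."""
        tot = self.densities.sum(axis=1)
        tot.index = pd.Index(self.sample_ids, name="sample_id")
        return tot

    def relative(self) -> pd.DataFrame:
        rel = self.densities.div(self.densities.sum(axis=1), axis=0)
        rel.index = pd.Index(self.sample_ids, name="sample_id")
        return rel


def sample_id(vessel: str, timepoint: float) -> str:
    t = int(timepoint) if float(timepoint).is_integer() else timepoint
    return f"{vessel}_t{t}"


def _meta_frame(index: pd.MultiIndex) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "vessel": [v for v, _ in index],
            "timepoint": [t for _, t in index],
        },
        index=pd.Index([sample_id(v, t) for v, t in index], name="sample_id"),
    )
    return meta


def _deterministic_density(tr: SpeciesTrajectory, t: float, cfg: TrajectoryConfig) -> float:
    tb = cfg.batch_hours
    if t <= tb:
        return tr.initial_density * np.exp(tr.batch_rate * t)
    x_switch = tr.initial_density * np.exp(tr.batch_rate * tb)
    decay = np.exp(-cfg.dilution_rate * (t - tb))
    return tr.steady_state + (x_switch - tr.steady_state) * decay


def simulate_timeseries(
    traj: TrajectoryConfig, n_vessels: int | None = None, seed: int | None = None
) -> GroundTruth:
    """Simulate true species densities for every vessel and timepoint.

    Batch phase: exponential growth.  Chemostat phase: exponential
    relaxation toward the per-species steady state at the dilution rate, so
    a non-growing species (steady state 0) washes out as exp(-D t).  Vessel
    individuality enters as an independent log-normal multiplier with scale
    ``sigma_bio`` on every density.
    """
    if n_vessels is None:
        n_vessels = traj.n_vessels
    rng = np.random.default_rng(seed)
    vessels = [f"V{i + 1}" for i in range(n_vessels)]
    index = pd.MultiIndex.from_product(
        [vessels, list(traj.timepoints)], names=["vessel", "timepoint"]
    )
    species = list(traj.species)
    base = np.array(
        [
            [_deterministic_density(traj.species[sp], t, traj) for sp in species]
            for _, t in index
        ]
    )
    noise = np.exp(rng.normal(0.0, traj.sigma_bio, size=base.shape)) \
        if traj.sigma_bio > 0 else 1.0
    densities = pd.DataFrame(base * noise, index=index, columns=species)
    return GroundTruth(densities, traj)


def simulate_16s(
    truth: GroundTruth,
    traj: TrajectoryConfig | None = None,
    n_tech: int | None = None,
    seed: int | None = None,
) -> list[SampleTable]:
    """Triplicate 16S count tables with dominant technical noise.

    The expected read share of a taxon is proportional to density times 16S
    copy number, perturbed per (replicate, sample, taxon) by a multiplicative
    log-normal factor of scale ``sigma_tech``.  Replicates 2 and 3 share a
    batch-effect component (half the technical variance), mimicking
    replicates processed together on one plate; replicate 1 is independent.
    Reads are multinomial at the configured depth.  An optional contaminant
    taxon is spiked into two or more samples of every replicate.
    """
    traj = traj or truth.config
    n_tech = n_tech if n_tech is not None else traj.n_tech
    rng = np.random.default_rng(seed)
    species = list(truth.densities.columns)
    copies = np.array([traj.copy_numbers[sp] for sp in species], dtype=float)
    dens = truth.densities.to_numpy()
    n_samples = dens.shape[0]
    meta = _meta_frame(truth.densities.index)

    shared = rng.normal(0.0, traj.sigma_tech / np.sqrt(2.0), size=dens.shape)
    tables = []
    for rep in range(1, n_tech + 1):
        if traj.sigma_tech == 0:
            eps = np.zeros(dens.shape)
        elif rep == 1:
            eps = rng.normal(0.0, traj.sigma_tech, size=dens.shape)
        else:
            eps = shared + rng.normal(
                0.0, traj.sigma_tech / np.sqrt(2.0), size=dens.shape
            )
        weights = dens * copies * np.exp(eps)
        counts = np.zeros_like(weights, dtype=int)
        for i in range(n_samples):
            w = weights[i]
            tot = w.sum()
            if tot > 0:
                counts[i] = rng.multinomial(traj.depth, w / tot)
        df = pd.DataFrame(counts, columns=species,
                          index=pd.Index(truth.sample_ids, name="sample_id"))
        if traj.contaminant:
            hit = rng.choice(n_samples, size=max(2, n_samples // 12), replace=False)
            df[traj.contaminant] = 0
            df.iloc[hit, df.columns.get_loc(traj.contaminant)] = traj.contaminant_reads
        rep_meta = meta.copy()
        rep_meta["replicate"] = rep
        tables.append(SampleTable(df, "counts", rep_meta))
    return tables


_METABOLITE_TEMPLATES: dict[str, tuple[str, float]] = {
    # name -> (template, plateau or initial concentration, arbitrary mM)
    "glucose": ("depleting", 6.0),
    "trehalose": ("depleting", 3.0),
    "pyruvic": ("two_phase", 2.0),
    "succinic": ("two_phase", 4.0),
    "lactic": ("two_phase", 3.0),
    "formic": ("two_phase", 5.0),
    "acetic": ("rising", 20.0),
    "propionic": ("rising", 4.0),
    "butyric": ("rising", 6.0),
    "iso-valeric": ("rising", 1.5),
}


def _metabolite_curve(template: str, scale: float, t: np.ndarray) -> np.ndarray:
    if template == "depleting":
        # consumed during batch growth; essentially gone by 12 h
        return scale * np.exp(-0.25 * t)
    if template == "rising":
        # fermentation end product accumulating to a plateau
        return scale * (1.0 - np.exp(-0.12 * t))
    if template == "two_phase":
        # intermediate: produced in batch, then consumed / diluted to a plateau
        rise = 1.0 - np.exp(-0.15 * t)
        fall = 0.2 + 0.8 * np.exp(-0.08 * np.maximum(t - 18.0, 0.0))
        return scale * rise * fall
    raise ValueError(f"unknown metabolite template {template!r}")


def simulate_metabolites(
    traj: TrajectoryConfig, seed: int | None = None
) -> SampleTable:
    """Per-vessel metabolite concentration table (mM) over the timepoints.

    Three trajectory shapes: batch-depleted sugars, end products rising to a
    plateau, and two-phase intermediates that peak around the batch-to-
    chemostat switch and then decay toward a lower plateau.  Vessel noise is
    a log-normal multiplier of scale ``metabolite_sigma``.
    """
    rng = np.random.default_rng(seed)
    vessels = [f"V{i + 1}" for i in range(traj.n_vessels)]
    t = np.array(traj.timepoints, dtype=float)
    index = pd.MultiIndex.from_product(
        [vessels, list(traj.timepoints)], names=["vessel", "timepoint"]
    )
    cols = list(_METABOLITE_TEMPLATES)
    base = np.column_stack(
        [
            np.tile(_metabolite_curve(tmpl, scale, t), traj.n_vessels)
            for tmpl, scale in _METABOLITE_TEMPLATES.values()
        ]
    )
    if traj.metabolite_sigma > 0:
        base = base * np.exp(
            rng.normal(0.0, traj.metabolite_sigma, size=base.shape)
        )
    meta = _meta_frame(index)
    df = pd.DataFrame(base, columns=cols, index=meta.index)
    return SampleTable(df, "concentration", meta)


def blank_event_table(
    panel: SpeciesPanel, n_events: int = 5000, seed: int | None = None
) -> EventTable:
    """A blank-vessel acquisition: pure medium background (debris only)."""
    meta = SampleMeta(sample_id="blank", role="blank")
    ev, _ = simulate_events(
        panel, {}, debris_fraction=0.5, n_events=n_events, seed=seed, meta=meta
    )
    return ev


def monoculture_event_tables(
    panel: SpeciesPanel,
    n_events: int = 5000,
    seed: int | None = None,
    density: float = 1.0e8,
) -> dict[str, EventTable]:
    """Gated monoculture acquisitions (no debris), one per panel species."""
    ss = np.random.SeedSequence(seed).spawn(len(panel.species))
    out = {}
    for sp, child in zip(panel.species, ss):
        meta = SampleMeta(sample_id=f"mono_{sp}", role="monoculture", species=sp)
        ev, _ = simulate_events(
            panel, {sp: density}, 0.0, n_events,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)), meta=meta,
        )
        out[sp] = ev
    return out


def community_event_tables(
    panel: SpeciesPanel,
    truth: GroundTruth,
    n_events: int = 2000,
    debris_fraction: float = 0.0,
    dilution_factor: float = 100.0,
    seed: int | None = None,
) -> dict[str, tuple[EventTable, np.ndarray]]:
    """One community acquisition per (vessel, timepoint) of the ground truth."""
    index = truth.densities.index
    ss = np.random.SeedSequence(seed).spawn(len(index))
    out = {}
    for (vessel, tp), child in zip(index, ss):
        sid = sample_id(vessel, tp)
        comp = truth.densities.loc[(vessel, tp)].to_dict()
        meta = SampleMeta(sample_id=sid, vessel=vessel, timepoint=tp, role="community")
        ev, labels = simulate_events(
            panel, comp, debris_fraction, n_events, dilution_factor,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)), meta=meta,
        )
        out[sid] = (ev, labels)
    return out
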