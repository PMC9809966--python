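"""End-to-end orchestration: simulate -> classify -> abundances -> statistics.

One :class:`PipelineConfig` (optionally read from YAML) drives a full run.
All randomness flows from a single root seed through named substreams, so a
rerun with the same configuration is numerically identical.  Every run
writes a JSON manifest with the seed, per-file SHA-256 hashes and package
version, plus a human-readable markdown report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (
    classified_to_abundance,
    correct_copy_number,
    filter_contaminants,
    to_absolute,
    volumetric_count,
)
from .classify import classify_events, fit_species_ensemble, threshold_gate
from .io import SampleTable, write_table
from .ordination import bray_curtis, envfit, pcoa
from .synthetic import (
    GroundTruth,
    community_event_tables,
    default_trajectory_config,
    make_species_panel,
    monoculture_event_tables,
    simulate_16s,
    simulate_metabolites,
    simulate_timeseries,
)
from .variability import (
    aggregate_cv,
    compare_methods_cv,
    cv_table,
    heterogeneity,
)

logger = logging.getLogger("gutvar")

__all__ = ["PipelineConfig", "run_pipeline", "report", "sequencing_vs_cytometry_cv"]

_STAGES = (
    "panel", "timeseries", "sixteen_s", "metabolites",
    "monocultures", "communities", "ensemble", "envfit",
)


@dataclass
class PipelineConfig:
    """Everything a full synthetic-scenario run needs."""

    seed: int = 0
    out_dir: str = "gutvar_run"
    # generator scenario
    n_species: int = 4
    separation: float = 4.0
    n_vessels: int = 6
    sigma_bio: float = 0.15
    sigma_tech: float = 0.5
    n_tech: int = 3
    depth: int = 10_000
    community_events: int = 2000
    debris_fraction: float = 0.0
    dilution_factor: float = 100.0
    # classifier settings
    n_members: int = 10
    vote_threshold: int = 7
    train_events: int = 5000
    n_estimators: int = 50
    # statistics
    ddof: int = 1
    heterogeneity_aggregation: str = "mean"
    n_axes: int = 2
    n_perm: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seeds(root: int) -> dict[str, int]:
    children = np.random.SeedSequence(root).spawn(len(_STAGES))
    return {
        name: int(c.generate_state(1)[0] % (2**31 - 1))
        for name, c in zip(_STAGES, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic scenario and write all outputs.

    Returns the manifest (also written to ``manifest.json``): output files
    with hashes, the seed, and headline statistics (mean CV per method,
    Wilcoxon p, ensemble accuracies, top envfit variables).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    files: dict[str, str] = {}

    def save(name: str, table: SampleTable) -> None:
        path = out / name
        write_table(table, path)
        files[name] = _sha256(path)

    logger.info("stage: synthetic data")
    traj = default_trajectory_config(
        n_vessels=config.n_vessels,
        sigma_bio=config.sigma_bio,
        sigma_tech=config.sigma_tech,
        n_tech=config.n_tech,
        depth=config.depth,
    )
    species = list(traj.species)[: config.n_species]
    traj = replace(traj, species={sp: traj.species[sp] for sp in species})
    panel = make_species_panel(
        len(species), config.separation, seeds["panel"], tuple(species)
    )
    truth = simulate_timeseries(traj, seed=seeds["timeseries"])
    counts_reps = simulate_16s(truth, traj, seed=seeds["sixteen_s"])
    metabolites = simulate_metabolites(traj, seed=seeds["metabolites"])
    truth_table = SampleTable(
        truth.densities.set_axis(pd.Index(truth.sample_ids, name="sample_id")),
        "absolute",
    )
    save("truth_densities.tsv", truth_table)
    for i, tab in enumerate(counts_reps, start=1):
        save(f"counts_rep{i}.tsv", tab)
    save("metabolites.tsv", metabolites)

    logger.info("stage: cytometry classification")
    monos = monoculture_event_tables(
        panel, max(config.train_events, 5000), seeds["monocultures"]
    )
    communities = community_event_tables(
        panel, truth, config.community_events, config.debris_fraction,
        config.dilution_factor, seeds["communities"],
    )
    ensemble = fit_species_ensemble(
        monos,
        n_members=config.n_members,
        n_events=config.train_events,
        seed=seeds["ensemble"],
        vote_threshold=config.vote_threshold,
        n_estimators=config.n_estimators,
    )
    classified, totals, het_rows = [], {}, []
    for sid, (events, _) in communities.items():
        gated = threshold_gate(events)
        if gated.n_events == 0:
            logger.warning("sample %s: no events after gating", sid)
            continue
        classified.append(classify_events(ensemble, gated))
        totals[sid] = volumetric_count(
            gated.n_events, gated.meta.acquired_volume_ul, gated.meta.dilution_factor
        )
        het = heterogeneity(gated, config.heterogeneity_aggregation)
        het_rows.append({"sample_id": sid, "heterogeneity": het.value,
                         "aggregation": het.aggregation})
    totals = pd.Series(totals, name="cells_per_ml")
    counts_df = pd.DataFrame(
        [{**c.counts, "unknown": c.unknown} for c in classified],
        index=pd.Index([c.meta.sample_id for c in classified], name="sample_id"),
    )
    meta0 = counts_reps[0].meta.drop(columns=["replicate"])
    save("classified_counts.tsv",
         SampleTable(counts_df, "counts", meta0.loc[counts_df.index]))
    totals_df = pd.DataFrame({"cells_per_ml": totals})
    totals_df.to_csv(out / "total_cell_densities.tsv", sep="\t",
                     index_label="sample_id")
    files["total_cell_densities.tsv"] = _sha256(out / "total_cell_densities.tsv")
    pd.DataFrame(het_rows).to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
    files["heterogeneity.tsv"] = _sha256(out / "heterogeneity.tsv")

    logger.info("stage: abundances")
    cyto = classified_to_abundance(classified, totals)
    save("cellscanner_rel.tsv", cyto["rel_with_unknown"])
    save("cellscanner_abs.tsv", cyto["absolute"])
    seq_rel_tables, seq_abs_tables = [], []
    for i, counts in enumerate(counts_reps, start=1):
        filtered = filter_contaminants(counts, species)
        rel = correct_copy_number(filtered, traj.copy_numbers)
        absolute = to_absolute(rel, totals.reindex(rel.samples.tolist()).fillna(0.0))
        seq_rel_tables.append(rel)
        seq_abs_tables.append(absolute)
        save(f"seq_rel_rep{i}.tsv", rel)
        save(f"seq_abs_rep{i}.tsv", absolute)

    logger.info("stage: variability")
    cv_tables = {
        "cellscanner_rel": cv_table(cyto["rel_with_unknown"], config.ddof,
                                    "cellscanner_rel"),
        "cellscanner_abs": cv_table(cyto["absolute"], config.ddof,
                                    "cellscanner_abs"),
        "hplc": cv_table(metabolites, config.ddof, "HPLC"),
    }
    for i, rel in enumerate(seq_rel_tables, start=1):
        cv_tables[f"seq_rel_rep{i}"] = cv_table(rel, config.ddof, f"seq_rel_rep{i}")
    for name, tab in cv_tables.items():
        agg = aggregate_cv(tab)
        df = tab.values.copy()
        df["average_per_timepoint"] = agg["row_means"]
        df.loc["average_per_variable"] = agg["column_means"]
        df.to_csv(out / f"cv_{name}.tsv", sep="\t", index_label="timepoint")
        files[f"cv_{name}.tsv"] = _sha256(out / f"cv_{name}.tsv")
    comparison = compare_methods_cv(
        cv_tables["seq_rel_rep1"], cv_tables["cellscanner_rel"]
    )

    logger.info("stage: ordination")
    rel1 = seq_rel_tables[0]
    dm = bray_curtis(rel1)
    ordination = pcoa(dm, config.n_axes)
    ordination.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t",
                                  index_label="sample_id")
    files["pcoa_coordinates.tsv"] = _sha256(out / "pcoa_coordinates.tsv")
    env_aligned = metabolites.data.loc[ordination.coordinates.index]
    vectors = envfit(ordination, env_aligned, config.n_perm, seeds["envfit"])
    env_df = pd.DataFrame(
        [
            {"variable": v.variable, "r2": v.r2, "p_perm": v.p_perm,
             **{f"axis{i + 1}": c for i, c in enumerate(v.direction)}}
            for v in vectors
        ]
    )
    env_df.to_csv(out / "envfit.tsv", sep="\t", index=False)
    files["envfit.tsv"] = _sha256(out / "envfit.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": asdict(config),
        "files": files,
        "runtime_s": round(time.time() - t0, 2),
        "summary": {
            "mean_cv_per_method": {
                name: aggregate_cv(tab)["grand_mean"]
                for name, tab in cv_tables.items()
            },
            "wilcoxon_seq_vs_cellscanner": {
                k: comparison[k]
                for k in ("n_cells", "p_greater", "p_two_sided", "mean_cv_ratio")
            },
            "member_accuracy": ensemble.member_accuracy_.tolist(),
            "proportion_explained": ordination.proportion_explained[
                : config.n_axes
            ].tolist(),
            "top_envfit": env_df.sort_values("r2", ascending=False)
            .head(3)["variable"].tolist(),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %d files in %s", len(files) + 1, out)
    return manifest


def sequencing_vs_cytometry_cv(
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Scaled-down replicate-variability comparison under the study design.

    Generates the default scenario (6 vessels, timepoints 12-67 h, 4 species,
    technical noise sigma_tech = 0.5 exceeding vessel noise sigma_bio = 0.15),
    builds the CV-across-vessels table for the first 16S technical replicate
    and for the cytometry-classified relative abundances, and returns the
    paired Wilcoxon comparison over the shared (timepoint, species) cells.
    """
    config = config or PipelineConfig()
    seeds = _stage_seeds(seed)
    traj = default_trajectory_config(
        n_vessels=config.n_vessels,
        sigma_bio=config.sigma_bio,
        sigma_tech=config.sigma_tech,
        n_tech=1,
        depth=config.depth,
    )
    species = list(traj.species)[: config.n_species]
    traj = replace(traj, species={sp: traj.species[sp] for sp in species})
    panel = make_species_panel(
        len(species), config.separation, seeds["panel"], tuple(species)
    )
    truth = simulate_timeseries(traj, seed=seeds["timeseries"])
    counts = simulate_16s(truth, traj, n_tech=1, seed=seeds["sixteen_s"])[0]
    seq_rel = correct_copy_number(counts, traj.copy_numbers)

    monos = monoculture_event_tables(panel, config.train_events, seeds["monocultures"])
    communities = community_event_tables(
        panel, truth, config.community_events, config.debris_fraction,
        config.dilution_factor, seeds["communities"],
    )
    ensemble = fit_species_ensemble(
        monos,
        n_members=config.n_members,
        n_events=config.train_events,
        seed=seeds["ensemble"],
        vote_threshold=config.vote_threshold,
        n_estimators=config.n_estimators,
    )
    classified = [
        classify_events(ensemble, threshold_gate(ev))
        for ev, _ in communities.values()
    ]
    cyto_rel = classified_to_abundance(classified)["rel_with_unknown"]
    cv_seq = cv_table(seq_rel, config.ddof, "seq_rel_rep1")
    cv_cyto = cv_table(cyto_rel, config.ddof, "cellscanner_rel")
    out = compare_methods_cv(cv_seq, cv_cyto)
    out["member_accuracy"] = ensemble.member_accuracy_.tolist()
    return out


def report(manifest: dict | str | Path) -> str:
    """Render a run manifest as a human-readable markdown summary."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    s = manifest["summary"]
    lines = [
        "# gutvar run report",
        "",
        f"- package version: {manifest['version']}",
        f"- seed: {manifest['seed']}",
        f"- runtime: {manifest.get('runtime_s', '?')} s",
        "",
        "## Mean CV per method",
        "",
        "| method | mean CV |",
        "|---|---|",
    ]
    for name, value in s["mean_cv_per_method"].items():
        lines.append(f"| {name} | {value:.4f} |")
    w = s["wilcoxon_seq_vs_cellscanner"]
    lines += [
        "",
        "## Sequencing vs. cytometry CV (paired Wilcoxon)",
        "",
        f"- paired cells: {w['n_cells']}",
        f"- one-sided p (sequencing > cytometry): {w['p_greater']:.3g}",
        f"- two-sided p: {w['p_two_sided']:.3g}",
        f"- mean CV ratio: {w['mean_cv_ratio']:.2f}",
        "",
        "## Classifier ensemble",
        "",
        "- per-member held-out accuracy: "
        + ", ".join(f"{a:.3f}" for a in s["member_accuracy"]),
    ]
    if s.get("top_envfit"):
        lines += [
            "",
            "## Ordination",
            "",
            "- proportion explained: "
            + ", ".join(f"{p:.3f}" for p in s["proportion_explained"]),
            f"- top envfit variables: {', '.join(s['top_envfit'])}",
        ]
    else:
        lines += ["", "## Ordination", "", "- no environmental table supplied"]
    return "\n".join(lines) + "\n"
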