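# gutvar

Technical versus biological variability in defined gut bacterial
communities.

When a synthetic community of gut bacteria (e.g. *Roseburia intestinalis*,
*Blautia hydrogenotrophica*, *Bacteroides thetaiotaomicron*, *Collinsella
aerofaciens*) is grown in parallel chemostat vessels and profiled with 16S
rRNA gene sequencing, flow cytometry, and HPLC, an obvious question is how
much of the observed vessel-to-vessel spread is biology and how much is
measurement. `gutvar` packages the analysis needed to answer it, for
microbial ecologists running replicated bioreactor experiments:

* **Flow-cytometry event classification** — ensembles of random forests
  gate cells from debris (trained on monocultures vs. a blank vessel) and
  assign community events to species, with an *unknown* class for events on
  which fewer than 7 of 10 classifiers agree. Includes in-silico community
  benchmarking against hidden truth labels.
* **Absolute abundances** — volumetric cell densities
  (events/µl × dilution × 1000), contaminant exclusion for defined
  communities, 16S copy-number correction, and scaling of relative
  compositions by total cell counts.
* **Variability statistics** — coefficient-of-variation tables across
  vessels per timepoint and variable, their aggregates, and paired Wilcoxon
  signed-rank comparisons between methods with an exact (full sign-flip
  enumeration) null up to 25 pairs; plus a cytometric population
  heterogeneity statistic (mean per-channel range).
* **Ordination** — Bray–Curtis dissimilarity, principal coordinates
  analysis (classical scaling), and `envfit`-style environmental vector
  fitting with permutation significance.
* **Synthetic data** — a generator reproducing the study design (6 vessels,
  12 h batch then chemostat at D = 1/24 h⁻¹, sampling at 12–67 h,
  triplicate 16S libraries whose technical noise exceeds vessel noise,
  washout of non-growing species, two-phase metabolite trajectories), so
  the whole pipeline is testable end to end without instrument data.

The statistical core in brief: for each measurement method *m*, each
timepoint *t* and variable *k*, compute CV across vessels,
CV\_{m,t,k} = sd(x)/mean(x); then test paired cells between methods with
the Wilcoxon signed-rank statistic W⁺ = Σᵢ rank(|dᵢ|)·1[dᵢ > 0], whose
exact null enumerates all 2ⁿ sign assignments. Classification uses the
agreement rule: an event is species *s* if at least 7 of 10 forests vote
*s*, else unknown.

## Worked example

Run the full pipeline on the default synthetic scenario:

```bash
gutvar run --seed 1 --out run1
```

This simulates the experiment, trains the classifier ensemble on simulated
monocultures, classifies every community sample, builds abundance and CV
tables, and writes `run1/manifest.json` plus a markdown report. The report
for seed 1 reads (excerpt):

```
## Mean CV per method

| method | mean CV |
|---|---|
| cellscanner_rel | 0.1536 |
| cellscanner_abs | 0.1719 |
| hplc | 0.0506 |
| seq_rel_rep1 | 0.4764 |
| seq_rel_rep2 | 0.4403 |
| seq_rel_rep3 | 0.4424 |

## Sequencing vs. cytometry CV (paired Wilcoxon)

- paired cells: 24
- one-sided p (sequencing > cytometry): 5.96e-08
- two-sided p: 1.19e-07
- mean CV ratio: 4.01
```

Reading it: across-vessel CVs from 16S sequencing average ~0.44–0.48 while
the cytometry-classification CVs average ~0.15 — a four-fold ratio — and
the paired one-sided signed-rank test over the 24 shared
(timepoint, species) cells is maximally significant (all 24 differences
positive, p = 2⁻²⁴ ≈ 6·10⁻⁸). Metabolite (HPLC) CVs are lowest, ~0.05.
That is the expected signature when technical sequencing noise
(σ_tech = 0.5) dominates true vessel-to-vessel variability (σ_bio = 0.15).

The same pieces are available as a library:

```python
from gutvar import (make_species_panel, fit_species_ensemble,
                    assemble_in_silico_community, evaluate_ensemble)
from gutvar.synthetic import monoculture_event_tables

panel = make_species_panel(n_species=4, separation=4.0, seed=1)
monos = monoculture_event_tables(panel, n_events=5000, seed=2)
ens = fit_species_ensemble(monos, n_members=10, n_events=1500, seed=3)
community, truth = assemble_in_silico_community(
    monos, {"RI": 0.4, "BH": 0.3, "BT": 0.2, "CA": 0.1}, 5000, seed=4)
print(evaluate_ensemble(ens, community, truth)["accuracy"])  # ~0.99
```

Other subcommands (`gutvar simulate|classify|abundance|variability|
ordination`) expose individual stages for externally supplied TSV/FCS
inputs; see `gutvar <cmd> --help`.

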