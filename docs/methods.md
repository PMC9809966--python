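# Methods

`gutvar` analyses replicated time series of a defined (synthetic) human gut
bacterial community grown in parallel emulated-chemostat microbioreactors.
Its purpose is to separate *technical* variability — noise introduced by the
measurement pipeline, chiefly 16S rRNA gene sequencing — from *biological*
variability between replicate vessels. This note documents the models,
parameter choices, numerical conventions, and the limits of what the
synthetic-data tests demonstrate.

## Event classification (cytometry)

Flow-cytometry events are described by 23 scatter/fluorescence parameters
(FSC-A … FSC-Width, the CytoFLEX S panel). Two classifier ensembles, both
random forests over the raw 23-channel values, implement the supervised
workflow:

* **Gating** (`CellGateClassifier`): six binary forests trained on
  monoculture (cell) versus blank-vessel (debris) events. Members differ
  only in their resampling / held-out-split seed. At prediction time an
  event is kept as a cell when a configurable number of members — majority,
  `⌈n/2⌉`, by default — votes for it. How gate votes are combined is not
  uniquely determined by the workflow we reproduce; majority is our
  (configurable) choice. A manual alternative, `threshold_gate`, keeps
  events with FL1-A > 3.5·10³ (the SYBR-positive gate).
* **Species assignment** (`SpeciesVoteClassifier`): ten multiclass forests.
  Each member draws its own random sample of `n_events` (default 5000)
  events per gated monoculture and splits off one seventh as a held-out
  test set — for 5000 events, 4286 train / 714 test. The one-seventh rule
  is adopted as the general partition rule for any `n_events`. A community
  event is assigned to the modal species when it collects at least
  `vote_threshold` (default 7) of the 10 votes; otherwise it is reported as
  **unknown**. For thresholds above half the membership a tie is
  impossible; for configured thresholds at or below half, ties abstain.
  The unknown class is carried through all downstream tables as its own
  category.

Forest hyperparameters (100 trees, unlimited depth) are configuration, not
science; monocultures smaller than `n_events` are sampled with replacement.
No transformation is applied to channel values by default (an optional
log1p transform exists); forests are invariant to monotone per-channel
transforms, so this choice is mostly cosmetic.

Ensembles are evaluated on communities assembled *in silico* from held
monoculture events at known proportions (floor quotas, remainder to the
largest proportion, shuffled). Reported accuracy excludes abstentions from
the denominator; a strict variant counts every unknown as an error.

## Absolute abundance

Volumetric counting converts gated event counts to densities:
`cells/ml = events / volume_µl × dilution × 1000`. Acquisition volumes are
explicit metadata (taken from the FCS `$VOL` keyword, in nL, when present).

16S counts are processed as: (1) contaminant exclusion — in a defined
community, a non-member taxon detected in at most one sample is dropped; a
non-member in two or more samples is retained (the recurrent-contaminant
case); members are always kept. Filtering precedes copy-number correction;
the scope of "more than one sample" is all samples of the experiment.
(2) copy-number correction — counts divided by the strain's 16S rRNA gene
copy number, then renormalised per sample. Copy numbers ship as an
editable TSV whose default values are placeholders (1) to be filled from
rrnDB; we deliberately do not invent strain values. (3) scaling — relative
abundances times the sample's flow-cytometry total give cells/ml; row sums
reproduce the totals exactly. All-zero samples propagate as *missing*
(dropped and recorded), never as NaN arithmetic.

## Variability statistics

The coefficient of variation, CV = sd/mean, is computed across vessels per
(timepoint, variable) cell, one table per measurement method. The default
standard deviation is the sample SD (ddof = 1); ddof is configurable
because published tables cannot always disambiguate it (a lone nonzero
value among five vessels gives CV = √5 ≈ 2.236 under ddof = 1, a value
that recurs in published tables for sporadically detected taxa). Cells
backed by fewer than two vessel values are missing; aggregates
(row/column/grand means) ignore missing cells, and an exclusion list
supports "average without contaminant X" summaries.

Two methods are compared with the paired Wilcoxon signed-rank test over
the (timepoint, variable) cells present in both tables (≥ 5 required).
The null distribution is exact — the full 2ⁿ sign-flip distribution,
computed by subset-sum dynamic programming over doubled midranks, so tied
magnitudes are handled exactly — for up to 25 informative pairs, and a
normal approximation with tie and continuity corrections beyond. Zero
differences are dropped (Wilcoxon's original rule); the Pratt variant is a
flag. Note that with midranks a difference vector such as
(+1, +2, +3, +4, −1) has W⁻ = 1.5 and exact two-sided p = 6/32, not the
1/8 a tie-free ranking would give; the tests pin both cases against a
brute-force enumeration oracle.

Population heterogeneity of a gated sample is the per-channel range
(max − min over events) aggregated across the 23 channels — mean by
default, sum as a variant (both readings exist in practice; outputs are
labelled). Method agreement uses Pearson or Spearman correlation.

## Ordination

Bray–Curtis dissimilarity d(i,j) = Σ|x_ik − x_jk| / Σ(x_ik + x_jk) feeds
classical scaling (PCoA): Gower-centre −½·J D² J, eigendecompose, scale
eigenvectors by √eigenvalue. No Lingoes/Cailliez correction is applied;
negative eigenvalues are reported and their axes dropped. On Euclidean
input distances the embedding is exact to 1e-9, which is the test oracle;
eigenvalues are cross-checked against scikit-bio's implementation.

`envfit` regresses each environmental variable on the sample scores of the
retained axes (default 2, as plotted ordinations use): R² is the squared
multiple correlation, the arrow is the normalised coefficient vector, and
p = (1 + #{permuted R² ≥ observed}) / (1 + n_perm) with the variable
permuted across samples (999 permutations by default, seeded). R² and
arrow direction are cross-checked against vegan's `envfit` via Rscript,
and the permutation null is calibrated (5% ± 2% rejection at α = 0.05
over 1000 simulations).

## Synthetic data generator

The generator reproduces the study design as generative assumptions, not a
mechanistic model:

* **Design constants** — 6 vessels; batch phase 12 h; chemostat dilution
  rate D = 1/24 h⁻¹ (complete medium changeover in 24 h); sampling at 12,
  25, 37, 49, 61, 67 h; 3 technical 16S replicates; 4 species (RI, BH, BT,
  CA) by default, with washout species (e.g. PC) addable.
* **Event clouds** — per species, channel values are exp(N(μ, σ)) with
  diagonal log-scale covariance (right-skewed, positive, like real data).
  Species log-means sit at the vertices of a regular simplex spanned by
  channel axes so every pair is at Mahalanobis distance `separation`
  (default 4) w.r.t. the base σ = 0.35. Species also differ in spread:
  each is tighter (factor 0.6 at separation 4, interpolating to no
  tightening at separation 0) on its own anchor channel. This reflects
  that real species differ in the width, not only the location, of optical
  parameters; it matters because four equidistant clouds that differ only
  in location have a multiclass Bayes accuracy of ≈ 0.942, whereas the
  location-plus-spread clouds support the > 0.95 per-member accuracy the
  separable fixture is meant to provide. Debris/blank events form their
  own dimmer, broader cloud well below the FL1-A gate.
* **Trajectories** — batch: exponential growth; chemostat: exponential
  relaxation toward a per-species steady state at rate D. This is
  phenomenological — no growth model is fitted in the analysis we
  reproduce, so none is invented — except washout, which is physically
  forced: a species with steady state 0 decays as exp(−D(t − 12)), hence
  e⁻¹ of its end-of-batch density 24 h after the switch. Default species
  parameters make BT dominate the batch phase and decline in chemostat
  mode while BH rises, RI and CA staying comparatively level. Biological
  noise is an independent log-normal multiplier (σ_bio = 0.15) per
  density.
* **16S counts** — expected read share ∝ density × copy number ×
  exp(technical noise), with per-(replicate, sample, taxon) log-normal
  technical noise σ_tech = 0.5. Replicates 2 and 3 share a batch-effect
  component carrying half the technical variance (replicates processed
  together are more alike); replicate 1 is independent. Reads are
  multinomial at depth 10⁴ by default. Generator copy numbers default to
  (6, 4, 5, 3) — synthetic values, unrelated to any database. σ_tech and
  σ_bio are not identifiable from published summary tables; the defaults
  are chosen to reproduce the qualitative ordering (technical > biological)
  rather than any specific table value.
* **Metabolites** — three smooth templates with small vessel noise
  (σ = 0.05, log-normal): sugars depleted during batch (gone by ~12 h),
  end products rising to a plateau, and two-phase intermediates peaking
  around the batch→chemostat switch before decaying to a lower plateau.

What the generator does **not** emulate: physiological drift of optical
phenotypes between batch and chemostat mode (classifiers trained on
monocultures face no domain shift here, unlike in reality), chimeras or
taxonomy errors in sequencing, pH/gas dynamics, and cross-feeding
mechanisms. Passing tests therefore demonstrate the correctness of the
statistical machinery under the assumed noise structure, not that real
communities satisfy those assumptions.

## Pipeline, determinism and problem sizes

`run_pipeline` chains simulate → classify → abundances → CV/Wilcoxon →
heterogeneity → PCoA/envfit from one config; all randomness derives from a
single root seed through named per-stage substreams, so reruns are
byte-identical (hash-stable manifest). Scaled-down defaults keep full runs
around half a minute on one core: 2000 community events per sample,
5000 training events per species, 50-tree forests in pipeline mode
(100-tree forests remain the estimator default); the replicate-variability
comparison uses the same sizes. These sizes are the package's defaults for
routine runs; estimator-level parameters accept larger values unchanged.

## Known limitations

* The FCS codec covers list-mode FCS 3.0/3.1 with float/double or uniform
  16/32-bit integer data and ignores compensation/spillover keywords (raw
  channel values are used throughout); exotic dialects are out of scope.
* Exact Wilcoxon p-values are limited to 25 informative pairs (subset-sum
  cost grows linearly in total rank mass but the exactness guarantee is
  only asserted there); beyond that the normal approximation is used.
* Bray–Curtis is a semimetric; no triangle-inequality-dependent method is
  applied to it.
* `envfit` fits linear vectors only (no surfaces/factors), matching the
  use it reproduces.
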