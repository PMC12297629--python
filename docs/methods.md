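# Methods

## Scope and data contract

`stilmap` operates strictly downstream of patch classification: its input is
a table of tissue patches per slide, each at a 0-based (row, col) lattice
position with one of three labels (TIL-positive, TIL-negative,
necrotic/other). Background is encoded by absence — only tissue patches
appear — which makes every grid a sparse mask. Slide tiling, stain
normalization and the patch classifier itself are out of scope.

## TIL score

The slide-level TIL score is the TIL-positive fraction among non-necrotic
tissue patches; necrotic/other patches are excluded from numerator and
denominator. A slide with only necrotic/other patches has no defined score
and is rejected. Patient scores are unweighted means over slides. Scores are
kept at full precision internally; any rounding is presentation-only.

## Gi* hot spot analysis

Each tissue patch is a spatial unit with value 1 (TIL-positive) or 0
(anything else). Weights are binary queen contiguity (8-neighborhood) among
tissue patches with self-inclusion — the "star" convention that
distinguishes Gi* from Gi. The statistic is reported as the z-score

    z_i = (Σ_j w_ij x_j − x̄ W_i) / (S · sqrt[(n U_i − W_i²)/(n − 1)]),

where x̄ and the population standard deviation S are computed over the n
tissue patches only, so background never dilutes the field mean. Two
degenerate cases are handled by convention rather than error, so cohort runs
survive rare uniform slides: a constant field (S = 0) yields all-zero z with
a `degenerate` flag, and a patch whose local denominator vanishes (W_i² =
nU_i, e.g. a patch adjacent to every other patch) gets z_i = 0.

The normal approximation is used throughout; no conditional-randomization
p-values are computed, since the z-scores feed only map rendering and the
hot-fraction summary. The **hot fraction** of a slide is the fraction of
tissue patches with z ≥ 1.96 (two-sided 5% cutoff; configurable). Maps are
rendered by a diverging blue–white–red colormap of z clipped to ±4
(configurable) on white background; clipping stabilizes color scaling
against extreme z on large uniform clusters.

Tests validate the implementation against an independent double-loop
evaluation of the definitional formula on random masked lattices (to 1e-8),
exact complement antisymmetry z(1−x) = −z(x), and approximate null
calibration (mean z in ±0.05, sd in [0.85, 1.15]) on iid 50×50 fields.

## Encoder and spatial TIL clusters

Hot spot map images are padded to square with the background color
(preserving lattice geometry; anisotropic stretch is available as
`resize_mode="stretch"`), bilinearly resized to 1024×1024×3 and scaled to
[0, 1]. The encoder is four stages of 3×3 stride-1 zero-padded convolution →
ReLU → 2×2 max pooling with channel widths (16, 8, 8, 4), taking
1024×1024×3 to 64×64×4 = 16,384 flattened features. The widths are chosen so
the flattened length is exactly 16,384.

The filters are **untrained**: He-scaled normal weights drawn once from a
fixed seed, zero biases. The encoder is therefore a deterministic
random-projection feature extractor; no training objective, reconstruction
loss, or GPU path exists. Random convolutional features preserve the coarse
color-mass layout of a map (how much saturated red/blue there is and roughly
where), which is what separates dense from sparse infiltration patterns;
they are not semantically tuned, and nothing downstream assumes they are.

PCA is fit once on the encoded cohort (centered, full SVD) and the smallest
number of components reaching 95% cumulative explained variance is kept
(capped at the matrix rank and optionally at a fixed `k_cap`, which can pin
a published component count). The component count is data-dependent by
design — e.g. a few dozen components on a 60-slide cohort, ~144 on a
200-slide cohort.

K-means (k-means++, 10 restarts, 300 iterations, tol 1e-4, fixed seed) is
run for each candidate k ∈ {2..6}; silhouette, Davies-Bouldin and
Calinski-Harabasz indices are evaluated on each partition, each metric votes
for its best k, the majority wins, and a three-way tie falls back to the
silhouette winner. Index implementations are cross-checked in tests against
brute-force evaluations of the definitional formulas (1e-8 on ≤50-point
instances). A single PCA/K-means model is fit once and applied to all
cohorts analyzed together.

With two clusters, sTILC names are assigned by hot spot content: lower mean
hot fraction → sTILC1 ("TIL-cold"), higher → sTILC2 ("TIL-hot"); ties break
deterministically to the first-indexed cluster with a warning. Naming is
undefined (an error) for k ≠ 2.

**Cohort-size note.** Internal validity indices need adequately populated
clusters: on the synthetic cohorts, Davies-Bouldin's per-cluster scatter
estimates are noisy below roughly 50 slides per cluster, and the vote can
wander among k ∈ {2..5} on cohorts of ~60 slides even when the two-cluster
partition itself is essentially perfect (ARI ≈ 1 against planted
archetypes). With the package's fixed encoder, from ~200 slides
Davies-Bouldin and Calinski-Harabasz agree on k = 2 decisively.
Cohort-level cluster-selection checks and the acceptance computation
therefore use 200-slide cohorts; per-slide operations are tested at much
smaller sizes.

The encoder filter bank is part of the method, not run-level randomness: one
fixed bank (the default `weight_seed`) is applied to every cohort, exactly
as a single trained-or-fixed encoder would be. Alternative random bases
differ in how much of the density signal survives into the leading
principal components, so re-drawing the encoder per analysis adds an
unnecessary — and avoidable — source of variability to cluster selection.

## LNM models and evaluation

Covariates use ordinal integer codings throughout: age 0 (<45) / 1 (45–65) /
2 (>65); T stage 0–3 for T1–T4; sTILC 1 (cold) / 2 (hot); outcome 1 for
N1–N3, 0 for N0. Tree ensembles split ordinals natively, so no one-hot
expansion is used. Cohorts are split 8:2 stratified on the outcome.

M1 and M2 are random forests returning ensemble vote fractions as
probabilities (no recalibration). Hyperparameters are selected by mean
stratified 5-fold cross-validated AUC over a small grid — tree count
{100, 300}, max depth {3, 5, unbounded}, min leaf {1, 5, 10} — with ties
resolved to the earliest grid entry and forests grown warm-start so each
depth/leaf combination builds its largest forest once per fold. The grid is
deliberately compact: on a few hundred records with ≤4 ordinal features,
300-tree forests are already stable (cross-validated AUC differences along
the tree-count axis are ~1e-3), and the compact grid keeps repeated
cohort-level refits cheap on a single CPU.

* **AUC** is the tie-corrected Mann-Whitney statistic (midranks), tested
  against exhaustive pair counting.
* **DeLong test**: structural-components (placement-value) estimator of
  Var(AUC₁ − AUC₂) for correlated curves via midranks; z referred to the
  standard normal, two-sided. Degenerate variance (e.g. identical score
  vectors) returns (z = 0, p = 1) by convention. The variance estimator is
  validated against a 2000-replicate paired bootstrap (within 15% at
  n = 100).
* **Brier score**: mean squared error of predicted probabilities.
* **Shapley attributions** are exact and interventional: all 2⁴ coalitions
  are enumerated, a coalition's value is the model output averaged over
  background rows with in-coalition features fixed to the explained record.
  Efficiency, dummy and symmetry hold to 1e-9 by construction. Whether a
  tree-path-dependent convention would give different magnitudes is an open
  question; the interventional choice is exact and axiom-clean at 4
  features. For cohort-level summaries the explained records and background
  are subsampled (80 records / 40 background rows by default in the
  replicate analyses) purely for tractability; per-record values are exact
  given the background.
* **Decision curves**: NB(t) = TP/N − FP/N · t/(1−t) on a 0.01..0.99 grid;
  treat-all has the closed form prevalence − (1−prevalence)·t/(1−t);
  treat-none is identically 0.
* **Baseline tables** use chi-square without continuity correction for
  categorical variables and Welch's t-test for the TIL score.

The ablation refits M1 with (a) all PCA components, (b) PC1+PC2 only,
(c) the sTILC label, exposing the overfitting of the high-dimensional
variants via train/validation AUC gaps.

## Synthetic-data generator

The generator emulates the study's data shapes with known truth:

* **Tissue masks**: unions of discs grown from the grid center (connected by
  construction; largest component kept), covering ≈60% of a 48×48 lattice.
* **TIL fields**: standard-normal noise smoothed by a separable moving
  average of window equal to the archetype's correlation length (window 1 =
  iid), thresholded at the quantile giving the target positive fraction
  among tissue patches. Density and clumpiness are therefore controlled
  independently. Cold archetype: 8% positive, correlation length 2; hot:
  45% positive, correlation length 8. 5% of tissue patches are relabeled
  necrotic/other uniformly (no necrotic cores — sufficient to exercise the
  score's exclusion rule, not a model of necrosis geometry).
* **Cohorts**: archetype drawn 50/50; age and T stage from marginals typical
  of a lung-adenocarcinoma case mix (age 0.05/0.47/0.48; T
  0.35/0.45/0.13/0.07); outcome Bernoulli with
  logit p = −1.0 + 0.6·T + 0.1·age − 3.0·TIL + 0.7·1[cold].
  The coefficients give ~30–35% prevalence and a detectable-but-unsaturated
  TIL advantage for M1 over M2 (validation ΔAUC roughly 0.05–0.2 at
  n = 500), keeping the DeLong comparison meaningful. The clinical table's
  sTILC column carries the ground-truth archetype coding (1 = cold,
  2 = hot); the end-to-end pipeline overwrites it with the image-derived
  assignment.

What the generator does **not** emulate: H&E texture, classifier error
processes, necrotic cores, multi-slide patients (one slide per patient),
or inter-hospital covariate shift. Passing recovery tests therefore shows
the pipeline recovers planted spatial/outcome structure under clean
conditions, not that it is robust to real-world label noise.

Determinism: each patient's mask, field and covariates come from child
streams spawned from the cohort seed; identical specs yield byte-identical
CSVs.

## Problem sizes used in the automated checks

Chosen for single-CPU runtimes: Gi* oracle lattices up to 30×30; null
calibration on 50×50 × 10 seeds; archetype-recovery ARI on 10 cohorts of 40
slides; consensus cluster selection and the acceptance computation on one
200-slide cohort; model discrimination and attribution checks on twenty
500-patient cohorts (fitted once and shared between checks); the pipeline
smoke test on 24 patients.

## Known limitations

* The encoder is a fixed random projection; its features are reproducible
  but not interpretable individually. Changing the weight seed changes the
  PCA basis and can weaken the density signal that separates the clusters —
  the encoder should be treated as frozen method configuration.
* sTILC naming is defined only for the two-cluster outcome.
* Consensus cluster selection is unreliable on small cohorts (see
  cohort-size note above).
* DeLong and the normal approximation for Gi* are asymptotic; very small
  cohorts or lattices should not rely on their p-values.
* Probabilities are raw forest vote fractions; no calibration module exists.
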