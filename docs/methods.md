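# Methods

This note documents the models, numerical choices and design decisions
behind `dropmet`, in the spirit of a package methods appendix. Everything
quantitative stated here is computed by the test suite or the acceptance
script; nothing is quoted from external data.

## 1. What the synthetic generator emulates

The generator produces peak-level GC–MS datasets with the statistical
structure the downstream analysis assumes. It works in two layers.

**True abundances.** Each species' per-sample abundance is
`base_abundance × subject_factor × fold(time, group, arm) × biological
jitter`. Fold profiles are the planted effects; subject factors are
log-normal offsets (σ = `subject_cv`, cohort default 0.30) constant within
a subject; run-level response jitter (σ = `run_cv`, cohort default 0.15)
perturbs non-baseline folds.

**Peak rendering.** Each species becomes one chromatographic peak: a
Gaussian on the absolute 20 Hz scan grid (width 0.8–1.2 s per species,
window ±3 σ), per-mass trace integrals equal to abundance × relative
spectral intensity, so that the scan-sum AUC equals the abundance up to a
constant factor — the simplest shape that exercises summation-based
quantification. Technical noise is strictly multiplicative log-normal
(`replicate_cv`, default 0.08 per measurement) plus small retention-time
jitter (0.3 s) and per-mass intensity jitter (2%). The signal-to-noise
value is proportional to rendered abundance (`sn_ref` = 600 intensity
units per S/N unit), so low-abundance species straddle the S/N = 20
picker threshold. Left-censoring zeroes scan intensities below the
detection limit `lod`; a mass disappears when all its scans are censored
and a peak disappears when all its masses are, which makes missingness
probability monotone non-increasing in abundance (the NMAR structure the
imputation assumes). Values at or above `lod` are never touched.

**Fragment spectra are stylized.** Each metabolite owns a small set of
characteristic nominal masses (unique across the panel except for the
derivatization-reagent fragments 73/147 Th, present in every derivatized
spectrum, and the phosphate marker 299 Th shared by the three sugar
phosphates); the published isotope-pair ions for glucose and lactate are
used verbatim. Real electron-impact spectra share many more fragments
across compounds; consequently, passing annotation tests here demonstrate
the matching machinery, not real-world disambiguation power.

### 1.1 The single-runner (MPR) design

Eight time points (baseline, laps L1–L6, one recovery point 20 min after
exercise), duplicate technical measurements, maximum perceived exertion
planted at lap 3. Planted effects derive from a latent model with four
main bases — anaerobic activity (fast rise, plateau), oxygen release
(contrast peaking at L3), TCA activity (rise after L3, sustained), and
energetic (spike after the exertion maximum) — plus an auxiliary "ketotic
rise" basis that accumulates into recovery. Log-fold profiles are linear
combinations of the bases; the pinned, study-scale folds are exact by
construction: lactate `e^1.3863 = 4` at its plateau, both ketone bodies
`e^2.7726 = 16` at recovery, succinate `e^0.6931 = 2` at its maximum,
glucose flat, the oxygen markers peaking at L3. Nine species load purely
on single factors — lactate, pyruvate (anaerobic); 2,3-bisphosphoglycerate,
ribose-5-P, ribulose-5-P (oxygen); citrate, succinate (TCA); creatine,
triethanolamine (energetic) — and form the planted key-metabolite set
(the package's choice of ninth member is succinate). Ketone bodies,
α-hydroxybutyrate, glycerol and alanine carry mixed profiles plus large
per-measurement "lap wobble" (log-σ 0.45–0.8) at exercise time points
only, so baseline and recovery folds stay exactly at their pinned values;
this models the lap-to-lap and drop-to-drop volatility of ketotic and
lipolytic markers, and it is what the duplicate measurements are for (see
the reliability gate, §3). Unidentified "decoy" species receive random
factor-mixture profiles drawn once from the panel seed — a species'
exercise response is a property of the species, not of the simulation
run — with small wobble (0.05).

### 1.2 The crossover cohort design

26 subjects × two inspired-oxygen arms (0.209 / 0.145), time points
baseline, 10/20/30 min and two recovery points, one measurement each.
Perceived exertion at the last exercise point is drawn from a
three-component truncated-normal mixture (centers 2.5/5/8.5, σ 0.8,
weights 0.38/0.36/0.26 on the 1–10 scale). σ = 0.8 was chosen so the
planted mixture is actually trimodal and its components recoverable; at
σ = 1 the components fuse (a kernel density over many draws shows two
modes, not three) and no grouping method can recover membership at the
planted rate. Early stopping follows a logistic model in exertion and
hypoxia (intercept −3.0, RPE slope 0.45, hypoxia offset 0.8), and a
stopped run's final sample carries the final-exercise fold column — the
sample drawn "at exhaustion" reflects the exhausted state, which is what
makes the downstream re-encoding of last exercise time points
scientifically sensible. Effect folds per metabolite depend on (RPE group,
arm): glucose and lactate rise strongly only in high-exertion runs and
more under hypoxia; β-hydroxybutyrate stays flat in the high-exertion
hypoxia cell; the oxygen markers respond to the arm, which also induces
arm-dependent missingness for the low-abundance pentose phosphates.
Measurement order is block-randomized with one subject per block
(≤ 12 samples), then shuffled within blocks.

## 2. Retention indices, annotation, quantification

- **RI formula.** Linear interpolation between alkane anchors
  (RI = 100·n), the van den Dool–Kratz convention for
  temperature-programmed GC. Outside the ladder span the terminal segment
  is continued linearly and the assignment flagged `ri_extrapolated` —
  early/late eluters are kept, not silently dropped.
- **S/N threshold.** `sn >= threshold` (inclusive), reading a stated
  threshold as the minimum acceptable ratio; default 20.
- **Similarity metric.** Cosine over the union of nominal masses on
  square-root intensities (damps base-peak dominance); cross-checked in
  the tests against an independent implementation (matchms CosineGreedy).
  Defaults `ri_tol` = 5 RI units, `sim_min` = 0.6 — typical for
  alkane-calibrated GC and configurable.
- **Stepwise matching.** Tiers searched in order (standards → in-house →
  database subset); one-to-one per sample, resolved greedily by
  descending similarity with |ΔRI| and name as tie-breaks. Greedy (not
  optimal assignment) matches the stepwise description; in the synthetic
  regime spectra are near-orthogonal and the two coincide.
- **Unidentified consensus.** Single-linkage clustering of unmatched peaks
  on RI (tolerance 5), labels `UNID_<rank>` ordered by median RI —
  deterministic and sample-order-independent.
- **Adjacency.** "Adjacent peaks" are peaks whose apexes differ by at
  most 3 s (configurable); their shared nominal masses are excluded from
  the top-5 ranking. Forced class-characteristic masses are *added* to
  the top five (a selection may hold six masses), reflecting that they
  are included purposefully rather than substituted.
- **Isotope pairs.** Per pair, light/heavy AUC ratio; the concentration
  estimate is the arithmetic mean of per-pair ratios × spiked amount, and
  per-pair ratios are reported for concordance checking. The estimate is
  exactly invariant to sample-wide intensity scaling.

## 3. Normalization, exclusion gates, imputation

Values are ratios to the cinnamic-acid internal standard; samples without
a positive IS AUC are excluded with a log entry. Two gates precede
multivariate modelling, both leaving univariate fold exports untouched:

1. **Missingness**: metabolites missing in more than 20% of samples
   (boundary kept at exactly 20%) are excluded from multivariate
   statistics. A per-condition Fisher-exact screen (BH-adjusted) reports
   condition-associated missingness, e.g. the arm-dependent censoring of
   the pentose phosphates.
2. **Replicate reliability**: in designs with duplicate measurements, the
   per-metabolite replicate log-RSD (root-mean-square deviation of
   replicates around their within-time-point mean) is computed; species
   above 0.3 are too volatile for covariance-based modelling and are
   excluded from it. Stable species sit near 0.16 (technical noise on
   both the analyte and the IS trace), the planted volatile species near
   0.5–1.1, so the gate has a wide margin. This is the standard RSD
   feature-filtering of metabolomics QC, and it is the analytic purpose
   of duplicate measurements.

**QRILC-style imputation** is re-implemented (rather than wrapped) so the
pipeline is self-contained and seedable: per metabolite on the natural-log
scale, a normal distribution is fitted to the observed values by maximum
likelihood under left-censoring at the per-metabolite observed minimum
(the usual surrogate for the unknown detection limit); missing entries
are drawn from the fitted normal truncated above at that censor point.
The Nelder–Mead optimizer starts at the naive moments; metabolites with
fewer than three observed values are dropped rather than imputed. Tests
verify parameter recovery (bias ≤ 0.1 in μ, ≤ 0.15 in σ on N(10,1)
censored at 9, n = 500) and that naive moments are biased upward where
the censored MLE is not — the quantitative justification for NMAR
treatment.

## 4. Cohort statistics

- **Fold changes** divide by each run's baseline after replicate
  aggregation by geometric mean (log-scale mean, the natural choice for
  multiplicative noise). Early-stopped runs are re-encoded so their last
  exercise sample occupies the final-exercise slot. The fold table is
  exactly invariant to per-run scaling.
- **Spearman PCA**: eigendecomposition of the metabolite rank-correlation
  matrix; scores are standardized ranks projected on eigenvectors, so
  eigenvalues and |loadings| are invariant under per-metabolite strictly
  monotone transforms — the design's key robustness property, appropriate
  for small heterogeneous cohorts. One consequence worth knowing: the
  rank transform compresses between-cluster gaps, so cluster-separation
  indices (silhouette) saturate near 0.33 for two well-separated groups
  of this size even without noise; separation should be judged by the
  projection ordering along the ellipse-center axis (AUC ≈ 1 in the
  planted scenario), not by silhouette magnitude.
- **Hotelling T²** on the first two score dimensions (matching 2-D score
  plots), cutoff from the exact in-model distribution
  `T² ~ ((n−1)²/n)·Beta(k/2, (n−k−1)/2)` at 1−α; removal applied once.
  Calibration on null multivariate-normal scores is 5% ± Monte-Carlo
  error; on rank-PCA scores the filter is mildly conservative (≈ 3%)
  because ranks are lighter-tailed.
- **Ellipse separation**: per-group mean and covariance at the χ²(2) 95%
  level; run projections on the unit center-difference vector; metabolite
  contributions are loadings projected on the same vector, ranked by
  magnitude.
- **Hierarchical clustering**: Euclidean distance on per-metabolite
  z-scored values, average linkage by default (SciPy's deterministic
  lowest-index tie-break), Newick export. The reduced-panel agreement
  check (`verify_reduction`) instead uses Ward linkage and drops
  zero-dynamics species first: whole-partition comparison needs decisive
  cut heights, which Ward's balanced clusters provide, and a flat
  z-scored column is pure noise in sample space.
- **Group tests**: two-sided Wilcoxon rank-sum, exact null when both
  sides have ≤ 25 runs and no ties, otherwise the normal approximation
  with tie correction; one Benjamini–Hochberg family jointly across every
  metabolite × time × comparison cell.
- **RPE grouping**: a three-component 1-D Gaussian mixture (5
  initializations, seeded); boundaries at posterior crossovers between
  mean-sorted components; fixed cuts (4, 7) for fewer than six runs or on
  request; a single-valued input collapses to one group with a flag.

## 5. The metabolic state model

Principal-axis factoring (statsmodels) on the correlation matrix of
log-scale, QC-gated, identified species, varimax rotation, deterministic
sign orientation. The factor count uses the Kaiser criterion
(eigenvalues > 1) when automatic; the packaged single-runner scenario
carries `n_factors = 4` in its ground truth. Key metabolites are ranked
by **communality** — the variance a metabolite shares with the extracted
factor space — with ties broken by name; `k_select="auto"` keeps species
with communality ≥ 0.49. Communality was chosen over maximum |loading|
deliberately: with 16 observations, loading-based ranking is unstable
when volatile high-fold species co-load on a factor, whereas communality
cleanly separates clean single-factor markers from wobble-carrying
mixtures; it is also a defensible reading of selecting the variables
"with the highest eigenvalues". Factor labels (anaerobic activity, TCA
activity, oxygen release, energetic) are string metadata assigned by
matching each factor's loaders against canonical marker sets; no semantic
inference is computed. Factor scores use the Thomson regression method;
the state timeline exports per-time factor means, key-metabolite means
min-max scaled to [0, 1] for rose/ring rendering, and redox-ratio means.

Krebs ratios are element-wise on the linear scale and exactly invariant
to per-sample normalization constants; a ratio column is omitted (with a
log entry) when a constituent is absent, and missing values propagate.

## 6. Problem sizes and determinism

Monte-Carlo tests use the sizes they state: 50 seeds for scenario
recovery (16-sample single-runner datasets at full peak level), 100 seeds
for censored-MLE recovery at n = 500, 500 replicates for Hotelling
calibration at n = 100, and 2000 replicates for the all-null FDR check at
the study's group sizes (29 vs 20). These sizes make the checks stable
while keeping the default suite fast. Every stochastic component consumes
a `numpy.random.Generator`; the CLI fans a single global seed into
per-stage seeds through `SeedSequence`, and identical configuration +
seed reproduce a run directory's SHA-256 manifest exactly.

## 7. Known limitations

- Spectra, retention times and abundances are stylized; annotation
  difficulty is far below that of real EI spectra, and the generator
  emits one peak per metabolite (no derivatization-variant merging).
- Effect profiles are descriptive fold trajectories, not a physiological
  model; the latent-factor construction exists to make planted structure
  recoverable, not to simulate metabolism.
- The cohort's planted group effects are shared across subjects up to
  log-normal jitter; real inter-individual response heterogeneity is
  richer (responders/non-responders, training state).
- No raw chromatogram/mzML synthesis, no baseline or deconvolution
  modelling — the pipeline consumes picked peak tables by design.
- The acceptance checks demonstrate recovery of *planted* effects under
  the generator's assumptions; they cannot validate the pipeline against
  undeposited clinical data.
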