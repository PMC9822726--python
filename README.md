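# dropmet

A tested, reusable analysis pipeline for **blood-drop GC–MS metabolomics of
exercising humans**: from per-sample peak tables through retention-index
annotation, top-5 mass-trace quantification, internal-standard
normalization, left-censored imputation, exertion-group statistics, Krebs
redox ratios, and a factor-analytic metabolic state model — together with a
synthetic-data generator that emulates the two study designs the pipeline
targets, so every stage is testable without access to clinical raw data.

**Who it is for.** Metabolomics analysts working with capillary
("drop-of-blood") GC–MS time-course data from exercise studies, and method
developers who need a fully synthetic, ground-truthed test bed for
peak-table-level pipelines.

## The science in brief

Capillary blood drops quenched in cold methanol/chloroform/water carry a
snapshot of central carbon metabolism. After derivatization, GC–MS produces
per-sample peak tables (apex retention time, signal-to-noise, per-mass
scan traces over 70–600 Th). The pipeline implements the analysis stages
such a study uses:

- **Retention indices.** An n-alkane ladder (C10…C36) calibrates a
  Kovats-style index: RI(rt of alkane Cn) = 100·n, linearly interpolated
  between alkanes (van den Dool–Kratz form for temperature-programmed GC).
- **Annotation.** Peaks are matched stepwise against tiered libraries
  (authentic standards → in-house → public-database subset) by RI window
  and spectral cosine on square-root intensities; unidentified but
  consistently occurring peaks receive stable `UNID_<k>` labels.
- **Quantification.** Each species is integrated as the plain scan-sum
  (AUC, no interpolation) of its five most intense mass traces, excluding
  derivatization-reagent fragments (73, 147 Th) and masses shared with
  adjacent peaks; characteristic masses (299 Th for phosphates) are
  included purposefully. Uniformly ¹³C-labeled glucose and lactate spikes
  give scale-free concentration checks via the ion pairs 319/323 + 217/220
  Th (glucose) and 117/119 + 190/193 Th (lactate).
- **Normalization & missingness.** Abundances are ratios to the cinnamic
  acid internal standard. Missing values are treated as *not missing at
  random* (left-censored at the detection limit): a censored-normal maximum
  likelihood fit per metabolite on the log scale, with truncated-normal
  imputation draws (QRILC-style). Metabolites missing in more than 20% of
  samples, or failing a technical-replicate reliability gate, are excluded
  from multivariate statistics (but kept in univariate fold profiles).
- **Statistics.** Fold changes vs. each run's baseline (early-stopped runs
  re-encoded to the final-exercise slot); PCA on the metabolite *Spearman*
  correlation matrix; Hotelling T² outlier removal; 95% confidence-ellipse
  separation of low- vs high-exertion runs with per-metabolite
  contributions along the center-to-center axis; hierarchical clustering;
  two-sided Wilcoxon rank-sum tests with one Benjamini–Hochberg family.
- **State model.** Krebs redox ratios (lactate/pyruvate for cytosolic and
  β-hydroxybutyrate/acetoacetate for mitochondrial NAD⁺/NADH; lactate/citrate
  and pyruvate/citrate for the anaerobic↔TCA switch), and a principal-axis
  factor analysis with varimax rotation that reduces the panel to nine key
  metabolites across four interpreted factors (anaerobic activity, oxygen
  release, TCA activity, energetic), exported as a state timeline for
  circos/rose rendering.

The **synthetic generator** plants all of this structure: a single-runner
design (baseline, six laps, recovery; duplicate measurements) whose pinned
effects are the study-scale folds — lactate plateauing at 4-fold, ketone
bodies reaching 16-fold post-exercise, succinate peaking near 2-fold,
glucose flat, 2,3-bisphosphoglycerate peaking at the maximum-exertion
lap — and a 26-subject crossover trial (FiO₂ 0.209 vs 0.145) with a
trimodal perceived-exertion outcome and intensity-dependent left-censoring.
Ground-truth objects record every planted quantity for recovery testing.

## Worked example

```python
from dropmet import synthgen as sg
from dropmet.scenario import ScenarioConfig
from dropmet.pipeline import run_dataset, mpr_fold_table

cfg = ScenarioConfig.preset("mpr_run")
panel = sg.panel_for(cfg)
tables, meta, truth = sg.simulate_mpr_run(panel, cfg, seed=1)   # 16 peak tables
data = run_dataset(panel, tables, meta)                          # S/N -> RI -> annotate -> quantify -> normalize
folds = mpr_fold_table(data.matrix)
print(folds.loc["recovery", ["acetoacetate", "beta-hydroxybutyrate",
                             "lactate", "glucose"]].round(2))
```

prints (seed 1):

```
metabolite
acetoacetate            18.46
beta-hydroxybutyrate    16.05
lactate                  3.01
glucose                  1.07
```

i.e. the pipeline recovers the planted post-exercise ketone-body surge
(16-fold, up to technical noise and the deliberately volatile lap-to-lap
behaviour of acetoacetate), the lactate elevation, and flat glucose; the
seed-averaged recovery (see below) sits within ~2% of the planted folds.
The factor-analytic state model on the same data selects the nine key
metabolites and labels the four factors:

```python
from dropmet.normimpute import exclude_unreliable
from dropmet.statemodel import factor_reduce
qc, _ = exclude_unreliable(data.matrix)        # replicate-reliability gate
print(factor_reduce(qc, n_factors=4, k_select=9).summary())
```

A command-line interface mirrors the library
(`dropmet run --preset mpr_run --seed 7 --outdir out/` then
`dropmet report --outdir out/`); every stage writes into a run directory
with a SHA-256 manifest, and identical configuration + seed reproduce the
manifest byte-for-byte.

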