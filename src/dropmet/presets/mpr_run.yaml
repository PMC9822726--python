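# Single-runner observational design: baseline, six laps, one recovery point,
# duplicate technical measurements. Planted effects come from a four-factor
# latent model (anaerobic activity, oxygen release, TCA activity, energetic);
# pinned study-scale folds: lactate plateau at 4x, ketone bodies 16x
# post-exercise, succinate peaking at 2x, glucose flat, oxygen-release
# markers peaking at the maximum-exertion lap (L3). Ketone bodies ride the
# TCA-activity rise plus lap-level biological wobble, so they track the
# oxidative recovery without being clean single-factor markers themselves.
design: mpr_run
n_subjects: 1
replicates: 2
arms: [0.209]
time_points:
  - {label: baseline, minutes: 0}
  - {label: L1, minutes: 10}
  - {label: L2, minutes: 20}
  - {label: L3, minutes: 31}
  - {label: L4, minutes: 41}
  - {label: L5, minutes: 51}
  - {label: L6, minutes: 61}
  - {label: recovery, minutes: 81}
rpe_model:
  kind: fixed
  trajectory: [1, 3, 5, 9, 6, 5, 4, 2]
factor_model:
  bases:
    anaerobic activity: [0.0,  0.85,  0.90,  1.00, 1.00,  1.00,  0.97,  0.80]
    oxygen release:     [0.0, -0.25,  0.15,  1.00, 0.00, -0.05, -0.15, -0.15]
    TCA activity:       [0.0, -0.05, -0.10,  0.00, 0.60,  0.85,  1.00,  0.90]
    energetic:          [0.0, -0.10, -0.15,  0.00, 0.90,  0.70,  0.40,  0.05]
  # auxiliary basis for species that accumulate into recovery (ketone
  # bodies): gradual rise through the run, surge after exercise
  extra_bases:
    ketotic rise:       [0.0,  0.05,  0.10,  0.18, 0.30,  0.50,  0.75,  1.00]
  # log-fold coefficients per basis
  # [anaerobic, oxygen, TCA, energetic, ketotic]; pinned folds:
  # lactate e^1.3863 = 4, ketones e^2.7726 = 16 at recovery (the
  # acetoacetate ketotic coefficient compensates its oxygen-basis value at
  # recovery), succinate e^0.6931 = 2 at its maximum, glucose flat.
  loadings:
    lactate:                 [1.3863, 0.0, 0.0, 0.0, 0.0]
    pyruvate:                [1.0296, 0.0, 0.0, 0.0, 0.0]
    2,3-bisphosphoglycerate: [0.0, 1.0986, 0.0, 0.0, 0.0]
    ribose-5-phosphate:      [0.0, 0.9163, 0.0, 0.0, 0.0]
    ribulose-5-phosphate:    [0.0, 0.8329, 0.0, 0.0, 0.0]
    citrate:                 [0.0, 0.0, 0.9163, 0.0, 0.0]
    succinate:               [0.0, 0.0, 0.6931, 0.0, 0.0]
    creatine:                [0.0, 0.0, 0.0, 0.7132, 0.0]
    triethanolamine:         [0.0, 0.0, 0.0, 0.6530, 0.0]
    beta-hydroxybutyrate:    [0.0, 0.0, 0.0, 0.0, 2.7726]
    acetoacetate:            [0.0, 0.4500, 0.0, 0.0, 2.8401]
    alpha-hydroxybutyrate:   [0.0, 0.2500, 0.9000, 0.0, 0.0]
    glycerol:                [0.3500, -0.3500, 0.7500, 0.0, 0.0]
    alanine:                 [0.5500, 0.0, 0.0, 0.0, 0.0]
    glucose:                 [0.0, 0.0, 0.0, 0.0, 0.0]
# per-measurement biological scatter (log-sd) of unstable species at
# exercise time points; the duplicate measurements exist to catch exactly
# this, and the replicate-QC gate removes these species from multivariate
# modelling while univariate fold profiles keep them
lap_wobble:
  beta-hydroxybutyrate: 0.80
  acetoacetate: 0.80
  alpha-hydroxybutyrate: 0.80
  glycerol: 0.70
  alanine: 0.60
decoy_coef_sd: 0.50
decoy_wobble: 0.05
key_metabolites:
  - lactate
  - pyruvate
  - citrate
  - succinate
  - 2,3-bisphosphoglycerate
  - ribose-5-phosphate
  - ribulose-5-phosphate
  - creatine
  - triethanolamine
replicate_cv: 0.08
subject_cv: 0.0
run_cv: 0.0
rt_jitter_s: 0.3
mass_jitter_cv: 0.02
sn_ref: 600.0
lod: 2.0
block_plan: {max_block_size: 12}
n_extra_metabolites: 12
panel_seed: 7
seed: 0
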