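# Prospective crossover trial: 26 subjects, both inspired-oxygen arms
# (FiO2 0.209 sea level / 0.145 simulated 3000 m), time points baseline,
# 10/20/30 min exercise and two recovery points. The perceived-exertion
# outcome at the last exercise time point is trimodal; effect folds depend
# on (RPE group, arm); runs may stop before 30 min with a probability that
# increases with RPE and under hypoxia.
design: cohort
n_subjects: 26
replicates: 1
arms: [0.209, 0.145]
time_points:
  - {label: baseline, minutes: 0}
  - {label: 10min, minutes: 10}
  - {label: 20min, minutes: 20}
  - {label: 30min, minutes: 30}
  - {label: recovery1, minutes: 40}
  - {label: recovery2, minutes: 50}
rpe_model:
  kind: mixture
  centers: [2.5, 5.0, 8.5]
  sds: [0.8, 0.8, 0.8]
  weights: [0.38, 0.36, 0.26]
effect_profiles:
  glucose:
    low:    {normoxia: [1, 1.00, 1.05, 1.10, 1.00, 0.95], hypoxia: [1, 1.00, 1.05, 1.15, 1.05, 1.00]}
    median: {normoxia: [1, 1.10, 1.25, 1.40, 1.20, 1.10], hypoxia: [1, 1.15, 1.35, 1.60, 1.40, 1.25]}
    high:   {normoxia: [1, 1.30, 1.60, 2.00, 1.50, 1.20], hypoxia: [1, 1.40, 1.90, 2.60, 2.20, 1.80]}
  lactate:
    low:    {normoxia: [1, 1.30, 1.45, 1.50, 1.25, 1.10], hypoxia: [1, 1.35, 1.50, 1.60, 1.30, 1.15]}
    median: {normoxia: [1, 1.80, 2.30, 2.60, 1.90, 1.50], hypoxia: [1, 2.00, 2.60, 3.00, 2.20, 1.70]}
    high:   {normoxia: [1, 2.50, 3.50, 4.50, 3.00, 2.00], hypoxia: [1, 2.80, 4.00, 5.00, 3.50, 2.50]}
  pyruvate:
    low:    {normoxia: [1, 1.15, 1.20, 1.25, 1.10, 1.05], hypoxia: [1, 1.20, 1.25, 1.30, 1.15, 1.08]}
    median: {normoxia: [1, 1.40, 1.60, 1.70, 1.40, 1.25], hypoxia: [1, 1.45, 1.70, 1.85, 1.55, 1.35]}
    high:   {normoxia: [1, 1.70, 2.10, 2.40, 1.90, 1.50], hypoxia: [1, 1.80, 2.30, 2.60, 2.10, 1.70]}
  acetoacetate:
    low:    {normoxia: [1, 1.10, 1.25, 1.40, 1.70, 2.00], hypoxia: [1, 1.10, 1.25, 1.40, 1.70, 2.00]}
    median: {normoxia: [1, 1.20, 1.50, 1.90, 2.40, 2.80], hypoxia: [1, 1.20, 1.50, 1.90, 2.40, 2.80]}
    high:   {normoxia: [1, 1.50, 2.20, 3.00, 4.00, 4.50], hypoxia: [1, 1.50, 2.20, 3.00, 4.00, 4.50]}
  beta-hydroxybutyrate:
    low:    {normoxia: [1, 1.10, 1.20, 1.40, 1.70, 2.00], hypoxia: [1, 1.10, 1.20, 1.40, 1.70, 2.00]}
    median: {normoxia: [1, 1.20, 1.40, 1.80, 2.30, 2.70], hypoxia: [1, 1.15, 1.30, 1.60, 2.00, 2.30]}
    high:   {normoxia: [1, 1.30, 1.80, 2.50, 3.50, 4.00], hypoxia: [1, 1.05, 1.15, 1.30, 1.50, 1.60]}
  alpha-hydroxybutyrate:
    low:    {normoxia: [1, 1.10, 1.20, 1.30, 1.20, 1.10], hypoxia: [1, 1.10, 1.20, 1.30, 1.20, 1.10]}
    median: {normoxia: [1, 1.20, 1.40, 1.60, 1.40, 1.25], hypoxia: [1, 1.20, 1.40, 1.60, 1.40, 1.25]}
    high:   {normoxia: [1, 1.40, 1.80, 2.20, 1.90, 1.60], hypoxia: [1, 1.40, 1.80, 2.20, 1.90, 1.60]}
  succinate:
    low:    {normoxia: [1, 1.20, 1.30, 1.40, 1.25, 1.10], hypoxia: [1, 1.20, 1.30, 1.40, 1.25, 1.10]}
    median: {normoxia: [1, 1.50, 1.80, 2.10, 1.70, 1.40], hypoxia: [1, 1.50, 1.80, 2.10, 1.70, 1.40]}
    high:   {normoxia: [1, 1.80, 2.50, 3.20, 2.50, 2.00], hypoxia: [1, 1.80, 2.50, 3.20, 2.50, 2.00]}
  alanine:
    low:    {normoxia: [1, 1.05, 1.10, 1.10, 1.05, 1.00], hypoxia: [1, 1.05, 1.10, 1.10, 1.05, 1.00]}
    median: {normoxia: [1, 1.10, 1.20, 1.30, 1.20, 1.10], hypoxia: [1, 1.10, 1.20, 1.30, 1.20, 1.10]}
    high:   {normoxia: [1, 1.20, 1.40, 1.60, 1.40, 1.20], hypoxia: [1, 1.20, 1.40, 1.60, 1.40, 1.20]}
  glycerol:
    low:    {normoxia: [1, 1.50, 1.80, 2.00, 1.60, 1.30], hypoxia: [1, 1.50, 1.80, 2.00, 1.60, 1.30]}
    median: {normoxia: [1, 1.50, 1.80, 2.00, 1.60, 1.30], hypoxia: [1, 1.45, 1.70, 1.90, 1.55, 1.28]}
    high:   {normoxia: [1, 1.50, 1.80, 2.00, 1.60, 1.30], hypoxia: [1, 1.30, 1.50, 1.60, 1.35, 1.20]}
  citrate:
    low:    {normoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.05], hypoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.05]}
    median: {normoxia: [1, 1.10, 1.20, 1.30, 1.25, 1.15], hypoxia: [1, 1.10, 1.20, 1.30, 1.25, 1.15]}
    high:   {normoxia: [1, 1.20, 1.40, 1.60, 1.40, 1.20], hypoxia: [1, 1.20, 1.40, 1.60, 1.40, 1.20]}
  2,3-bisphosphoglycerate:
    low:    {normoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.00], hypoxia: [1, 1.20, 1.40, 1.50, 1.30, 1.10]}
    median: {normoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.00], hypoxia: [1, 1.20, 1.40, 1.50, 1.30, 1.10]}
    high:   {normoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.00], hypoxia: [1, 1.25, 1.50, 1.70, 1.40, 1.15]}
  ribose-5-phosphate:
    low:    {normoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.00], hypoxia: [1, 1.20, 1.40, 1.50, 1.30, 1.10]}
    median: {normoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.00], hypoxia: [1, 1.20, 1.40, 1.50, 1.30, 1.10]}
    high:   {normoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.00], hypoxia: [1, 1.25, 1.50, 1.70, 1.40, 1.15]}
  ribulose-5-phosphate:
    low:    {normoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.00], hypoxia: [1, 1.20, 1.40, 1.50, 1.30, 1.10]}
    median: {normoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.00], hypoxia: [1, 1.20, 1.40, 1.50, 1.30, 1.10]}
    high:   {normoxia: [1, 1.05, 1.10, 1.15, 1.10, 1.00], hypoxia: [1, 1.25, 1.50, 1.70, 1.40, 1.15]}
incomplete_model:
  intercept: -3.0
  rpe_coef: 0.45
  hypoxia_coef: 0.8
  stop_weights: {10min: 0.35, 20min: 0.65}
replicate_cv: 0.08
subject_cv: 0.30
run_cv: 0.15
rt_jitter_s: 0.3
mass_jitter_cv: 0.02
sn_ref: 600.0
lod: 3.0
block_plan: {max_block_size: 12}
n_extra_metabolites: 15
panel_seed: 7
seed: 0
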