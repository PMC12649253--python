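# depmsm — multi-state models of depressive-symptom dynamics with feature selection

Longitudinal aging panels (CHARLS-style biennial surveys) measure depressive
symptoms with the 10-item CES-D scale at each wave.  Over several waves a
person may develop a first symptom episode, stay symptomatic, remit, and
relapse — distinct phases with potentially distinct risk factors.  `depmsm`
implements the full analysis for this question: it classifies wave-level
CES-D scores into five states (no symptom, new episode, persistence,
remission, relapse), builds a stacked counting-process design over the
permissible transitions S = {1→2, 2→3, 2→4, 3→4, 4→5}, and fits
transition-specific Cox models

    λ_{i,hg}(t) = λ_{0,hg}(t) · exp(β_hg′ x_i),   hg ∈ S,

by maximizing the stacked partial likelihood with per-transition adaptive
Lasso penalties,

    β̂ = argmin_β  −(1/n) Σ_{hg∈S} Σ_i [ β_hg′x_i − log Σ_{j∈R_h} e^{β_hg′x_j} ]
                   + Σ_{hg∈S} λ_hg Σ_r |β_hg,r| / |β̃_hg,r| ,

so that each transition keeps only its own relevant risk factors.  Effects
are reported as transition rate ratios TRR = exp(β̂) with 95% Wald limits
from a post-selection refit.  Because the underlying survey microdata are
restricted, the package ships a seeded synthetic-cohort generator that
emulates the study's structure (published covariate marginals, published
coefficients as true effects, wave-censored observation), so the entire
pipeline is testable end to end.  It is aimed at biostatisticians working
with multi-state event-history models on panel data.

See `docs/methods.md` for the model, its assumptions, and every numerical
and design choice.

## Worked example

The numbered scripts under `analysis/` run the study pipeline on a synthetic
cohort (each accepts `--seed`, `--out-dir`, and where relevant `--config`):

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_classify_states.py
python analysis/03_prepare_covariates.py
python analysis/04_build_design.py
python analysis/05_fit_penalized.py
python analysis/06_report_effects.py
```

With seed 1 (2,000 subjects, waves at 0/2/4/7 years) the cohort yields

```
observed transition events: {'12': 755, '23': 224, '24': 266, '34': 48, '45': 40}
```

i.e. 755 first episodes, 224 persistence events, 314 remissions and 40
relapses — the same order as the published cohort's frequencies.  The
penalized fit then selects a sparse set of effects per transition block
(blocks 2→4 and 3→4 share one remission block) and reports them as rate
ratios:

```
selected effects (Est, SE, TRR [95% CL], sig):
  [12] sex_x_age: +0.8586 (0.1355) TRR 2.3599 [1.8095, 3.0777] **
  [23] sex: +0.4185 (0.1408) TRR 1.5197 [1.1532, 2.0026] *
  [24+34] sex: -0.3209 (0.1131) TRR 0.7255 [0.5813, 0.9055] *
  [45] sex_x_age: +1.8771 (0.5645) TRR 6.5345 [2.1613, 19.7568] **
```

Read: being female multiplies the persistence intensity by ≈ 1.52 and the
remission intensity by ≈ 0.73; the sex × age product (which, uncentered, is
nearly collinear with the sex main effect and here absorbs it) raises onset
and — most strongly — relapse intensity.  `**` marks p ≤ 0.001, `*`
p ≤ 0.05.  The onset-age summary splits subjects who ever reached each
state at 60 years of onset age:

```
 state   n  mean_onset_age  early_onset  late_onset
     2 755       62.104461          304         451
     3 224       61.220448           98         126
     4 314       60.634941          145         169
     5  40       60.784073           20          20
```

`analysis/07_validation_study.py` reruns the estimator on cohorts with known
truth and prints its operating characteristics (support recovery, false
positives, bias, KKT certificates).  `depmsm.pipeline.run_pipeline` drives
all stages in one call from a YAML config.

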