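# neuroplay

Game-based assessment of peripheral neuropathy (PNP) from
pressure-sensing shoe insoles — a tested, end-to-end pipeline for
researchers in digital biomarkers and diabetic neuropathy screening.

Patients with diabetes or metabolic syndrome play four short video games
(Apple Catch, Balloon Flying, Cross-Pressure, Island Jump) controlled
solely by modulating plantar pressure on 8-sensor insoles sampled at
200 Hz.  From the gaming telemetry the package computes a per-foot
catalog of 762 primary and task-combination features, six key-capability
scores (reaction time, sensation, skillfulness, muscle strength, balance,
endurance, each on [0, 1]), and clinical labels per foot: PNP (≥ 2
positive findings among NSS ≥ 3, vibration, temperature, pinprick, ankle
reflex and 10-g monofilament testing), asymmetric PNP, and the
small-fiber / large-fiber / mixed phenotype.  Elastic-net logistic models
(glmnet objective `(1/n)·NLL + λ[(1−α)/2‖β‖² + α‖β‖₁]`) are selected by
repeated stratified 5-fold cross-validated AUC over nested prefixes of
the top-ranked features and evaluated on a stratified 3:7 hold-out;
phenotype models are evaluated CV-only with the Hand-Till multiclass AUC.

Since no raw cohort data are public, the package ships a first-class
synthetic-cohort generator: virtual patients with latent per-foot
small/large-fiber deficits that drive the bedside exam, nerve-conduction
values, and a closed-loop simulated player (reaction latency, motor
noise, sensing deadband, force ceiling, fatigue) that actually plays the
games.  See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from neuroplay import (GeneratorConfig, PipelineConfig,
                       simulate_cohort_study, run_pnp_pipeline,
                       cohort_summary)

study = simulate_cohort_study(n=120, config=GeneratorConfig(),
                              seed=7, rate=50.0)
print(cohort_summary(study.statuses))
report = run_pnp_pipeline(study, PipelineConfig.fast(), seed=7,
                          multiclass=False)
print(report.binary["left"].summary())
```

prints (abridged):

```
                count    n  percent
left_foot_pnp      84  120     70.0
right_foot_pnp     85  120     70.8
any_pnp            89  120     74.2
asymmetric_pnp     35  120     29.2
PNP classification results (elastic-net logistic)
====================================================
train n = 84   test n = 36   candidate features = 227
selected features (5):
  CP.T11.normalized_pressure
  IJ.T07.pressure_gradient
  CP.TCL3.sd.time_outside_zone
  CP.T02.pressure_time_integral
  IJ.T13.deviation
alpha = 0.1   lambda = 0.0316228
cross-validated AUC = 1.000
held-out confusion matrix [tp fn / fp tn] = [23 2 / 1 10]
sensitivity = 92.0%   specificity = 90.9%
balanced accuracy = 91.5%   AUC-ROC = 0.956
```

Reading this: the generator hit its configured ~75% PNP prevalence and
~27% asymmetric-finding rate; after variance and intercorrelation
filtering 227 candidate features remain; the subset search settled on
five Cross-Pressure and Island-Jump features (steady-pressure quality
and jump precision) at α = 0.1, and the held-out left-foot AUC of 0.956
shows that on this strong-effect synthetic cohort the game features
separate neuropathic from healthy feet well.

A thin CLI wraps the same calls:

```bash
neuroplay simulate --n 20 --seed 1 --out cohort_features.csv
neuroplay score --n 5 --seed 1          # capability scores + tier per participant
neuroplay phenotype --n 50 --seed 1     # cohort prevalence table
neuroplay pipeline --n 120 --seed 1     # train/evaluate the PNP models
```

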