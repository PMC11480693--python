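# Methods

`neuroplay` is an end-to-end, testable reimplementation of a game-based
screening pipeline for peripheral neuropathy (PNP): four short video games
controlled entirely through pressure-sensing shoe insoles, a feature
catalog computed from the gaming telemetry, bedside clinical scoring that
labels each foot, and penalized-regression classifiers that predict those
labels from the game features.  Because no raw study data are public, the
package pairs the analysis pipeline with a first-class synthetic-cohort
generator whose defaults emulate the published study conditions; every
statistical property of the pipeline is demonstrated on cohorts drawn
from that generator.

## The virtual patient model

Each participant carries a latent per-foot state with three components on
[0, 1]: a small-fiber deficit (C/Aδ pathways: temperature and pain
sensation), a large-fiber deficit (Aα/Aβ: vibration, pressure, reflexes)
and a symptom burden.  Severity is `max(small, large)`: either fiber
class alone can make a foot clinically neuropathic.  Diseased
participants draw their affected fiber class(es) from a phenotype mix
(SFN : LFN : mixed = 0.11 : 0.44 : 0.45, matching the published phenotype
table's left-foot proportions) with affected deficits uniform on
[0.55, 1] and unaffected ones on [0, 0.1]; healthy participants sit below
0.05.

**Clinical observation model.**  Each sign item (vibration, temperature,
pinprick, ankle reflex, each of three monofilament sites) turns abnormal
with probability `logistic(-4 + 8 d)` of the deficit `d` of the fiber
class it tests — about 2% false-abnormal at `d = 0` and 98% at `d = 1`.
An `exam_noise` temperature parameter scales the logit; at 0 the exam
becomes a deterministic threshold at `d = 0.5`, which the null-case and
saturated-case tests exercise.  The NSS total is Binomial(10,
`logistic(-2.5 + 5·burden)`).  Exam noise is *shared between sides*: one
latent uniform per item per participant is compared against each side's
abnormality probability.  Discordant findings therefore arise only from
genuine left/right deficit differences.  (Per-side-independent item noise
is incompatible with a ~27% asymmetric-finding rate: at mid-range
deficits it alone would produce discordance in well over half of
participants.)

**Calibration.**  The generator has two latent knobs — the disease
probability and the probability of a per-foot deficit perturbation (one
side's deficits multiplied by `1 − U(0.3, 0.7)`).  At config-build time a
fixed-seed Monte-Carlo fixed-point iteration (30 000 draws, 4 iterations)
solves both so that the *simulated clinical exam* reproduces the
configured PNP prevalence (default 75.1%) and asymmetric-finding rate
(default 26.7%).  Setting the asymmetry target to 0 disables the
perturbation entirely and both feet share identical latents.

**Covariates** (age, sex, weight/BMI, diabetes type and duration,
cognition) follow the published cohort's marginals but are drawn
independently of disease state, emulating the covariate-matched
subcohort; propensity matching itself is out of scope.

**Nerve conduction.**  Per foot, sural sensory and tibial motor NCV and
amplitude decline linearly in the large-fiber deficit
(e.g. sural NCV = 48 − 14·d m/s, sd 3) and a whole-foot record is missing
with probability 0.135 (≈ 5/37, the study's incompleteness rate).

## The closed-loop player

The four games' fixed task programs define, at any sampling rate, the
region-level pressure trajectory a perfect player would apply.  A
simulated player tracks that trajectory subject to six motor-control
parameters derived from the latent deficits (each with individual jitter
reflecting healthy between-subject variability):

| parameter | meaning | default map |
|---|---|---|
| reaction latency (s) | dead time before responding; lag τ = latency/2 | 0.22 + 0.50·mean(small, large) |
| pressure noise sd | AR(1) noise (τ = 0.15 s) + 6 Hz tremor | 0.015 + 0.09·mean |
| sensing deadband | per-task target misperception, U(−db, db) | 0.005 + 0.10·small |
| max force fraction | output ceiling | 1 − 0.30·large |
| fatigue rate (/min) | multiplicative target droop over the session | 0.005 + 0.055·large |
| tremor freq (Hz) | fixed | 6 |

Releases are ballistic (stopping to press is immediate), so release
detection in the jumping game is well defined even for lagged players.
An `effect_scale` knob multiplies every deficit-dependent gain (0 =
null link, used for the null-distribution checks; intermediate values for
graded-effect studies), and `null_motor` severs the link entirely.

The generator emulates seated pressure-control behavior only: no gait,
stance or biomechanical foot model, no learning effects across the
session, no handedness/footedness asymmetry in control skill.  Passing
tests therefore demonstrate the pipeline's statistical machinery —
calibration arithmetic, feature extraction, selection hygiene, metric
arithmetic, null behavior — not clinical validity on real insole data.

## Games and scoring

All game mechanics are deterministic functions of the normalized streams.
Clinically stated rules are kept exactly: task counts 14/12/16/16, the
4.5 s steady-pressure hold, the 25 s inactivity timeout, the 5 s
uncorrected-collision restart, and the 3-failed-efforts allowance
(applied per island / per task instance).  All purely geometric
tolerances are pinned package conventions collected in one constants
table (exported as JSON for audit): catch band 0.08, smiley band 0.06,
pressure bands low [0.15, 0.45] and high [0.55, 0.85], release detection
at 20% of the rolling peak within 100 ms.  The carriage control law maps
the left/right forefoot pressure difference to position (the simplest law
consistent with the game description).  Every task outcome is embedded in
the event log (`task_end` payload), so outcomes are reconstructible from
the log alone.

## Feature catalog

Primary features are per-task parameters: four pressure kernels (mean,
range, max gradient, trapezoidal pressure-time integral) on the task's
controlling region plus per-game timing and outcome measures (reaction,
anticipation, execution, relaxation, time-outside-zone, deviations,
attempts, collisions, stability).  Secondary features are the sum, mean
and sample SD (n−1; single member → SD 0) of each primary parameter over
the members of each task combination (TC); TC registries per side are AC
2, BF 4, CP 6, IJ 3.  Reaction time is operationalized as the first
pressure change ≥ 0.05 sustained ≥ 50 ms after task onset.  Timed-out
measurements carry the task's maximum duration as a sentinel (order
"slower is worse" is preserved for modeling) and are flagged; per-foot
vectors hold NaN for anything unobtainable, never silently dropping keys.

The canonical catalog is generated exhaustively from these definitions:
**762 features per foot** (a regression constant asserted in tests).  The
original study reports 2622 parameters per side; its per-game parameter
and TC enumerations are not fully published, so that figure cannot be
re-derived and this package's catalog is a documented reconstruction, not
a reproduction.

## Capability scores

The six key capabilities are reconstructions: the study names them and
their intent but no equations.  Each maps a metric through a fixed
clamped linear ramp whose anchors were frozen from the ideal-player and
zero-effort/maximally-impaired reference simulations: reaction (mean of
reaction/anticipation times, anchors 0.85–8 s), sensation (mean deviation
from target pressure, 0.02–0.45), skillfulness (total score / 58),
muscle strength (success rate in high-pressure tasks), balance
(left/right success-rate gap, 0.01–0.60), endurance (out-of-band burden
over the final quarter of the steady-pressure tasks, 0–20 s).  Endurance
deliberately measures *late-session* performance rather than a
late-minus-early drift: a drift statistic saturates to zero once early
performance is already at the floor, destroying monotonicity in severity.
Tier cut-points (mean ≥ 0.85 expert, ≥ 0.65 advanced, ≥ 0.4 average) are
conventions.

## Clinical scoring

NSS categories 0–2/3–4/5–6/7–10; NDS categories 0–2/3–5/6–8/9–10.  The
published NDS rubric is not restated in the source, so the 0–10
composition here is a convention: vibration, temperature and pinprick
contribute 1 point per abnormal side, the ankle reflex 2 points per side,
capped at 10.  PNP per foot = ≥ 2 positive findings among {symptoms
(NSS ≥ 3), vibration, temperature, pinprick, reflex, monofilament ≥ 1
insensate site}; "symptoms positive" as NSS ≥ 3 (the mild threshold) is
likewise a documented choice.  Phenotypes partition each foot by
small-fiber score (temperature + pinprick) and large-fiber score (reflex
+ vibration + monofilament positivity): without / SFN / LFN / mixed.
The partition is verified against exhaustive enumeration of all item
combinations.

## Statistics and modeling

Test selection is distribution-driven with a Shapiro-Wilk gate at
α = 0.05 (the authors do not name their normality test); missing NCS
values are deleted pairwise; Holm-Bonferroni is the pairwise multiplicity
control; adjusted R² = 1 − (1 − r²)(n − 1)/(n − 2) from the simple OLS
line.

The classifier pipeline: near-zero-variance filter (SD < 1e−8 or < 3
distinct values) and a greedy |r| > 0.75 intercorrelation filter on the
full feature table; a stratified 3:7 hold-out split (test size
⌊0.3 n⌋, per-class floors corrected by largest remainder — 173 records
split 122/51); univariate screening (t / Mann-Whitney, p < 0.05, with a
smallest-p fallback) and ROC-based importance ranking on the training
partition only; a nested-prefix search over the top-20 features crossed
with an elastic-net grid (α ∈ {0.1, 0.55, 1.0}; λ log-spaced over
[1e−5, 10], 100 points) scored by repeated stratified 5-fold × 10-repeat
CV mean AUC.  Ties prefer the smaller subset, then the larger λ.  The
penalty uses the glmnet parameterization
`(1/n)·NLL + λ[(1−α)/2‖β‖² + α‖β‖₁]` (scikit-learn saga, `C = 1/(nλ)`);
at λ = 0 the fit matches an unpenalized MLE to 1e−4.  Whether the
original univariate screen was nested inside CV folds is unstated; here
it runs once on the training partition, and a permutation test verifies
the held-out labels cannot influence selection.  The source text states
both "10 repeats" and "3 times" for the CV scheme; 10 repeats is adopted.

One consequence of AUC-based selection worth knowing: when a single
feature dominates, CV AUC is invariant to λ and the tie rule picks
maximal shrinkage, so predicted probabilities concentrate near the class
prior and the fixed 0.5 threshold can classify everything as the majority
class.  AUC (the selection and headline metric) is unaffected;
threshold-based metrics from such fits should be read with that in mind.

Binary AUC is the tie-corrected rank statistic (checked exactly against
brute-force concordance counting); the multiclass phenotype models are
evaluated CV-only (no hold-out, matching the small-sample design) with
the Hand-Till average of pairwise class-separability AUCs.

## Problem sizes and numerical choices

The device samples at 200 Hz; all engines, targets and features are
rate-agnostic, and the ideal player attains every game maximum at 200,
50 and 25 Hz alike.  Monte-Carlo cohort studies in the tests and the
acceptance script run at 25–50 Hz with the reduced `fast`/`screen`
model-selection grids (same pipeline stages, smaller α/λ/prefix grids and
fewer CV repeats) — the package's chosen problem sizes for replicated
property checks: strong-effect recovery at n = 200, the null property
over 20 replicate cohorts of n = 200, the graded-effect trend over
3 effect levels × 10 seeds at n = 120, capability monotonicity at 50
sessions per severity level.  Generator effect sizes, game tolerances and
acceptance bands are identical at every rate and grid.

Degenerate inputs are rejected loudly: constant vectors in correlation,
single-class labels in AUC/splitting, calibration windows whose maximum
does not exceed their minimum (the offending sensor is named), malformed
session files (with line numbers), unknown game identifiers.

## Known limitations

* Generator coefficients linking severity to motor behavior are free
  parameters, not estimates — the source provides no quantitative link.
* The published real-cohort results (held-out AUCs 0.72/0.75, multiclass
  0.76/0.72, the NCS correlation table) are not reproducible without the
  cohort; the package reproduces their *arithmetic* from printed
  confusion matrices and counts, and verifies the method's statistical
  properties on synthetic cohorts instead.
* The exact insole sensor-to-region map, the games' true geometry and
  control gains, and the full AC parameter list are unpublished; all are
  pinned conventions here.
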