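"""Virtual cohort generation.

Each virtual participant carries a latent per-foot neuropathy state: a
small-fiber deficit (temperature/pain pathways), a large-fiber deficit
(vibration/pressure/reflex pathways) and a symptom burden, all on [0, 1].
Severity is ``max(small, large)`` — either fiber class alone can make a
foot clinically neuropathic.  The latent state drives three observation
channels:

* the bedside exam (:func:`sample_clinical_exam`) — each sign item turns
  abnormal with probability ``logistic(a + b * deficit)`` of the fiber
  class it tests; exam noise is shared between sides so that asymmetric
  findings reflect genuine left/right deficit differences;
* nerve conduction studies (:func:`sample_ncs`) — NCV and amplitude
  decline linearly in the large-fiber deficit plus Gaussian noise, with a
  configurable fraction of incomplete records;
* motor control (:func:`motor_params_from_latent` +
  :func:`simulate_player`) — reaction latency, pressure noise, sensing
  deadband, force ceiling and fatigue drift scale with the deficits and
  shape the pressure streams with which the games are played.

The generator calibrates its latent disease probability and per-foot
perturbation probability by internal Monte-Carlo fixed-point iteration so
that the *downstream clinical exam* reproduces the configured PNP
prevalence and asymmetric-finding rate.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .calibration import (
    CHANNELS,
    FOREFOOT_CHANNELS,
    HEEL_CHANNELS,
    PressureStream,
)
from .clinical import ClinicalExam, FootSigns
from .errors import ConfigError
from .games.programs import ideal_targets

FEET = ("left", "right")

_CALIBRATION_SEED = 987_654_321  # internal MC; independent of user seeds
_CALIBRATION_N = 30_000
_CALIBRATION_ITER = 4


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the virtual cohort.

    Defaults emulate the study conditions: ~75% PNP prevalence, ~27%
    asymmetric findings, covariates matching the published cohort medians,
    a small/large/mixed phenotype mix matching the published phenotype
    counts, and an exam misclassification of ~2% at deficit 0 and ~98% at
    deficit 1 (logistic intercept -4, slope 8).
    """

    prevalence: float = 0.751
    asymmetry: float = 0.267      # target rate of >= 1 discordant finding
    # exam model
    exam_a: float = -4.0
    exam_b: float = 8.0
    exam_noise: float = 1.0       # 0 -> deterministic threshold at deficit .5
    nss_a: float = -2.5
    nss_b: float = 5.0
    # latent deficit distributions
    phenotype_mix: tuple = (0.11, 0.44, 0.45)   # SFN, LFN, mixed
    deficit_low: float = 0.55
    deficit_high: float = 1.0
    deficit_bg: float = 0.10      # upper bound of the unaffected fiber class
    healthy_max: float = 0.05
    asym_reduction: tuple = (0.3, 0.7)
    # nerve conduction model (baseline, decline over full deficit, noise sd)
    sural_ncv: tuple = (48.0, 14.0, 3.0)      # m/s
    sural_amp: tuple = (12.0, 9.0, 1.5)       # uV
    tibial_ncv: tuple = (46.0, 12.0, 3.0)     # m/s
    tibial_amp: tuple = (10.0, 7.0, 1.2)      # mV
    ncs_missing: float = 0.135
    # motor control maps (baseline + gain * deficit)
    latency_base: float = 0.22
    latency_gain: float = 0.50    # s per unit mean deficit
    noise_base: float = 0.015
    noise_gain: float = 0.09      # normalized pressure sd per unit deficit
    deadband_base: float = 0.005
    deadband_gain: float = 0.10   # per unit small-fiber deficit
    force_loss: float = 0.30      # ceiling drop per unit large-fiber deficit
    fatigue_base: float = 0.005
    fatigue_gain: float = 0.055   # droop fraction/minute per unit deficit
    tremor_freq: float = 6.0      # Hz
    effect_scale: float = 1.0     # scales all deficit-dependent motor gains
    null_motor: bool = False      # motor params independent of the latents
    # session
    rate_hz: float = 200.0

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not 0.0 <= self.asymmetry < 1.0:
            raise ConfigError(f"asymmetry must be in [0, 1), got {self.asymmetry}")
        if not 0.0 <= self.ncs_missing <= 1.0:
            raise ConfigError("ncs_missing must be in [0, 1]")

    def to_yaml(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text_or_stream) -> "GeneratorConfig":
        if isinstance(text_or_stream, str):
            text_or_stream = io.StringIO(text_or_stream)
        d = yaml.safe_load(text_or_stream) or {}
        fields = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    age: float
    sex: str
    weight: float
    bmi: float
    diabetes_type: str       # none | type1 | type2
    diabetes_duration: float
    cognition_normal: bool


@dataclass(frozen=True)
class FootLatent:
    small_fiber_deficit: float
    large_fiber_deficit: float
    symptom_burden: float

    @property
    def severity(self) -> float:
        return max(self.small_fiber_deficit, self.large_fiber_deficit)


@dataclass(frozen=True)
class LatentNeuropathy:
    left: FootLatent
    right: FootLatent

    def foot(self, side: str) -> FootLatent:
        return self.left if side == "left" else self.right


@dataclass(frozen=True)
class MotorControlParams:
    reaction_latency: float       # s, dead time before responding
    pressure_noise_sd: float      # normalized units
    sensing_deadband: float       # normalized units
    max_force_fraction: float     # output ceiling in (0, 1]
    fatigue_rate: float           # droop fraction per minute
    tremor_freq: float            # Hz

    @classmethod
    def ideal(cls) -> "MotorControlParams":
        return cls(0.0, 0.0, 0.0, 1.0, 0.0, 0.0)


@dataclass(frozen=True)
class NcsFoot:
    sural_sensory_ncv: float | None
    sural_sensory_amplitude: float | None
    tibial_motor_ncv: float | None
    tibial_motor_amplitude: float | None
    complete: bool


@dataclass(frozen=True)
class NcsRecord:
    left: NcsFoot
    right: NcsFoot

    def foot(self, side: str) -> NcsFoot:
        return self.left if side == "left" else self.right


@dataclass
class Participant:
    profile: ParticipantProfile
    latent: LatentNeuropathy
    motor: dict  # foot -> MotorControlParams


# ---------------------------------------------------------------------------
# exam model

def _item_prob(deficit, cfg: GeneratorConfig):
    """P(item abnormal | fiber deficit) with a temperature-like noise
    scale; noise 0 degenerates to a hard threshold at deficit 0.5."""
    z = cfg.exam_a + cfg.exam_b * np.asarray(deficit, float)
    if cfg.exam_noise <= 0:
        return (z > 0).astype(float)
    return 1.0 / (1.0 + np.exp(-z / cfg.exam_noise))


def _nss_prob(burden, cfg: GeneratorConfig):
    z = cfg.nss_a + cfg.nss_b * np.asarray(burden, float)
    if cfg.exam_noise <= 0:
        return (z > 0).astype(float)
    return 1.0 / (1.0 + np.exp(-z / cfg.exam_noise))


def _sample_exam_arrays(small, large, burden, cfg: GeneratorConfig, rng):
    """Vectorized exam sampling.

    ``small``/``large`` have shape (n, 2) (columns left/right); exam noise
    (the latent uniforms) is shared between sides.  Returns a dict of
    integer arrays.
    """
    n = small.shape[0]
    out = {}
    for item, deficit in (("temperature", small), ("pinprick", small),
                          ("vibration", large), ("ankle_reflex", large)):
        u = rng.random((n, 1))
        out[item] = (u < _item_prob(deficit, cfg)).astype(int)
    u_sites = rng.random((n, 3, 1))
    p_large = _item_prob(large, cfg)[:, None, :]
    out["monofilament_sites"] = (u_sites < p_large).sum(axis=1).astype(int)
    out["nss_total"] = rng.binomial(10, _nss_prob(burden, cfg))
    return out


def _exam_from_arrays(arrays: dict, i: int) -> ClinicalExam:
    feet = []
    for j in range(2):
        feet.append(FootSigns(
            vibration=int(arrays["vibration"][i, j]),
            temperature=int(arrays["temperature"][i, j]),
            pinprick=int(arrays["pinprick"][i, j]),
            ankle_reflex=int(arrays["ankle_reflex"][i, j]),
            monofilament_sites=int(arrays["monofilament_sites"][i, j]),
        ))
    return ClinicalExam(int(arrays["nss_total"][i]), feet[0], feet[1])


def sample_clinical_exam(latent: LatentNeuropathy, seed,
                         config: GeneratorConfig | None = None) -> ClinicalExam:
    """Draw a bedside exam for one participant from the latent state."""
    cfg = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    small = np.array([[latent.left.small_fiber_deficit,
                       latent.right.small_fiber_deficit]])
    large = np.array([[latent.left.large_fiber_deficit,
                       latent.right.large_fiber_deficit]])
    burden = np.array([max(latent.left.symptom_burden,
                           latent.right.symptom_burden)])
    arrays = _sample_exam_arrays(small, large, burden, cfg, rng)
    return _exam_from_arrays(arrays, 0)


# ---------------------------------------------------------------------------
# latent state sampling and generator calibration

def _sample_latent_arrays(n: int, p_d: float, q: float,
                          cfg: GeneratorConfig, rng):
    """Vectorized latent draws -> (small, large, burden, diseased) with
    small/large of shape (n, 2)."""
    diseased = rng.random(n) < p_d
    phen = rng.choice(3, size=n, p=np.asarray(cfg.phenotype_mix) /
                      np.sum(cfg.phenotype_mix))
    small_b = rng.uniform(0.0, cfg.healthy_max, n)
    large_b = rng.uniform(0.0, cfg.healthy_max, n)
    hi = rng.uniform(cfg.deficit_low, cfg.deficit_high, (n, 2))
    bg = rng.uniform(0.0, cfg.deficit_bg, (n, 2))
    small_aff = diseased & ((phen == 0) | (phen == 2))
    large_aff = diseased & ((phen == 1) | (phen == 2))
    small = np.repeat(small_b[:, None], 2, axis=1)
    large = np.repeat(large_b[:, None], 2, axis=1)
    # both feet share the base deficits; asymmetry enters only through the
    # perturbation below
    small[diseased] = np.repeat(bg[diseased][:, :1], 2, axis=1)
    large[diseased] = np.repeat(bg[diseased][:, 1:], 2, axis=1)
    small[small_aff] = np.repeat(hi[small_aff][:, :1], 2, axis=1)
    large[large_aff] = np.repeat(hi[large_aff][:, 1:], 2, axis=1)
    # per-foot asymmetric perturbation: one side's deficits reduced
    perturb = diseased & (rng.random(n) < q)
    side = rng.integers(0, 2, n)
    factor = 1.0 - rng.uniform(*cfg.asym_reduction, n)
    rows = np.flatnonzero(perturb)
    small[rows, side[rows]] *= factor[rows]
    large[rows, side[rows]] *= factor[rows]
    sev = np.maximum(small, large).max(axis=1)
    burden = np.clip(sev * rng.uniform(0.6, 1.1, n), 0.0, 1.0)
    return small, large, burden, diseased


def _clinical_rates(small, large, burden, cfg, rng):
    """(prevalence, asymmetric-finding rate) of a vectorized cohort."""
    a = _sample_exam_arrays(small, large, burden, cfg, rng)
    mono_pos = (a["monofilament_sites"] >= 1).astype(int)
    symptoms = (a["nss_total"] >= 3).astype(int)[:, None]
    findings = (symptoms + a["vibration"] + a["temperature"] + a["pinprick"]
                + a["ankle_reflex"] + mono_pos)
    pnp_foot = findings >= 2
    any_pnp = pnp_foot.any(axis=1)
    items = np.stack([a["vibration"], a["temperature"], a["pinprick"],
                      a["ankle_reflex"], mono_pos])
    asym = (items[:, :, 0] != items[:, :, 1]).any(axis=0)
    return float(any_pnp.mean()), float(asym.mean())


_calibration_cache: dict = {}


def calibrate_generator(cfg: GeneratorConfig) -> tuple[float, float]:
    """Solve for (disease probability, perturbation probability) so the
    simulated exam hits the configured prevalence and asymmetry rate."""
    key = (cfg.prevalence, cfg.asymmetry, cfg.exam_a, cfg.exam_b,
           cfg.exam_noise, cfg.nss_a, cfg.nss_b, cfg.phenotype_mix,
           cfg.deficit_low, cfg.deficit_high, cfg.deficit_bg,
           cfg.healthy_max, cfg.asym_reduction)
    if key in _calibration_cache:
        return _calibration_cache[key]
    p_d = cfg.prevalence
    q = cfg.asymmetry if cfg.asymmetry > 0 else 0.0
    for _ in range(_CALIBRATION_ITER):
        rng = np.random.default_rng(_CALIBRATION_SEED)
        small, large, burden, _ = _sample_latent_arrays(
            _CALIBRATION_N, p_d, q, cfg, rng)
        prev_hat, asym_hat = _clinical_rates(small, large, burden, cfg, rng)
        if prev_hat > 0:
            p_d = float(np.clip(p_d * cfg.prevalence / prev_hat, 0.01, 0.99))
        if cfg.asymmetry > 0 and asym_hat > 0:
            q = float(np.clip(q * cfg.asymmetry / asym_hat, 0.0, 1.0))
    _calibration_cache[key] = (p_d, q)
    return p_d, q


# ---------------------------------------------------------------------------
# covariates

def _sample_profiles(n: int, rng) -> list[ParticipantProfile]:
    """Covariates emulating the published cohort; independent of disease
    (matched-cohort emulation)."""
    profiles = []
    sex = rng.choice(["male", "female"], n, p=[0.62, 0.38])
    age = np.clip(rng.normal(66.0, 8.5, n), 18.0, 85.0)
    weight = np.clip(rng.normal(88.0, 15.0, n), 45.0, 160.0)
    height = np.where(sex == "male", rng.normal(1.76, 0.07, n),
                      rng.normal(1.64, 0.06, n))
    dia = rng.choice(["none", "type1", "type2"], n, p=[0.091, 0.228, 0.681])
    duration = np.where(dia == "none", 0.0,
                        np.clip(rng.lognormal(np.log(13.0), 0.75, n), 0.0, 60.0))
    cognition = rng.random(n) < 0.85
    for i in range(n):
        profiles.append(ParticipantProfile(
            participant_id=f"P{i + 1:04d}",
            age=round(float(age[i]), 1),
            sex=str(sex[i]),
            weight=round(float(weight[i]), 1),
            bmi=round(float(weight[i] / height[i] ** 2), 1),
            diabetes_type=str(dia[i]),
            diabetes_duration=round(float(duration[i]), 1),
            cognition_normal=bool(cognition[i]),
        ))
    return profiles


# ---------------------------------------------------------------------------
# motor control

def motor_params_from_latent(foot: FootLatent, cfg: GeneratorConfig,
                             rng) -> MotorControlParams:
    """Map latent deficits to control quality (plus individual jitter)."""
    if cfg.null_motor:
        small = large = mix = 0.0
    else:
        small = foot.small_fiber_deficit
        large = foot.large_fiber_deficit
        mix = 0.5 * (small + large)
    # individual jitter reflects between-subject variability of healthy
    # motor control (reaction times alone vary by tens of ms)
    s = cfg.effect_scale
    latency = np.clip(cfg.latency_base + s * cfg.latency_gain * mix
                      + rng.normal(0.0, 0.06), 0.05, 1.5)
    noise = np.clip(cfg.noise_base + s * cfg.noise_gain * mix
                    + rng.normal(0.0, 0.006), 0.002, 0.35)
    deadband = np.clip(cfg.deadband_base + s * cfg.deadband_gain * small
                       + rng.normal(0.0, 0.005), 0.0, 0.35)
    force = np.clip(1.0 - s * cfg.force_loss * large
                    + rng.normal(0.0, 0.03), 0.45, 1.0)
    fatigue = max(0.0, cfg.fatigue_base + s * cfg.fatigue_gain * large
                  + rng.normal(0.0, 0.003))
    return MotorControlParams(float(latency), float(noise), float(deadband),
                              float(force), float(fatigue), cfg.tremor_freq)


def sample_cohort(n: int, config: GeneratorConfig | None = None,
                  seed: int = 0) -> list[Participant]:
    """Generate ``n`` virtual participants (profiles, latents, motor
    parameters).  Fully reproducible from (n, config, seed)."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    cfg = config or GeneratorConfig()
    p_d, q = calibrate_generator(cfg)
    rng = np.random.default_rng(seed)
    small, large, burden, _ = _sample_latent_arrays(n, p_d, q, cfg, rng)
    profiles = _sample_profiles(n, rng)
    cohort = []
    for i in range(n):
        latent = LatentNeuropathy(
            FootLatent(float(small[i, 0]), float(large[i, 0]),
                       float(burden[i])),
            FootLatent(float(small[i, 1]), float(large[i, 1]),
                       float(burden[i])),
        )
        motor = {side: motor_params_from_latent(latent.foot(side), cfg, rng)
                 for side in FEET}
        cohort.append(Participant(profiles[i], latent, motor))
    return cohort


def cohort_manifest(cohort: list[Participant]) -> pd.DataFrame:
    """One row per participant (CSV-ready)."""
    rows = []
    for p in cohort:
        row = asdict(p.profile)
        for side in FEET:
            f = p.latent.foot(side)
            row[f"severity_{side}"] = round(f.severity, 4)
            row[f"small_fiber_{side}"] = round(f.small_fiber_deficit, 4)
            row[f"large_fiber_{side}"] = round(f.large_fiber_deficit, 4)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nerve conduction studies

def sample_ncs(latent: LatentNeuropathy, seed,
               config: GeneratorConfig | None = None) -> NcsRecord:
    """NCV/amplitude decline linearly in the large-fiber deficit."""
    cfg = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    feet = {}
    for side in FEET:
        large = latent.foot(side).large_fiber_deficit
        vals = {}
        for name, (base, decline, sd) in (
                ("sural_sensory_ncv", cfg.sural_ncv),
                ("sural_sensory_amplitude", cfg.sural_amp),
                ("tibial_motor_ncv", cfg.tibial_ncv),
                ("tibial_motor_amplitude", cfg.tibial_amp)):
            vals[name] = max(0.0, base - decline * large
                             + rng.normal(0.0, sd))
        complete = bool(rng.random() >= cfg.ncs_missing)
        if not complete:
            vals = {k: None for k in vals}
        feet[side] = NcsFoot(complete=complete, **vals)
    return NcsRecord(feet["left"], feet["right"])


# ---------------------------------------------------------------------------
# closed-loop player

_NOISE_TAU_S = 0.15  # correlation time of the motor noise process

_FORE_IDX = tuple(CHANNELS.index(c) for c in FOREFOOT_CHANNELS)
_HEEL_IDX = tuple(CHANNELS.index(c) for c in HEEL_CHANNELS)


def _track(target: np.ndarray, task_onsets_idx, params: MotorControlParams,
           rate: float, t_offset: float, rng) -> np.ndarray:
    """Track a region target trajectory with the participant's motor
    limitations: per-task sensing offsets, fatigue droop, dead time,
    first-order lag, correlated noise with tremor, and a force ceiling.
    Releases (target back to zero) are ballistic, not lagged."""
    n = len(target)
    dt = 1.0 / rate
    t = np.arange(n) * dt + t_offset
    perceived = target.copy()
    if params.sensing_deadband > 0:
        bounds = np.asarray(list(task_onsets_idx) + [n])
        lengths = np.diff(bounds)
        offsets = rng.uniform(-params.sensing_deadband,
                              params.sensing_deadband, len(lengths))
        offset_arr = np.repeat(offsets, lengths)
        if bounds[0] > 0:
            offset_arr = np.concatenate([np.zeros(bounds[0]), offset_arr])
        active = perceived > 0
        perceived[active] = np.maximum(perceived[active]
                                       + offset_arr[active], 0.0)
    droop = 1.0 - np.clip(params.fatigue_rate * t / 60.0, 0.0, 0.4)
    perceived = perceived * droop
    k = int(round(params.reaction_latency * rate))
    if k > 0:
        perceived = np.concatenate([np.zeros(k), perceived[:-k]])
    tau = 0.5 * params.reaction_latency
    if tau > 0:
        alpha = 1.0 - np.exp(-dt / tau)
        y = lfilter([alpha], [1.0, -(1.0 - alpha)], perceived)
    else:
        y = perceived.copy()
    active = perceived > 1e-9
    y *= active  # stop pressing is immediate
    if params.pressure_noise_sd > 0:
        phi = np.exp(-dt / _NOISE_TAU_S)
        innov = rng.normal(0.0, params.pressure_noise_sd * np.sqrt(1 - phi ** 2), n)
        noise = lfilter([1.0], [1.0, -phi], innov)
        if params.tremor_freq > 0:
            noise = noise + 0.5 * params.pressure_noise_sd * np.sin(
                2 * np.pi * params.tremor_freq * t + rng.uniform(0, 2 * np.pi))
        y = y + noise * active
    return np.clip(y, 0.0, params.max_force_fraction)


def simulate_player(params: dict, game: str, seed,
                    rate: float | None = None, t_offset: float = 0.0,
                    config: GeneratorConfig | None = None) -> dict:
    """Simulate one game being played; ``params`` maps foot ->
    :class:`MotorControlParams`.  Returns normalized per-foot streams."""
    cfg = config or GeneratorConfig()
    rate = rate or cfg.rate_hz
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    targets, spec = ideal_targets(game, rate)
    onsets = [int(round(task.t_onset * rate)) for task in spec.tasks]
    streams = {}
    for foot in FEET:
        n = len(targets[foot]["forefoot"])
        values = np.zeros((n, len(CHANNELS)))
        for region, idx in (("forefoot", _FORE_IDX), ("heel", _HEEL_IDX)):
            tgt = targets[foot][region]
            if not np.any(tgt):
                continue
            y = _track(tgt, onsets, params[foot], rate, t_offset, rng)
            for j in idx:
                values[:, j] = y
        streams[foot] = PressureStream(values, rate=rate, foot=foot,
                                       normalized=True)
    return streams
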