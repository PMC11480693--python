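"""End-to-end study pipeline on virtual cohorts.

``simulate_session`` renders one participant's full gaming session
(closed-loop player -> optional raw-mbar round trip through calibration ->
game engines -> feature extraction); ``simulate_cohort_study`` produces
the cohort-level feature table, clinical labels and capability scores; and
``run_pnp_pipeline`` trains and evaluates the per-foot binary PNP models
(stratified 3:7 hold-out) plus the multiclass phenotype models
(repeated-CV only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationProfile,
    N_CHANNELS,
    denormalize,
    normalize,
)
from .capabilities import CapabilityScores, score_capabilities
from .clinical import ClinicalExam, PnpStatus, pnp_status
from .errors import DegenerateInputError
from .features import FEET, GameSession, extract_features, feature_table
from .games import GAMES, play_session
from .modeling import (
    EvalReport,
    PhenotypeClassifier,
    PhenotypeResults,
    PipelineConfig,
    PnpClassifier,
    PnpClassifierResults,
)
from .synthetic import (
    GeneratorConfig,
    Participant,
    sample_clinical_exam,
    sample_cohort,
    sample_ncs,
    simulate_player,
)


def _synthetic_calibration(rng) -> CalibrationProfile:
    """A plausible per-participant raw-pressure calibration profile."""
    prof = CalibrationProfile()
    for foot in FEET:
        prof.p_min[foot] = rng.uniform(260.0, 330.0, N_CHANNELS)
        prof.p_max[foot] = rng.uniform(4200.0, 6500.0, N_CHANNELS)
    return prof


def simulate_session(participant: Participant,
                     config: GeneratorConfig | None = None,
                     seed=0, rate: float | None = None,
                     raw_round_trip: bool = False) -> GameSession:
    """Simulate the four-game session of one participant.

    With ``raw_round_trip`` the normalized player output is mapped to raw
    mbar with a synthetic calibration profile and re-normalized through the
    calibration path, exercising the full acquisition chain.
    """
    cfg = config or GeneratorConfig()
    rate = rate or cfg.rate_hz
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    profile = _synthetic_calibration(rng) if raw_round_trip else None
    streams, t_offset = {}, 0.0
    for game in GAMES:
        s = simulate_player(participant.motor, game, rng, rate=rate,
                            t_offset=t_offset, config=cfg)
        if raw_round_trip:
            s = {foot: normalize(denormalize(st, profile), profile)
                 for foot, st in s.items()}
        streams[game] = s
        t_offset += s["left"].duration
    results = play_session(streams)
    session = GameSession(streams, results,
                          participant_id=participant.profile.participant_id)
    for game in GAMES:
        session.log.extend(results[game].log)
    return session


@dataclass
class CohortStudy:
    """A fully simulated study: cohort, labels, features, capabilities."""

    cohort: list[Participant]
    exams: list[ClinicalExam]
    statuses: list[PnpStatus]
    features: pd.DataFrame            # rows = (participant, foot)
    capabilities: list[CapabilityScores]
    game_scores: list[dict]
    ncs: list = field(default_factory=list)

    def foot_table(self, foot: str) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
        """(features, pnp labels, phenotype labels) for one foot side."""
        x = self.features.xs(foot, level="foot").dropna(axis=1, how="all")
        y = np.array([s.pnp[foot] for s in self.statuses], dtype=int)
        ph = np.array([s.phenotype[foot] for s in self.statuses])
        return x, y, ph


def simulate_cohort_study(n: int, config: GeneratorConfig | None = None,
                          seed: int = 0, rate: float | None = None,
                          with_ncs: bool = False) -> CohortStudy:
    """Simulate a complete cohort: exams, sessions, features, labels."""
    cfg = config or GeneratorConfig()
    cohort = sample_cohort(n, cfg, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    exams, statuses, sessions = [], [], []
    capabilities, game_scores, ncs = [], [], []
    for p in cohort:
        exam = sample_clinical_exam(p.latent, rng, cfg)
        exams.append(exam)
        statuses.append(pnp_status(exam))
        if with_ncs:
            ncs.append(sample_ncs(p.latent, rng, cfg))
        session = simulate_session(p, cfg, rng, rate=rate)
        sessions.append(session)
        scores = {g: session.results[g].score for g in session.results}
        game_scores.append(scores)
        capabilities.append(score_capabilities(extract_features(session),
                                               scores))
    table = feature_table(sessions)
    return CohortStudy(cohort, exams, statuses, table, capabilities,
                       game_scores, ncs)


@dataclass
class PipelineReport:
    binary: dict[str, PnpClassifierResults]
    multiclass: dict[str, PhenotypeResults]

    def summary(self) -> str:
        parts = []
        for foot, res in self.binary.items():
            parts.append(f"--- {foot} foot ---")
            parts.append(res.summary())
        for foot, res in self.multiclass.items():
            parts.append(f"--- {foot} foot (phenotype) ---")
            parts.append(res.summary())
        return "\n".join(parts)


def run_pnp_pipeline(study: CohortStudy,
                     config: PipelineConfig | None = None,
                     seed: int = 0,
                     multiclass: bool = True) -> PipelineReport:
    """Per-foot binary PNP models with held-out evaluation, plus (optional)
    multiclass phenotype models evaluated by repeated CV on all data."""
    cfg = config or PipelineConfig()
    binary, multi = {}, {}
    for foot in FEET:
        x, y, ph = study.foot_table(foot)
        if len(np.unique(y)) < 2:
            raise DegenerateInputError(f"{foot}: single-class PNP labels")
        binary[foot] = PnpClassifier(x, y, cfg).fit(seed)
        if multiclass and len(np.unique(ph)) >= 2:
            multi[foot] = PhenotypeClassifier(x, ph, cfg).fit(seed)
    return PipelineReport(binary, multi)
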