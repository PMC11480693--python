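"""Six hypothesis-driven key-capability scores on [0, 1].

reaction time (speed of immediate task responses), sensation (precision of
pressure application), skillfulness (overall game achievement), muscle
strength (success in high-pressure tasks), balance (left/right performance
symmetry) and endurance (consistency of pressure control over the
session).  Each underlying metric is mapped to [0, 1] by a fixed clamped
linear map whose anchor points were frozen from reference simulations: the
ideal player defines the "perfect" end (score 1), a zero-effort/maximally
impaired reference the floor.  1 = perfect performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureVector
from .games.constants import GAME_MAX_SCORE
from .games.programs import game_spec

CAPABILITY_AXES = ("reaction_time", "sensation", "skillfulness",
                   "muscle_strength", "balance", "endurance")

# (best, worst) anchors of the underlying metrics; "best" reproduces the
# ideal-player simulation with margin, "worst" the zero-effort floor
ANCHORS = {
    "reaction_time": (0.85, 8.0),    # s, mean anticipation/reaction
    "sensation": (0.02, 0.45),       # mean deviation, normalized pressure
    "balance": (0.01, 0.60),         # |left - right| success-rate gap
    "endurance": (0.0, 20.0),        # s, late-session out-of-band burden
}

TIER_CUTS = (("expert", 0.85), ("advanced", 0.65), ("average", 0.40),
             ("beginner", -np.inf))


@dataclass(frozen=True)
class CapabilityScores:
    reaction_time: float
    sensation: float
    skillfulness: float
    muscle_strength: float
    balance: float
    endurance: float
    tier: str

    def as_dict(self) -> dict:
        return {axis: getattr(self, axis) for axis in CAPABILITY_AXES}

    @property
    def mean_score(self) -> float:
        vals = [v for v in self.as_dict().values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan


def _lower_better(value: float, axis: str) -> float:
    best, worst = ANCHORS[axis]
    if not np.isfinite(value):
        return np.nan
    return float(np.clip((worst - value) / (worst - best), 0.0, 1.0))


def _vals(vec: FeatureVector, ids) -> np.ndarray:
    got = vec.values.reindex(ids).to_numpy(float)
    return got[np.isfinite(got)]


def _task_ids(game: str, level_key: str, levels) -> list[int]:
    spec = game_spec(game)
    return [t.task_id for t in spec.tasks if t.params.get(level_key) in levels]


def _tier(mean_score: float) -> str:
    for name, cut in TIER_CUTS:
        if mean_score >= cut:
            return name
    return "beginner"


def score_capabilities(vectors: dict[str, FeatureVector],
                       game_scores: dict[str, int]) -> CapabilityScores:
    """Compute the six capability scores from per-foot feature vectors and
    the four game scores.  Metrics whose source game is missing come out
    NaN (not available)."""
    left, right = vectors["left"], vectors["right"]

    # reaction: mean over AC reaction times, CP/IJ anticipation times
    parts = [_vals(left, [f"AC.T{t:02d}.reaction_time"
                          for t in range(1, 15)])]
    for vec in (left, right):
        parts.append(_vals(vec, [c for c in vec.values.index
                                 if c.endswith(".anticipation_time")
                                 and c.count(".") == 2]))
    reaction_vals = np.concatenate(parts) if parts else np.array([])
    reaction = (_lower_better(float(np.mean(reaction_vals)), "reaction_time")
                if reaction_vals.size else np.nan)

    # sensation: precision of pressure application
    sens_parts = []
    sens_parts.append(_vals(left, [f"AC.T{t:02d}.capture_error"
                                   for t in range(1, 15)]))
    for vec in (left, right):
        sens_parts.append(_vals(vec, [c for c in vec.values.index
                                      if c.endswith(".deviation")
                                      and c.count(".") == 2]))
        sens_parts.append(_vals(vec, [c for c in vec.values.index
                                      if c.endswith(".min_smiley_distance")
                                      and c.count(".") == 2]))
    sens_vals = np.concatenate(sens_parts)
    sensation = (_lower_better(float(np.mean(sens_vals)), "sensation")
                 if sens_vals.size else np.nan)

    # skillfulness: total achievement over the session
    if game_scores:
        total = sum(game_scores.get(g, 0) for g in GAME_MAX_SCORE)
        maximum = sum(GAME_MAX_SCORE[g] for g in GAME_MAX_SCORE
                      if g in game_scores) or np.nan
        skillfulness = float(np.clip(total / maximum, 0.0, 1.0))
    else:
        skillfulness = np.nan

    # strength: success in high-pressure tasks (CP high bands, IJ high
    # targets)
    strength_vals = []
    cp_high = _task_ids("CP", "level", {"high"})
    ij_high = _task_ids("IJ", "level", {"high"})
    for vec in (left, right):
        strength_vals.append(_vals(vec, [f"CP.T{t:02d}.success"
                                         for t in cp_high]))
        strength_vals.append(_vals(vec, [f"IJ.T{t:02d}.success"
                                         for t in ij_high]))
    sv = np.concatenate(strength_vals)
    muscle_strength = float(np.mean(sv)) if sv.size else np.nan

    # balance: symmetry of per-side success rates
    def side_rate(vec):
        ids = [c for c in vec.values.index
               if c.count(".") == 2 and (c.endswith(".success")
                                         or c.endswith(".collected"))]
        v = _vals(vec, ids)
        return float(np.mean(v)) if v.size else np.nan
    lr, rr = side_rate(left), side_rate(right)
    balance = _lower_better(abs(lr - rr), "balance") \
        if np.isfinite(lr) and np.isfinite(rr) else np.nan

    # endurance: how well pressure control holds up late in the session —
    # the out-of-band burden over the final quarter of the (long, late)
    # steady-pressure tasks; a late-minus-early drift would saturate once
    # early performance is already at the floor
    cp_series = []
    for t in [t.task_id for t in game_spec("CP").tasks]:
        for vec in (left, right):
            val = vec.values.get(f"CP.T{t:02d}.time_outside_zone", np.nan)
            if np.isfinite(val):
                cp_series.append(val)
                break
    if len(cp_series) >= 8:
        k = len(cp_series) // 4
        endurance = _lower_better(float(np.mean(cp_series[-k:])),
                                  "endurance")
    else:
        endurance = np.nan

    scores = dict(reaction_time=reaction, sensation=sensation,
                  skillfulness=skillfulness, muscle_strength=muscle_strength,
                  balance=balance, endurance=endurance)
    finite = [v for v in scores.values() if np.isfinite(v)]
    tier = _tier(float(np.mean(finite))) if finite else "beginner"
    return CapabilityScores(tier=tier, **scores)


def spider_chart_data(scores: CapabilityScores) -> list[tuple[str, float | None]]:
    """Axis/value pairs in the fixed axis order; NaN becomes None."""
    out = []
    for axis in CAPABILITY_AXES:
        v = getattr(scores, axis)
        out.append((axis, float(v) if np.isfinite(v) else None))
    return out
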