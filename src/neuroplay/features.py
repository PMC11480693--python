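"""Primary and secondary game-feature extraction.

Primary features are per-task game parameters (timings, pressures and
game-specific measures); secondary features are the sum, mean and sample
SD of a primary parameter over the member tasks of a task combination
(TC).  One feature vector is produced per foot per session; its key set
is the fixed canonical catalog (``feature_catalog``), with unobtainable
measurements encoded as NaN (explicitly not-available, never dropped).

Feature id grammar::

    GAME.T{kk}.param            primary, e.g.  CP.T03.anticipation_time
    GAME.TC{L|R}{n}.stat.param  secondary, e.g. IJ.TCL2.mean.deviation
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .calibration import PressureStream
from .errors import GameError, NeuroplayError
from .events import SessionLog
from .games.combos import foot_task_ids, get_task_combinations
from .games.constants import GAME_CONSTANTS, GAMES
from .games.engine import GameResult, TaskOutcome
from .games.programs import game_spec

logger = logging.getLogger(__name__)

CATALOG_VERSION = "1.0"

FEET = ("left", "right")

PRESSURE_PARAMS = ("normalized_pressure", "pressure_difference",
                   "pressure_gradient", "pressure_time_integral")

PRIMARY_PARAMS = {
    "AC": ("success", "reaction_time", "time_to_target", "hold_stability",
           "overshoot_count", "capture_error", "tracking_error")
          + PRESSURE_PARAMS,
    "BF": ("collected", "min_smiley_distance", "collision_count",
           "restart_count") + PRESSURE_PARAMS,
    "CP": ("success", "anticipation_time", "time_outside_zone",
           "relaxation_time") + PRESSURE_PARAMS,
    "IJ": ("success", "attempts", "deviation", "anticipation_time",
           "execution_time", "execution_mean_pressure") + PRESSURE_PARAMS,
}

# sentinel for timed-out/failed timing measurements = the task's maximum
# duration ("slower is worse" is preserved for modeling)
TASK_MAX_DURATION = {g: GAME_CONSTANTS[g]["task_duration_s"] for g in GAMES}
TASK_MAX_DURATION["AC"] = GAME_CONSTANTS["AC"]["fall_duration_s"]


@dataclass
class FeatureVector:
    foot: str
    values: pd.Series
    catalog_version: str = CATALOG_VERSION

    @property
    def available(self) -> pd.Series:
        return self.values.notna()


@dataclass
class GameSession:
    """Everything the extractor needs: normalized streams and engine
    results, per game."""

    streams: dict[str, dict[str, PressureStream]]
    results: dict[str, GameResult]
    participant_id: str = ""
    log: SessionLog = field(default_factory=SessionLog)


def task_pressure_features(window: np.ndarray, rate: float) -> dict:
    """The four pressure parameters of a task window.

    mean pressure; max - min; max absolute per-sample gradient (1/s); and
    the trapezoidal pressure-time integral (s).
    """
    window = np.asarray(window, float)
    if window.size == 0:
        raise GameError("empty task window")
    grad = float(np.max(np.abs(np.diff(window))) * rate) if window.size > 1 else 0.0
    return {
        "normalized_pressure": float(np.mean(window)),
        "pressure_difference": float(np.ptp(window)),
        "pressure_gradient": grad,
        "pressure_time_integral": float(np.trapezoid(window, dx=1.0 / rate)),
    }


def task_timing_features(outcome: TaskOutcome, log: SessionLog) -> dict:
    """Timing features of one task, cross-checked against the log.

    Reaction time is the onset-to-first-sustained-response latency (the
    engine detects a pressure change >= 0.05 lasting >= 50 ms); failed or
    timed-out measurements carry the task's maximum duration as sentinel
    and are flagged through the companion ``*_available`` entries of the
    outcome measurements.
    """
    if not log.for_task(outcome.game, outcome.task_id).events:
        raise GameError(
            f"outcome {outcome.game}.T{outcome.task_id} not present in log")
    sentinel = TASK_MAX_DURATION[outcome.game]
    if outcome.t_first_response is None:
        reaction = sentinel
    else:
        reaction = outcome.t_first_response - outcome.t_onset
    out = {"reaction_time": float(reaction)}
    m = outcome.measurements
    for key in ("anticipation_time", "time_outside_zone", "relaxation_time",
                "execution_time", "time_to_target"):
        if key in m:
            out[key] = float(m[key])
    return out


def task_game_specific_features(outcome: TaskOutcome) -> dict:
    """Per-game extras taken from the engine's task measurements."""
    m = outcome.measurements
    keys = {
        "AC": ("success", "hold_stability", "overshoot_count",
               "capture_error", "tracking_error"),
        "BF": ("collected", "min_smiley_distance", "collision_count",
               "restart_count"),
        "CP": ("success",),
        "IJ": ("success", "attempts", "deviation", "execution_mean_pressure"),
    }[outcome.game]
    return {k: float(m[k]) for k in keys if k in m}


def aggregate_secondary(primary: dict, tc) -> dict:
    """sum/mean/SD of each primary parameter over a TC's member tasks.

    ``primary`` maps parameter -> {task_id -> value}; not-available (NaN)
    members are excluded (their count is logged); a TC left with no
    members yields NaN aggregates; a single member yields SD 0.
    """
    out = {}
    for param, by_task in primary.items():
        vals = np.asarray([by_task.get(t, np.nan) for t in tc.member_task_ids],
                          float)
        ok = np.isfinite(vals)
        n_excluded = int((~ok).sum())
        if n_excluded:
            logger.debug("TC %s param %s: %d member(s) not available",
                         tc.id, param, n_excluded)
        v = vals[ok]
        if v.size == 0:
            s = m = sd = np.nan
        else:
            s = float(np.sum(v))
            m = float(np.mean(v))
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        out[f"{tc.id}.sum.{param}"] = s
        out[f"{tc.id}.mean.{param}"] = m
        out[f"{tc.id}.sd.{param}"] = sd
    return out


def _controlling_signal(game: str, task, foot: str,
                        streams: dict) -> tuple[np.ndarray, float]:
    """The pressure signal a task's features are computed on, for this
    foot's feature vector, over the task's time span."""
    p = task.params
    if game == "CP":
        stream = streams[p["foot"]]
        sig = stream.region(p["region"])
    else:
        stream = streams[foot]
        sig = stream.region("forefoot")
    rate = stream.rate
    dur = (GAME_CONSTANTS["AC"]["fall_duration_s"] if game == "AC"
           else GAME_CONSTANTS[game]["task_duration_s"])
    i0 = int(round(task.t_onset * rate))
    i1 = i0 + int(round(dur * rate))
    return sig[i0:i1], rate


def extract_foot_features(session: GameSession, foot: str) -> FeatureVector:
    values: dict[str, float] = {}
    for game in GAMES:
        spec = game_spec(game)
        scope = foot_task_ids(game, foot)
        scope_set = set(scope)
        present = game in session.results
        if not present:
            logger.warning("session %s: game %s missing; features flagged "
                           "not available", session.participant_id, game)
        outcomes = ({o.task_id: o for o in session.results[game].outcomes}
                    if present else {})
        log = session.results[game].log if present else SessionLog()
        params = PRIMARY_PARAMS[game]
        pos = {tid: k for k, tid in enumerate(scope)}
        mat = np.full((len(scope), len(params)), np.nan)
        for task in spec.tasks:
            if task.task_id not in scope_set:
                continue
            feats: dict[str, float] = {}
            if present:
                out = outcomes[task.task_id]
                feats.update(task_timing_features(out, log))
                feats.update(task_game_specific_features(out))
                sig, rate = _controlling_signal(game, task,
                                                foot, session.streams[game])
                feats.update(task_pressure_features(sig, rate))
            for pi, param in enumerate(params):
                val = feats.get(param, np.nan)
                values[f"{game}.T{task.task_id:02d}.{param}"] = val
                mat[pos[task.task_id], pi] = val
        # TC aggregation, vectorized over the parameter axis
        for tc in get_task_combinations(game, foot):
            sub = mat[[pos[t] for t in tc.member_task_ids]]
            ok = np.isfinite(sub)
            cnt = ok.sum(axis=0)
            with np.errstate(invalid="ignore"):
                s = np.where(cnt > 0, np.nansum(sub, axis=0), np.nan)
                m = s / np.where(cnt > 0, cnt, 1)
                m = np.where(cnt > 0, m, np.nan)
                sq = np.where(cnt > 1,
                              (np.nansum(sub ** 2, axis=0) - cnt * m ** 2)
                              / np.maximum(cnt - 1, 1), 0.0)
                sd = np.where(cnt > 0, np.sqrt(np.maximum(sq, 0.0)), np.nan)
            for pi, param in enumerate(params):
                values[f"{tc.id}.sum.{param}"] = s[pi]
                values[f"{tc.id}.mean.{param}"] = m[pi]
                values[f"{tc.id}.sd.{param}"] = sd[pi]
    catalog = feature_catalog(foot)
    series = pd.Series(values, dtype=float).reindex(catalog)
    return FeatureVector(foot, series)


def extract_features(session: GameSession) -> dict[str, FeatureVector]:
    """One feature vector per foot; a pure function of the session."""
    return {foot: extract_foot_features(session, foot) for foot in FEET}


@lru_cache(maxsize=4)
def _feature_catalog_cached(foot: str) -> tuple[str, ...]:
    return tuple(_build_catalog(foot))


def feature_catalog(foot: str) -> list[str]:
    """The canonical, exhaustive feature id list for one foot."""
    return list(_feature_catalog_cached(foot))


def _build_catalog(foot: str) -> list[str]:
    ids = []
    for game in GAMES:
        for task_id in foot_task_ids(game, foot):
            for param in PRIMARY_PARAMS[game]:
                ids.append(f"{game}.T{task_id:02d}.{param}")
        for tc in get_task_combinations(game, foot):
            for param in PRIMARY_PARAMS[game]:
                for stat in ("sum", "mean", "sd"):
                    ids.append(f"{tc.id}.{stat}.{param}")
    if len(set(ids)) != len(ids):
        raise NeuroplayError("feature catalog contains duplicate ids")
    return ids


def catalog_manifest(foot: str = "left") -> pd.DataFrame:
    """Catalog as a table: id, game, scope, statistic, parameter."""
    rows = []
    for fid in feature_catalog(foot):
        parts = fid.split(".")
        if len(parts) == 3:
            game, scope, param = parts
            stat = "value"
        else:
            game, scope, stat, param = parts
        rows.append({"id": fid, "game": game, "scope": scope,
                     "statistic": stat, "parameter": param})
    return pd.DataFrame(rows)


def feature_table(sessions: list[GameSession]) -> pd.DataFrame:
    """Rows = participant x foot, columns = feature ids."""
    rows, index = [], []
    for s in sessions:
        vecs = extract_features(s)
        for foot in FEET:
            rows.append(vecs[foot].values)
            index.append((s.participant_id, foot))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index,
                                              names=["participant", "foot"]))
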