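"""Deterministic state machines for the four games.

Each ``play_*`` function consumes normalized pressure streams, replays the
fixed task program against them, and emits a :class:`SessionLog`, one
:class:`TaskOutcome` per task and the game score.  The engines are pure
functions of the streams: identical input yields identical logs and
scores.  Every ``task_end`` event carries the full outcome payload, so
outcomes are reconstructible from the log alone
(:func:`outcomes_from_log`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..calibration import PressureStream
from ..errors import GameError
from ..events import SessionLog
from .constants import GAME_CONSTANTS, GAMES
from .programs import GameSpec, game_spec

TIMEOUT = "timeout"  # sentinel marker in event payloads


@dataclass
class TaskOutcome:
    game: str
    task_id: int
    success: bool
    attempts: int
    t_onset: float
    t_first_response: float | None
    t_complete: float
    measurements: dict[str, Any] = field(default_factory=dict)

    def payload(self) -> dict:
        return {
            "success": self.success,
            "attempts": self.attempts,
            "t_onset": self.t_onset,
            "t_first_response": self.t_first_response,
            "t_complete": self.t_complete,
            "measurements": {k: (None if v is None else float(v) if
                                 isinstance(v, (int, float, np.floating, np.integer))
                                 else v)
                             for k, v in self.measurements.items()},
        }


@dataclass
class GameResult:
    game: str
    log: SessionLog
    outcomes: list[TaskOutcome]
    score: int


def _check_streams(spec: GameSpec, *streams: PressureStream) -> float:
    rates = {s.rate for s in streams}
    if len(rates) != 1:
        raise GameError("streams have mismatched sampling rates")
    rate = rates.pop()
    for s in streams:
        if s.duration + 0.5 / rate < spec.duration:
            raise GameError(
                f"{spec.game}: stream of {s.duration:.2f}s shorter than the "
                f"game program ({spec.duration:.2f}s)")
    return rate


def _causal_ma(x: np.ndarray, k: int) -> np.ndarray:
    """Trailing moving average with window k samples (k >= 1)."""
    if k <= 1:
        return x
    c = np.cumsum(np.insert(x, 0, 0.0))
    out = np.empty_like(x)
    out[k - 1:] = (c[k:] - c[:-k]) / k
    # warm-up: average over what is available
    for i in range(min(k - 1, len(x))):
        out[i] = c[i + 1] / (i + 1)
    return out


def _first_sustained(mask: np.ndarray, n_sustained: int) -> int | None:
    """Index of the first run of True of length >= n_sustained, else None."""
    if not mask.any():
        return None
    if n_sustained <= 1:
        return int(np.argmax(mask))
    if len(mask) < n_sustained:
        return None
    c = np.cumsum(np.insert(mask.astype(np.int64), 0, 0))
    run = c[n_sustained:] - c[:-n_sustained]  # window sums
    hits = np.flatnonzero(run == n_sustained)
    return int(hits[0]) if hits.size else None


def first_response_index(signal: np.ndarray, rate: float,
                         threshold: float = 0.05,
                         sustain_s: float = 0.05) -> int | None:
    """First sample where the signal deviates from its initial value by at
    least ``threshold`` for ``sustain_s`` continuously (reaction onset)."""
    dev = np.abs(signal - signal[0]) >= threshold
    return _first_sustained(dev, max(1, int(round(sustain_s * rate))))


# ---------------------------------------------------------------------------
# Apple Catch

def play_apple_catch(left: PressureStream, right: PressureStream) -> GameResult:
    """Carriage x(t) = clamp(pR_fore - pL_fore, -1, 1), 100 ms smoothed.

    A task succeeds when the carriage stays within the catch band around
    the apple for the entire final capture window of the fall; the
    carriage resets to center between tasks (the program's inter-task gap).
    """
    spec = game_spec("AC")
    c = GAME_CONSTANTS["AC"]
    rate = _check_streams(spec, left, right)
    x = np.clip(right.region("forefoot") - left.region("forefoot"), -1.0, 1.0)
    x = _causal_ma(x, max(1, int(round(c["smooth_window_s"] * rate))))

    log, outcomes = SessionLog(), []
    band = c["catch_band"]
    fall_n = int(round(c["fall_duration_s"] * rate))
    cap_n = int(round(c["capture_window_s"] * rate))
    for task in spec.tasks:
        apple = task.params["apple_x"]
        i0 = int(round(task.t_onset * rate))
        xs = x[i0:i0 + fall_n]
        log.append(task.t_onset, "AC", task.task_id, "task_start",
                   apple_x=apple)
        dist = np.abs(xs - apple)
        cap = dist[-cap_n:]
        success = bool(np.all(cap <= band))
        in_band_i = np.flatnonzero(dist <= band)
        t_target = (task.t_onset + in_band_i[0] / rate if in_band_i.size
                    else None)
        # overshoots: sign flips of the tracking error after first reaching
        # the band; a small hysteresis keeps numerically-zero error from
        # registering as crossings
        overshoot = 0
        if in_band_i.size:
            err = xs[in_band_i[0]:] - apple
            err = err[np.abs(err) > 0.005]
            overshoot = int(np.sum(np.abs(np.diff(np.sign(err))) == 2))
        fr = first_response_index(xs, rate)
        meas = {
            "success": float(success),
            "time_to_target": (t_target - task.t_onset if t_target is not None
                               else c["fall_duration_s"]),
            "time_to_target_available": t_target is not None,
            "hold_stability": float(np.std(xs[-cap_n:])),
            "overshoot_count": float(overshoot),
            "capture_error": float(np.mean(cap)),
            "tracking_error": float(np.mean(dist)),
            "apple_x": apple,
        }
        t_end = task.t_onset + c["fall_duration_s"]
        log.append(t_end, "AC", task.task_id,
                   "apple_caught" if success else "apple_missed")
        log.append(t_end, "AC", task.task_id, "carriage_reset")
        out = TaskOutcome("AC", task.task_id, success, 1, task.t_onset,
                          task.t_onset + fr / rate if fr is not None else None,
                          t_end, meas)
        log.append(t_end, "AC", task.task_id, "task_end", **out.payload())
        outcomes.append(out)
    score = sum(o.success for o in outcomes)
    log.append(spec.duration - 0.5 / rate, "AC", None, "game_end", score=score)
    return GameResult("AC", log, outcomes, score)


# ---------------------------------------------------------------------------
# Balloon Flying

def play_balloon_flying(left: PressureStream, right: PressureStream) -> GameResult:
    """Altitude h(t) = assigned foot's forefoot pressure (0 = ground).

    The balloon collides when it is below the obstacle top while passing
    the obstacle; an uncorrected collision (never climbing clear within
    5 s) triggers an automatic restart and fails the task.  A smiley is
    collected when the balloon passes within the altitude band at the
    smiley's position.
    """
    spec = game_spec("BF")
    c = GAME_CONSTANTS["BF"]
    rate = _check_streams(spec, left, right)
    feet = {"left": left.region("forefoot"), "right": right.region("forefoot")}

    log, outcomes = SessionLog(), []
    for task in spec.tasks:
        p = task.params
        h = feet[p["foot"]]
        i0 = int(round(task.t_onset * rate))
        n = int(round(spec.task_duration * rate))
        hs = h[i0:i0 + n]
        log.append(task.t_onset, "BF", task.task_id, "task_start",
                   foot=p["foot"], obstacle=p["obstacle"],
                   smiley_h=p["smiley_h"])
        obs_h = p["obstacle_h"]
        w0, w1 = c["obstacle_window_s"]
        j0, j1 = int(round(w0 * rate)), int(round(w1 * rate))
        below = hs[j0:j1] < obs_h
        collisions = 0
        restarted = False
        if below.any():
            entries = np.flatnonzero(np.diff(np.concatenate(([0],
                                     below.astype(np.int8)))) == 1)
            collisions = int(entries.size)
            first = j0 + int(entries[0])
            t_coll = task.t_onset + first / rate
            log.append(t_coll, "BF", task.task_id, "collision",
                       obstacle=p["obstacle"])
            # corrective measure = climbing clear of the obstacle
            deadline = first + int(round(c["collision_restart_s"] * rate))
            clear = np.flatnonzero(hs[first:min(deadline, n)] >= obs_h)
            if not clear.size and deadline <= n:
                restarted = True
                log.append(task.t_onset + deadline / rate, "BF",
                           task.task_id, "restart")
        k0 = int(round((c["smiley_time_s"] - c["smiley_window_s"]) * rate))
        k1 = int(round((c["smiley_time_s"] + c["smiley_window_s"]) * rate))
        min_dist = float(np.min(np.abs(hs[k0:k1] - p["smiley_h"])))
        collected = (not restarted) and min_dist <= c["smiley_band"]
        fr = first_response_index(hs, rate)
        meas = {
            "collected": float(collected),
            "min_smiley_distance": min_dist,
            "collision_count": float(collisions),
            "restart_count": float(restarted),
        }
        t_end = task.t_onset + spec.task_duration - 0.5 / rate
        if collected:
            log.append(task.t_onset + c["smiley_time_s"], "BF", task.task_id,
                       "smiley_collected")
        out = TaskOutcome("BF", task.task_id, collected, 1 + int(restarted),
                          task.t_onset,
                          task.t_onset + fr / rate if fr is not None else None,
                          t_end, meas)
        log.append(t_end, "BF", task.task_id, "task_end", **out.payload())
        outcomes.append(out)
    score = sum(o.success for o in outcomes)
    log.append(spec.duration - 0.5 / rate, "BF", None, "game_end", score=score)
    return GameResult("BF", log, outcomes, score)


# ---------------------------------------------------------------------------
# Cross-Pressure

def play_cross_pressure(left: PressureStream, right: PressureStream) -> GameResult:
    """Hold the target region's pressure inside the band for 4.5 s.

    A task succeeds at first-band-entry + 4.5 s of continuous in-band
    pressure; with no success within 25 s the game proceeds (failure).
    Anticipation (onset to first band entry), cumulative out-of-band time
    after first entry, and relaxation time (success to release) are
    recorded; timed-out quantities carry the timeout sentinel.
    """
    spec = game_spec("CP")
    c = GAME_CONSTANTS["CP"]
    rate = _check_streams(spec, left, right)
    streams = {"left": left, "right": right}

    log, outcomes = SessionLog(), []
    hold_n = int(round(c["hold_duration_s"] * rate))
    for task in spec.tasks:
        p = task.params
        sig = streams[p["foot"]].region(p["region"])
        i0 = int(round(task.t_onset * rate))
        n = int(round(spec.task_duration * rate))
        s = sig[i0:i0 + n]
        lo, hi = p["band"]
        log.append(task.t_onset, "CP", task.task_id, "task_start",
                   foot=p["foot"], region=p["region"], level=p["level"])
        in_band = (s >= lo) & (s <= hi)
        entry = int(np.argmax(in_band)) if in_band.any() else None
        success_i = _first_sustained(in_band, hold_n)
        timeout = c["timeout_s"]
        if entry is None:
            anticipation, available = timeout, False
            time_outside = timeout
            relax, relax_avail = timeout, False
            success = False
            t_complete = task.t_onset + timeout
            log.append(t_complete - 0.5 / rate, "CP", task.task_id, "timeout")
        else:
            anticipation, available = entry / rate, True
            log.append(task.t_onset + entry / rate, "CP", task.task_id,
                       "band_enter")
            success = success_i is not None
            if success:
                end_i = success_i + hold_n
                t_complete = task.t_onset + end_i / rate
                time_outside = float(np.sum(~in_band[entry:end_i])) / rate
                rel = np.flatnonzero(s[end_i:] < c["relax_threshold"])
                if rel.size:
                    relax, relax_avail = rel[0] / rate, True
                else:
                    relax, relax_avail = (n - end_i) / rate, False
                log.append(t_complete, "CP", task.task_id, "success")
            else:
                t_complete = task.t_onset + timeout
                time_outside = float(np.sum(~in_band[entry:])) / rate
                relax, relax_avail = timeout, False
                log.append(t_complete - 0.5 / rate, "CP", task.task_id,
                           "timeout")
        fr = first_response_index(s, rate)
        meas = {
            "success": float(success),
            "anticipation_time": float(anticipation),
            "anticipation_available": available,
            "time_outside_zone": float(time_outside),
            "relaxation_time": float(relax),
            "relaxation_available": relax_avail,
            "level": p["level"],
        }
        out = TaskOutcome("CP", task.task_id, success, 1, task.t_onset,
                          task.t_onset + fr / rate if fr is not None else None,
                          min(t_complete, task.t_onset + spec.task_duration
                              - 0.5 / rate),
                          meas)
        log.append(out.t_complete, "CP", task.task_id, "task_end",
                   **out.payload())
        outcomes.append(out)
    score = sum(o.success for o in outcomes)
    log.append(spec.duration - 0.5 / rate, "CP", None, "game_end", score=score)
    return GameResult("CP", log, outcomes, score)


# ---------------------------------------------------------------------------
# Island Jump

def _detect_attempts(cs: np.ndarray, rate: float, c: dict):
    """Segment the charge signal into attempts.

    An attempt starts when the charge exceeds the onset threshold and ends
    at a release (fast drop below release_fraction x rolling peak) or when
    the charge decays below the onset threshold without one.
    Returns a list of dicts with start/end indices, peak, and clean flag.
    """
    attempts = []
    n = len(cs)
    w = max(1, int(round(c["release_window_s"] * rate)))
    i = 0
    while i < n:
        while i < n and cs[i] <= c["onset_threshold"]:
            i += 1
        if i >= n:
            break
        start = i
        peak = cs[i]
        release = None
        clean = False
        while i < n:
            peak = max(peak, cs[i])
            if cs[i] < c["release_fraction"] * peak:
                clean = bool(np.max(cs[max(start, i - w):i + 1]) >=
                             0.8 * peak)
                release = i
                break
            i += 1
        if release is None:
            release = n - 1
        attempts.append({"start": start, "end": release, "peak": float(peak),
                         "clean": clean})
        # wait for the charge to settle before the next attempt
        while i < n and cs[i] > c["onset_threshold"]:
            i += 1
    return attempts


def play_island_jump(left: PressureStream, right: PressureStream) -> GameResult:
    """Charge the jump with forefoot pressure and release at the target.

    The jump executes on release; it succeeds when the released pressure is
    within the target band and the jump direction (relative left/right
    forefoot loading) matches the island.  A miss drops the bird into the
    water and the island is retried; after 3 failed efforts the island is
    marked failed and the game advances.
    """
    spec = game_spec("IJ")
    c = GAME_CONSTANTS["IJ"]
    rate = _check_streams(spec, left, right)
    pl = left.region("forefoot")
    pr = right.region("forefoot")
    charge = pl + pr

    log, outcomes = SessionLog(), []
    for task in spec.tasks:
        p = task.params
        i0 = int(round(task.t_onset * rate))
        n = int(round(spec.task_duration * rate))
        cs = charge[i0:i0 + n]
        dl = (pl - pr)[i0:i0 + n]
        log.append(task.t_onset, "IJ", task.task_id, "task_start",
                   direction=p["direction"], level=p["level"],
                   target=p["target"])
        segs = _detect_attempts(cs, rate, c)
        success = False
        attempts = 0
        last = None
        for seg in segs:
            attempts += 1
            exec_mask = cs[seg["start"]:seg["end"] + 1] > 0.5 * seg["peak"]
            d_exec = dl[seg["start"]:seg["end"] + 1][exec_mask]
            mean_diff = float(np.mean(d_exec)) if d_exec.size else 0.0
            if mean_diff > c["direction_deadband"]:
                direction = "left"
            elif mean_diff < -c["direction_deadband"]:
                direction = "right"
            else:
                direction = "straight"
            deviation = abs(seg["peak"] - p["target"])
            ok = (seg["clean"] and deviation <= c["target_band"]
                  and direction == p["direction"])
            last = (seg, deviation, direction)
            t_rel = task.t_onset + seg["end"] / rate
            log.append(t_rel, "IJ", task.task_id, "jump",
                       released=seg["peak"], direction=direction,
                       clean=seg["clean"], success=ok)
            if ok:
                success = True
                break
            log.append(t_rel, "IJ", task.task_id, "splash")
            if attempts >= c["max_failed"]:
                log.append(t_rel, "IJ", task.task_id, "island_failed")
                break
        timeout = spec.task_duration
        if last is None:  # no attempt at all in the window
            attempts = 1
            meas = {
                "success": 0.0, "attempts": 1.0,
                "deviation": p["target"],  # full shortfall: never charged
                "deviation_available": False,
                "anticipation_time": timeout, "anticipation_available": False,
                "execution_time": timeout, "execution_available": False,
                "execution_mean_pressure": 0.0,
                "level": p["level"],
            }
            fr_t = None
            t_complete = task.t_onset + timeout - 0.5 / rate
        else:
            seg, deviation, direction = last
            exec_vals = cs[seg["start"]:seg["end"] + 1]
            meas = {
                "success": float(success),
                "attempts": float(attempts),
                "deviation": float(deviation),
                "deviation_available": True,
                "anticipation_time": segs[0]["start"] / rate,
                "anticipation_available": True,
                "execution_time": (seg["end"] - seg["start"]) / rate,
                "execution_available": True,
                "execution_mean_pressure": float(np.mean(exec_vals)),
                "level": p["level"],
            }
            fr = first_response_index(cs, rate)
            fr_t = task.t_onset + fr / rate if fr is not None else None
            t_complete = task.t_onset + last[0]["end"] / rate
        out = TaskOutcome("IJ", task.task_id, success, attempts, task.t_onset,
                          fr_t, t_complete, meas)
        log.append(out.t_complete, "IJ", task.task_id, "task_end",
                   **out.payload())
        outcomes.append(out)
    score = sum(o.success for o in outcomes)
    log.append(spec.duration - 0.5 / rate, "IJ", None, "game_end", score=score)
    return GameResult("IJ", log, outcomes, score)


_PLAYERS = {
    "AC": play_apple_catch,
    "BF": play_balloon_flying,
    "CP": play_cross_pressure,
    "IJ": play_island_jump,
}


def play_game(game: str, left: PressureStream, right: PressureStream) -> GameResult:
    if game not in _PLAYERS:
        raise GameError(f"unknown game {game!r}; expected one of {GAMES}")
    return _PLAYERS[game](left, right)


def play_session(streams: dict[str, dict[str, PressureStream]]) -> dict[str, GameResult]:
    """Play all four games; ``streams[game][foot]`` are normalized streams."""
    results = {}
    for game in GAMES:
        if game not in streams:
            continue
        results[game] = play_game(game, streams[game]["left"],
                                  streams[game]["right"])
    return results


def outcomes_from_log(log: SessionLog, game: str) -> list[TaskOutcome]:
    """Rebuild the per-task outcomes from ``task_end`` events alone."""
    outcomes = []
    for ev in log.for_game(game).of_type("task_end"):
        p = ev.payload
        outcomes.append(TaskOutcome(
            game, ev.task_id, bool(p["success"]), int(p["attempts"]),
            p["t_onset"], p["t_first_response"], p["t_complete"],
            dict(p["measurements"])))
    return outcomes
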