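"""Fixed game programs and ideal target trajectories.

The study protocol fixes the order of games and tasks for every
participant; the programs below are the versioned equivalent.  Each task
definition carries its onset on the game clock plus the game-specific
payload (apple position, obstacle class, pressure band, island target).

``ideal_targets`` renders, for any sampling rate, the region-level
pressure trajectory a perfect player would apply — it is both the
reference the closed-loop player simulator tracks and the proof that the
maximum score is attainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..errors import GameError
from .constants import GAME_CONSTANTS, GAMES, MAX_FAILED_EFFORTS

PROGRAM_VERSION = "1.0"


@dataclass(frozen=True)
class TaskDef:
    task_id: int
    t_onset: float
    params: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class GameSpec:
    game: str
    tasks: tuple[TaskDef, ...]
    task_duration: float
    max_failed_efforts: int = MAX_FAILED_EFFORTS
    version: str = PROGRAM_VERSION

    @property
    def duration(self) -> float:
        return self.tasks[-1].t_onset + self.task_duration

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)


# 7 apples on each side, alternating; x in [-1, 1], negative = left
_AC_APPLES = (-0.6, 0.5, -0.3, 0.7, -0.8, 0.4, -0.5,
              0.6, -0.7, 0.3, -0.4, 0.8, -0.2, 0.5)

# (foot, obstacle class): two of each class per foot
_BF_TASKS = (
    ("left", "low"), ("right", "low"),
    ("left", "intermediate"), ("right", "intermediate"),
    ("left", "high"), ("right", "high"),
    ("left", "low"), ("right", "low"),
    ("left", "intermediate"), ("right", "intermediate"),
    ("left", "high"), ("right", "high"),
)

# {left, right} x {forefoot, heel} x {low, high}, two blocks
_CP_TASKS = tuple(
    (side, region, level)
    for _block in range(2)
    for side in ("left", "right")
    for region in ("forefoot", "heel")
    for level in ("low", "high")
)

# (direction, target level); 6 left, 6 right, 4 straight
_IJ_TASKS = (
    ("left", "low"), ("right", "low"), ("straight", "low"),
    ("left", "middle"), ("right", "middle"), ("straight", "middle"),
    ("left", "high"), ("right", "high"), ("straight", "high"),
    ("left", "low"), ("right", "middle"), ("straight", "low"),
    ("left", "middle"), ("right", "high"), ("left", "high"), ("right", "low"),
)


def game_spec(game: str) -> GameSpec:
    """The fixed task program for one of AC, BF, CP, IJ."""
    if game not in GAMES:
        raise GameError(f"unknown game {game!r}; expected one of {GAMES}")
    c = GAME_CONSTANTS[game]
    dur = c["task_duration_s"]
    if game == "AC":
        tasks = tuple(
            TaskDef(i + 1, i * dur, {"apple_x": x,
                                     "foot": "left" if x < 0 else "right"})
            for i, x in enumerate(_AC_APPLES))
    elif game == "BF":
        heights = c["obstacle_heights"]
        tasks = tuple(
            TaskDef(i + 1, i * dur,
                    {"foot": foot, "obstacle": obs,
                     "obstacle_h": heights[obs],
                     "smiley_h": heights[obs] + c["smiley_offset"]})
            for i, (foot, obs) in enumerate(_BF_TASKS))
    elif game == "CP":
        tasks = tuple(
            TaskDef(i + 1, i * dur,
                    {"foot": side, "region": region, "level": level,
                     "band": c["band_low"] if level == "low" else c["band_high"],
                     "block": i // 8 + 1})
            for i, (side, region, level) in enumerate(_CP_TASKS))
    else:  # IJ
        tasks = tuple(
            TaskDef(i + 1, i * dur,
                    {"direction": direction, "level": level,
                     "target": c["targets"][level]})
            for i, (direction, level) in enumerate(_IJ_TASKS))
    return GameSpec(game, tasks, dur)


def session_game_order() -> tuple[str, ...]:
    return GAMES


def _knots_to_array(knots, n, rate):
    t = np.arange(n) / rate
    xs = [k[0] for k in knots]
    ys = [k[1] for k in knots]
    return np.interp(t, xs, ys)


def ideal_targets(game: str, rate: float):
    """Region-level target pressure trajectories of a perfect player.

    Returns ``(targets, spec)`` where ``targets[foot][region]`` is an array
    of length ``round(spec.duration * rate)`` with region in
    {'forefoot', 'heel'}.
    """
    spec = game_spec(game)
    c = GAME_CONSTANTS[game]
    n = int(round(spec.duration * rate))
    targets = {f: {"forefoot": np.zeros(n), "heel": np.zeros(n)}
               for f in ("left", "right")}

    def fill(foot, region, knots, onset):
        dur = spec.task_duration
        m = int(round(dur * rate))
        i0 = int(round(onset * rate))
        arr = _knots_to_array(knots, m, rate)
        targets[foot][region][i0:i0 + m] = arr

    for task in spec.tasks:
        p = task.params
        if game == "AC":
            # press the steering foot's forefoot with |apple_x| for the fall
            fall = c["fall_duration_s"]
            knots = [(0.0, 0.0), (0.05, abs(p["apple_x"])),
                     (fall, abs(p["apple_x"])), (fall + 0.2, 0.0),
                     (spec.task_duration, 0.0)]
            fill(p["foot"], "forefoot", knots, task.t_onset)
        elif game == "BF":
            h = p["smiley_h"]
            t_sm = c["smiley_time_s"]
            knots = [(0.0, 0.0), (0.5, 0.0), (1.0, h),
                     (t_sm + c["smiley_window_s"], h),
                     (t_sm + 1.0, 0.0), (spec.task_duration, 0.0)]
            fill(p["foot"], "forefoot", knots, task.t_onset)
        elif game == "CP":
            lo, hi = p["band"]
            center = (lo + hi) / 2.0
            knots = [(0.0, 0.0), (0.6, 0.0), (1.0, center), (6.2, center),
                     (7.0, 0.0), (spec.task_duration, 0.0)]
            fill(p["foot"], p["region"], knots, task.t_onset)
        else:  # IJ: charge both/one forefoot to the target, release at 4 s
            target = p["target"]
            w = {"left": (1.0, 0.0), "right": (0.0, 1.0),
                 "straight": (0.5, 0.5)}[p["direction"]]
            knots = [(0.0, 0.0), (1.0, 0.0), (2.2, target),
                     (3.999, target), (4.0, 0.0), (spec.task_duration, 0.0)]
            for foot, weight in zip(("left", "right"), w):
                if weight > 0:
                    dur = spec.task_duration
                    m = int(round(dur * rate))
                    i0 = int(round(task.t_onset * rate))
                    arr = _knots_to_array(knots, m, rate) * weight
                    targets[foot]["forefoot"][i0:i0 + m] = arr
    return targets, spec
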