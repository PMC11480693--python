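"""Task-combination (TC) registry.

A TC groups game tasks with similar specifications for one foot side;
secondary features (sum/mean/SD of a primary feature over the member
tasks) are computed per TC.  Registry, per side:

* AC — TC1: tasks steered by that foot; TC2: all 14 tasks.
* BF — TC1/2/3: that foot's tasks with low/intermediate/high obstacles;
  TC4: all of that foot's tasks.
* CP — TC1-4: {forefoot, heel} x {low, high} for that side; TC5: all-low,
  TC6: all-high.
* IJ — TC1/2/3: islands with low/middle/high targets involving that foot
  (straight islands involve both feet).
"""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import GameError
from .constants import GAMES
from .programs import game_spec


@dataclass(frozen=True)
class TaskCombination:
    id: str           # e.g. "AC.TCL1"
    game: str
    foot: str
    index: int
    member_task_ids: tuple[int, ...]
    description: str = ""


def _tc_id(game: str, foot: str, index: int) -> str:
    return f"{game}.TC{'L' if foot == 'left' else 'R'}{index}"


def get_task_combinations(game: str, foot: str) -> list[TaskCombination]:
    if game not in GAMES:
        raise GameError(f"unknown game {game!r}")
    if foot not in ("left", "right"):
        raise GameError(f"unknown foot {foot!r}")
    spec = game_spec(game)
    tasks = spec.tasks
    tcs: list[TaskCombination] = []

    def add(index, members, description):
        tcs.append(TaskCombination(_tc_id(game, foot, index), game, foot,
                                   index, tuple(members), description))

    if game == "AC":
        side = [t.task_id for t in tasks if t.params["foot"] == foot]
        add(1, side, f"apples steered by the {foot} foot")
        add(2, [t.task_id for t in tasks], "all apples")
    elif game == "BF":
        mine = [t for t in tasks if t.params["foot"] == foot]
        for i, obs in enumerate(("low", "intermediate", "high"), start=1):
            add(i, [t.task_id for t in mine if t.params["obstacle"] == obs],
                f"{obs} obstacles, {foot} foot")
        add(4, [t.task_id for t in mine], f"all {foot}-foot tasks")
    elif game == "CP":
        mine = [t for t in tasks if t.params["foot"] == foot]
        i = 1
        for region in ("forefoot", "heel"):
            for level in ("low", "high"):
                add(i, [t.task_id for t in mine
                        if t.params["region"] == region
                        and t.params["level"] == level],
                    f"{region} {level}, {foot} side")
                i += 1
        for level in ("low", "high"):
            add(i, [t.task_id for t in mine if t.params["level"] == level],
                f"all {level}, {foot} side")
            i += 1
    else:  # IJ
        involving = [t for t in tasks
                     if t.params["direction"] in (foot, "straight")]
        for i, level in enumerate(("low", "middle", "high"), start=1):
            add(i, [t.task_id for t in involving
                    if t.params["level"] == level],
                f"{level} targets involving the {foot} foot")
    return tcs


def foot_task_ids(game: str, foot: str) -> list[int]:
    """Task ids that belong to a foot's feature scope for a game."""
    spec = game_spec(game)
    if game == "IJ":
        return [t.task_id for t in spec.tasks
                if t.params["direction"] in (foot, "straight")]
    if game == "AC":
        # the carriage is steered by both feet jointly, so every apple is in
        # scope for either foot (pressure features use that foot's signal)
        return [t.task_id for t in spec.tasks]
    return [t.task_id for t in spec.tasks if t.params["foot"] == foot]
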