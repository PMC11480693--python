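"""Session event log.

A gaming session is fully described by a sequence of timestamped events:
game boundaries, task boundaries, band entries, collisions, restarts,
releases and task outcomes.  Task outcomes are reconstructible from the log
alone because every ``task_end`` event carries the outcome payload.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterator


@dataclass(frozen=True)
class GameEvent:
    t_s: float
    game: str
    task_id: int | None
    event: str
    payload: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "t_s": round(float(self.t_s), 6),
                "game": self.game,
                "task_id": self.task_id,
                "event": self.event,
                "payload": self.payload,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "GameEvent":
        d = json.loads(line)
        return cls(d["t_s"], d["game"], d["task_id"], d["event"], d.get("payload", {}))


@dataclass
class SessionLog:
    events: list[GameEvent] = field(default_factory=list)

    def append(self, t_s, game, task_id, event, **payload) -> None:
        self.events.append(GameEvent(t_s, game, task_id, event, payload))

    def extend(self, other: "SessionLog") -> None:
        self.events.extend(other.events)

    def __iter__(self) -> Iterator[GameEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def for_game(self, game: str) -> "SessionLog":
        return SessionLog([e for e in self.events if e.game == game])

    def for_task(self, game: str, task_id: int) -> "SessionLog":
        return SessionLog(
            [e for e in self.events if e.game == game and e.task_id == task_id]
        )

    def of_type(self, event: str) -> "SessionLog":
        return SessionLog([e for e in self.events if e.event == event])
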