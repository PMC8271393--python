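"""Timestamped event logs.

Events carry an onset in seconds from recording start, an optional duration,
a label (``"blink"``, ``"stimulus"``, ``"chew"``, detector outputs, robot
commands ...) and a free-form ``info`` mapping with event-specific payload
(e.g. the chosen stimulus index).  Logs round-trip through tab-separated
files with columns ``onset_s  duration_s  label`` plus a JSON-encoded info
column, and through JSON-lines for session replay logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator

import pandas as pd

__all__ = ["Event", "EventLog"]


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    label: str
    info: dict[str, Any] = field(default_factory=dict)

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


class EventLog:
    """An ordered collection of :class:`Event`."""

    def __init__(self, events: Iterable[Event] = ()) -> None:
        self._events: list[Event] = list(events)

    def append(self, event: Event) -> None:
        self._events.append(event)

    def add(self, onset_s: float, duration_s: float, label: str, **info: Any) -> Event:
        ev = Event(float(onset_s), float(duration_s), label, dict(info))
        self._events.append(ev)
        return ev

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self._events)

    def __getitem__(self, i: int) -> Event:
        return self._events[i]

    def filter(self, label: str) -> "EventLog":
        return EventLog(ev for ev in self._events if ev.label == label)

    def labels(self) -> list[str]:
        return [ev.label for ev in self._events]

    def sorted(self) -> "EventLog":
        return EventLog(sorted(self._events, key=lambda ev: ev.onset_s))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [ev.onset_s for ev in self._events],
                "duration_s": [ev.duration_s for ev in self._events],
                "label": [ev.label for ev in self._events],
                "info": [json.dumps(ev.info, sort_keys=True) for ev in self._events],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventLog":
        df = pd.read_csv(path, sep="\t")
        events = []
        for row in df.itertuples(index=False):
            info = json.loads(getattr(row, "info", "{}") or "{}") if hasattr(row, "info") else {}
            events.append(Event(float(row.onset_s), float(row.duration_s), str(row.label), info))
        return cls(events)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ev in self._events:
                fh.write(
                    json.dumps(
                        {"t": ev.onset_s, "duration": ev.duration_s, "type": ev.label, "payload": ev.info},
                        sort_keys=True,
                    )
                    + "\n"
                )

    def __repr__(self) -> str:  # pragma: no cover
        return f"EventLog(n={len(self._events)})"
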