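"""Trace events: a serializable record of everything the engine does.

Replaying the spike deltas of a trace (initial spikes, plus deliveries
and inputs, minus consumptions) reproduces the final spike count of
every surviving neuron; the test suite asserts this invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

#: event kinds
FIRE = "fire"
FORGET = "forget"
DIVIDE = "divide"
DISSOLVE = "dissolve"
DELIVER = "deliver"
INPUT = "input"
LOST = "lost"

KINDS = (FIRE, FORGET, DIVIDE, DISSOLVE, DELIVER, INPUT, LOST)


@dataclass(frozen=True)
class TraceEvent:
    step: int
    kind: str
    neuron_id: int
    label: str
    data: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "step": self.step,
            "kind": self.kind,
            "neuron_id": self.neuron_id,
            "label": self.label,
            "data": self.data,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TraceEvent":
        return cls(d["step"], d["kind"], d["neuron_id"], d["label"], dict(d["data"]))


def replay_spike_deltas(initial: dict[int, int], events: list[TraceEvent]) -> dict[int, int]:
    """Accumulate per-neuron spike deltas from a trace.

    Returns the implied final spike count per neuron id; ids of divided
    or dissolved neurons are dropped (their remaining spikes are
    consumed by the structural rule itself).
    """
    counts = dict(initial)
    for ev in events:
        if ev.kind in (DELIVER, INPUT):
            counts[ev.neuron_id] = counts.get(ev.neuron_id, 0) + ev.data["amount"]
        elif ev.kind in (FIRE, FORGET):
            counts[ev.neuron_id] -= ev.data["consumed"]
        elif ev.kind == DIVIDE:
            counts.pop(ev.neuron_id, None)
            for child in ev.data["children"]:
                counts[child["id"]] = 0
        elif ev.kind == DISSOLVE:
            counts.pop(ev.neuron_id, None)
    return counts
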