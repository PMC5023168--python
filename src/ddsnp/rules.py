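"""Developmental rules and the label-pattern rule resolver.

Rules are attached to neuron *labels*, not to individual neurons: a
neuron created by division carries exactly the rules its label resolves
to.  Four rule kinds exist — firing, forgetting, division, dissolution —
mirroring the four developmental rule forms of DDSN P systems.

Label patterns are either literal labels or regular expressions (written
``re:<pattern>``, matched against the whole label), which is how the
exponential output-neuron family ``o_<bitstring>`` is covered by a fixed
number of rule entries.  Division child labels may use the placeholder
``{label}``, substituted with the parent's label at application time, so
one entry expresses the whole binary division chain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

from .errors import SpecError
from .guards import SpikeCountSet


@dataclass(frozen=True)
class FiringRule:
    """``[E/a^c -> a^p; d]``: consume c spikes, emit p after delay d."""

    guard: SpikeCountSet
    consume: int
    produce: int
    delay: int = 0

    def __post_init__(self):
        if not (self.consume >= self.produce >= 1):
            raise SpecError(
                f"firing rule requires c >= p >= 1, got c={self.consume} p={self.produce}"
            )
        if self.delay < 0:
            raise SpecError(f"delay must be >= 0, got {self.delay}")
        _check_guard_min(self.guard, self.consume)

    def __repr__(self):
        d = f"; {self.delay}" if self.delay else ""
        return f"[{self.guard.describe()}/a^{self.consume} -> a^{self.produce}{d}]"


@dataclass(frozen=True)
class ForgettingRule:
    """``[E/a^s -> λ]``: consume s spikes, emit nothing."""

    guard: SpikeCountSet
    consume: int

    def __post_init__(self):
        if self.consume < 1:
            raise SpecError(f"forgetting rule requires s >= 1, got {self.consume}")
        _check_guard_min(self.guard, self.consume)

    def __repr__(self):
        return f"[{self.guard.describe()}/a^{self.consume} -> λ]"


@dataclass(frozen=True)
class DivisionRule:
    """``[E]_i -> []_j || []_k``: replace the neuron with two empty children.

    Child labels may contain ``{label}``, replaced by the parent label,
    e.g. children ``{label}1`` / ``{label}0`` grow a bitstring suffix.
    """

    guard: SpikeCountSet
    child_left: str
    child_right: str

    def resolve_children(self, parent_label: str) -> tuple[str, str]:
        return (
            self.child_left.replace("{label}", parent_label),
            self.child_right.replace("{label}", parent_label),
        )

    def __repr__(self):
        return f"[{self.guard.describe()}] -> []_{self.child_left} || []_{self.child_right}"


@dataclass(frozen=True)
class DissolutionRule:
    """``[E]_i -> δ``: remove the neuron and all incident synapses."""

    guard: SpikeCountSet

    def __repr__(self):
        return f"[{self.guard.describe()}] -> δ"


Rule = Union[FiringRule, ForgettingRule, DivisionRule, DissolutionRule]


def _check_guard_min(guard: SpikeCountSet, consume: int) -> None:
    # every admissible count must cover what the rule consumes
    m = guard.min_value()
    if m is not None and m < consume:
        raise SpecError(
            f"guard {guard.describe()} admits {m} spikes but the rule consumes {consume}"
        )


class LabelPattern:
    """A literal label or a ``re:``-prefixed full-match regular expression."""

    __slots__ = ("raw", "_regex")

    def __init__(self, raw: str):
        self.raw = raw
        self._regex = re.compile(raw[3:]) if raw.startswith("re:") else None

    def matches(self, label: str) -> bool:
        if self._regex is None:
            return self.raw == label
        return self._regex.fullmatch(label) is not None

    @property
    def is_literal(self) -> bool:
        return self._regex is None

    def __repr__(self):
        return f"LabelPattern({self.raw!r})"

    def __eq__(self, other):
        return isinstance(other, LabelPattern) and self.raw == other.raw

    def __hash__(self):
        return hash(self.raw)


class RuleResolver:
    """Ordered mapping from label patterns to rule lists.

    Resolution concatenates the rule lists of every matching pattern, in
    entry order, so it is finite and order-stable for any concrete label.
    Results are memoised per concrete label (labels of a running system
    are drawn from a small set of families).
    """

    def __init__(self, entries: list[tuple[str, list[Rule]]]):
        self.entries: list[tuple[LabelPattern, tuple[Rule, ...]]] = [
            (LabelPattern(pat), tuple(rules)) for pat, rules in entries
        ]
        self._cache: dict[str, tuple[Rule, ...]] = {}

    def resolve(self, label: str) -> tuple[Rule, ...]:
        cached = self._cache.get(label)
        if cached is None:
            rules: list[Rule] = []
            for pattern, entry_rules in self.entries:
                if pattern.matches(label):
                    rules.extend(entry_rules)
            cached = self._cache[label] = tuple(rules)
        return cached

    def __eq__(self, other):
        return isinstance(other, RuleResolver) and self.entries == other.entries
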