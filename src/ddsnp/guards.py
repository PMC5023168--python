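"""Spike-count guards: decidable sets of admissible spike counts.

Every rule in the simulator is guarded by a regular language over the
single spike symbol ``a``.  A unary regular language is exactly a finite
union of arithmetic progressions, so guards are stored as a tuple of
``(offset, period)`` pairs, each denoting ``{offset + k*period : k >= 0}``
(period 0 denotes the singleton ``{offset}``).  Membership is O(number of
progressions), independent of the spike count.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SpecError


@dataclass(frozen=True)
class SpikeCountSet:
    """A finite union of arithmetic progressions of nonnegative integers."""

    progressions: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for prog in self.progressions:
            if len(prog) != 2:
                raise SpecError(f"progression must be (offset, period): {prog!r}")
            offset, period = prog
            if offset < 0 or period < 0:
                raise SpecError(f"offset and period must be >= 0: {prog!r}")

    def contains(self, h: int) -> bool:
        """True iff ``h`` lies in some progression.  Pure."""
        if h < 0:
            raise ValueError(f"spike count must be nonnegative, got {h}")
        for offset, period in self.progressions:
            if period == 0:
                if h == offset:
                    return True
            elif h >= offset and (h - offset) % period == 0:
                return True
        return False

    __contains__ = contains

    def min_value(self) -> int | None:
        """Smallest member, or None for the empty set."""
        if not self.progressions:
            return None
        return min(offset for offset, _ in self.progressions)

    @property
    def is_empty(self) -> bool:
        return not self.progressions

    def describe(self) -> str:
        if not self.progressions:
            return "{}"
        parts = []
        for offset, period in self.progressions:
            if period == 0:
                parts.append(f"{{{offset}}}")
            else:
                parts.append(f"{{{offset}+{period}k}}")
        return "∪".join(parts)


def singleton(value: int) -> SpikeCountSet:
    """The guard ``a^value`` — exactly `value` spikes."""
    return SpikeCountSet(((value, 0),))


def at_least_every(offset: int, period: int) -> SpikeCountSet:
    """The guard ``{offset, offset+period, offset+2*period, ...}``.

    Covers all the composed expressions the constructions use, e.g.
    ``a(a^2)^+`` is ``at_least_every(3, 2)`` and ``a^3(a^3)^+`` is
    ``at_least_every(6, 3)``.
    """
    return SpikeCountSet(((offset, period),))
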