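"""System specification and runtime configuration containers.

A DDSN P system ``Π = (O, H, syn, n_1..n_m, R, in, out)`` is described
statically by :class:`SystemSpec`.  The spike alphabet ``O = {a}`` is a
singleton, so spikes are stored as counts.  The synapse dictionary
``syn`` plays a double role: restricted to the initially present labels
it gives the initial wiring, and at every neuron creation it says which
synapses to instantiate between the new neuron and existing neurons.

The runtime state is a :class:`Configuration`: live neurons with unique
integer ids (labels may repeat), a directed synapse graph over ids,
pending delayed emissions, and the step counter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import SpecError
from .rules import LabelPattern, RuleResolver


@dataclass
class NeuronState:
    """One live neuron: unique id, label, spike count, closed-until step.

    ``reopen_at`` is the first step index at which the neuron is open
    again; a neuron is closed during every step t with t < reopen_at.
    """

    id: int
    label: str
    spikes: int = 0
    reopen_at: int = 0

    def is_open(self, step: int) -> bool:
        return step >= self.reopen_at


class SynapseDictionary:
    """The static ``syn ⊆ H × H`` as ordered (from, to) pattern pairs.

    Each side is a literal label or a ``re:`` pattern.  Pairs with two
    identical literal sides are rejected (``(i, i) ∉ syn``).
    """

    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs: list[tuple[LabelPattern, LabelPattern]] = []
        for a, b in pairs:
            pa, pb = LabelPattern(a), LabelPattern(b)
            if pa.is_literal and pb.is_literal and a == b:
                raise SpecError(f"self-loop pair ({a!r}, {a!r}) not allowed in syn")
            self.pairs.append((pa, pb))

    def raw_pairs(self) -> list[tuple[str, str]]:
        return [(a.raw, b.raw) for a, b in self.pairs]

    def __eq__(self, other):
        return isinstance(other, SynapseDictionary) and self.pairs == other.pairs


@dataclass
class SystemSpec:
    """Static description of a DDSN P system.

    Parameters
    ----------
    labels
        The label set ``H``; literal labels plus ``re:`` patterns for
        parameterised families (e.g. the output family ``o_<bits>``).
    syn
        The synapse dictionary.
    initial
        ``(label, spikes)`` for each initially present neuron, in order.
    resolver
        Maps every concrete label to its (possibly empty) rule list.
    in_labels
        Labels through which external spike trains enter.
    out_pattern
        Full-match regular expression selecting output-neuron labels.
    declared_horizon
        Step count at which the construction's answer is final, when
        the builder knows a closed form; used to pick ``max_steps``.
    """

    labels: list[str]
    syn: SynapseDictionary
    initial: list[tuple[str, int]]
    resolver: RuleResolver
    in_labels: list[str]
    out_pattern: str
    name: str = "ddsnp-system"
    declared_horizon: int | None = None

    def __post_init__(self):
        self._out_re = re.compile(self.out_pattern)
        self._label_patterns = [LabelPattern(l) for l in self.labels]
        for label, spikes in self.initial:
            if spikes < 0:
                raise SpecError(f"initial spikes must be >= 0 for {label!r}")
            if not self.label_in_h(label):
                raise SpecError(f"initial label {label!r} not in H")

    def label_in_h(self, label: str) -> bool:
        return any(p.matches(label) for p in self._label_patterns)

    def is_out_label(self, label: str) -> bool:
        return self._out_re.fullmatch(label) is not None

    def default_max_steps(self) -> int:
        # 10x the declared horizon for family-built systems, else 10000
        if self.declared_horizon is not None:
            return 10 * self.declared_horizon
        return 10_000


# Per-input-neuron spike trains: label -> (i_1, i_2, ..., i_r); the count
# at position j enters the system during step j (0 means nothing enters).
SpikeTrainSet = dict[str, list[int]]


def validate_trains(trains: SpikeTrainSet, spec: SystemSpec) -> None:
    for label, seq in trains.items():
        if label not in spec.in_labels:
            raise SpecError(f"train targets non-input label {label!r}")
        if any(c < 0 for c in seq):
            raise SpecError(f"negative spike count in train for {label!r}")


class Configuration:
    """Mutable runtime state of a computation."""

    def __init__(self):
        self.neurons: dict[int, NeuronState] = {}
        self.out_edges: dict[int, set[int]] = {}
        self.in_edges: dict[int, set[int]] = {}
        self.label_index: dict[str, set[int]] = {}
        # pending delayed emissions: (due step, source id, amount)
        self.pending: list[tuple[int, int, int]] = []
        self.step: int = 0
        self.halted: bool = False
        self._next_id: int = 1

    # -- structural mutations ------------------------------------------------

    def add_neuron(self, label: str, spikes: int = 0, reopen_at: int = 0) -> NeuronState:
        neuron = NeuronState(self._next_id, label, spikes, reopen_at)
        self._next_id += 1
        self.neurons[neuron.id] = neuron
        self.out_edges[neuron.id] = set()
        self.in_edges[neuron.id] = set()
        self.label_index.setdefault(label, set()).add(neuron.id)
        return neuron

    def remove_neuron(self, neuron_id: int) -> None:
        neuron = self.neurons.pop(neuron_id)
        for dst in self.out_edges.pop(neuron_id):
            self.in_edges[dst].discard(neuron_id)
        for src in self.in_edges.pop(neuron_id):
            self.out_edges[src].discard(neuron_id)
        ids = self.label_index[neuron.label]
        ids.discard(neuron_id)
        if not ids:
            del self.label_index[neuron.label]

    def add_synapse(self, src: int, dst: int) -> None:
        if src == dst:
            raise SpecError(f"self-loop synapse on neuron id {src}")
        self.out_edges[src].add(dst)
        self.in_edges[dst].add(src)

    # -- queries -------------------------------------------------------------

    def ids_with_label(self, label: str) -> set[int]:
        return self.label_index.get(label, set())

    def ids_matching(self, pattern: LabelPattern) -> list[int]:
        if pattern.is_literal:
            return sorted(self.ids_with_label(pattern.raw))
        ids: list[int] = []
        for label, lids in self.label_index.items():
            if pattern.matches(label):
                ids.extend(lids)
        return sorted(ids)

    def synapse_between_labels(self, a: str, b: str) -> bool:
        """Any runtime synapse from a neuron labeled ``a`` to one labeled ``b``?"""
        a_ids = self.label_index.get(a)
        b_ids = self.label_index.get(b)
        if not a_ids or not b_ids:
            return False
        return any(self.out_edges[u] & b_ids for u in a_ids)

    def synapse_pairs(self) -> list[tuple[int, int]]:
        return sorted((u, v) for u, outs in self.out_edges.items() for v in outs)

    def live_labels(self) -> list[str]:
        return sorted(n.label for n in self.neurons.values())

    def spikes_by_id(self) -> dict[int, int]:
        return {i: n.spikes for i, n in self.neurons.items()}

    def instantiate_dictionary(self, syn: SynapseDictionary, neuron: NeuronState) -> list[tuple[int, int]]:
        """Create the ``syn``-dictionary synapses for a newly created neuron.

        For every pair (A, B): if the new label matches A, a synapse is
        drawn to every existing neuron matching B, and symmetrically for
        B.  Applied at neuron creation only — initially and on division —
        never retroactively.
        """
        created: list[tuple[int, int]] = []
        for pa, pb in syn.pairs:
            if pa.matches(neuron.label):
                for other in self.ids_matching(pb):
                    if other != neuron.id and other not in self.out_edges[neuron.id]:
                        self.add_synapse(neuron.id, other)
                        created.append((neuron.id, other))
            if pb.matches(neuron.label):
                for other in self.ids_matching(pa):
                    if other != neuron.id and neuron.id not in self.out_edges[other]:
                        self.add_synapse(other, neuron.id)
                        created.append((other, neuron.id))
        return created


def initial_configuration(spec: SystemSpec) -> Configuration:
    """Build the step-0 configuration: initial neurons plus the syn
    dictionary restricted to label pairs both present initially."""
    config = Configuration()
    for label, spikes in spec.initial:
        config.add_neuron(label, spikes)
    for neuron_id in sorted(config.neurons):
        config.instantiate_dictionary(spec.syn, config.neurons[neuron_id])
    return config
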