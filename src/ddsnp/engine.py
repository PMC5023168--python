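"""Exact execution engine for DDSN P systems.

One transition (:func:`step`) has three phases:

1. **select** — every live, open neuron picks at most one applicable rule
   based on its start-of-step spike count.  Rules are applied in a
   sequential manner inside a neuron but in parallel between neurons, so
   selection sees no effect of any same-step action.  In ``strict`` mode
   more than one applicable rule raises :class:`AmbiguityError`;
   ``random`` mode draws one with a seeded RNG.
2. **act** — consume spikes; firing rules schedule an emission due at
   step ``t + d`` (due this very step when ``d = 0``) and close the
   neuron through step ``t + d - 1``; division replaces the parent by two
   empty children that inherit its synapses and gain dictionary
   synapses; dissolution removes the neuron with all incident synapses.
3. **deliver** — emissions due this step travel along the *current*
   synapses of their source, and external train entries for this step
   enter the input neurons.  Only neurons that are live and open at this
   point receive; everything else is logged as lost.  Spikes delivered
   during step t become usable at step t + 1.

A computation halts when all neurons are open, no rule is applicable, no
delayed emission is pending and the input trains are exhausted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import AmbiguityError, MaxStepsExceeded, SpecError
from .rules import (
    DissolutionRule,
    DivisionRule,
    FiringRule,
    ForgettingRule,
    Rule,
    RuleResolver,
)
from .system import (
    Configuration,
    NeuronState,
    SpikeTrainSet,
    SystemSpec,
    initial_configuration,
    validate_trains,
)
from . import trace as tr

STRICT = "strict"
RANDOM = "random"


def applicable_rules(
    label: str, spikes: int, config: Configuration, resolver: RuleResolver
) -> list[Rule]:
    """All rules of ``label`` whose guard admits ``spikes`` and whose
    structural precondition (for division) holds right now."""
    out: list[Rule] = []
    for rule in resolver.resolve(label):
        if not rule.guard.contains(spikes):
            continue
        if isinstance(rule, DivisionRule) and not division_allowed(config, label, rule):
            # a blocked division is simply inapplicable; other rules stay eligible
            continue
        out.append(rule)
    return out


def select_rule(
    label: str,
    spikes: int,
    config: Configuration,
    resolver: RuleResolver,
    mode: str = STRICT,
    rng: random.Random | None = None,
    *,
    neuron_id: int = -1,
) -> Rule | None:
    """Pick the rule a neuron applies this step, or None.

    Strict mode (the default) demands determinism: two or more
    applicable rules raise :class:`AmbiguityError`.  Random mode draws
    uniformly with the caller's seeded RNG.
    """
    rules = applicable_rules(label, spikes, config, resolver)
    if not rules:
        return None
    if len(rules) == 1:
        return rules[0]
    if mode == STRICT:
        raise AmbiguityError(config.step + 1, neuron_id, label, spikes, rules)
    if rng is None:
        raise SpecError("random mode requires an explicit seed")
    return rules[rng.randrange(len(rules))]


def division_allowed(config: Configuration, parent_label: str, rule: DivisionRule) -> bool:
    """Structural precondition of division: with parent label i and child
    labels j, k, no runtime synapse may connect any neuron labeled i with
    any neuron labeled j or k, in either direction (it would become a
    self-loop after the division)."""
    j, k = rule.resolve_children(parent_label)
    i = parent_label
    for a, b in ((i, j), (j, i), (i, k), (k, i)):
        if config.synapse_between_labels(a, b):
            return False
    return True


def apply_division(
    config: Configuration, neuron: NeuronState, rule: DivisionRule, spec: SystemSpec
) -> list[NeuronState]:
    """Replace ``neuron`` by two empty children (mutates ``config``).

    Children get fresh ids, zero spikes and the rule's labels; they
    inherit every incoming and outgoing synapse of the parent, then gain
    the synapse-dictionary instantiations for their new labels against
    every currently existing neuron.  Returns the two children.
    """
    left_label, right_label = rule.resolve_children(neuron.label)
    for child_label in (left_label, right_label):
        if not spec.label_in_h(child_label):
            raise SpecError(f"division child label {child_label!r} not in H")
    parents_out = sorted(config.out_edges[neuron.id])
    parents_in = sorted(config.in_edges[neuron.id])
    config.remove_neuron(neuron.id)
    children = []
    for child_label in (left_label, right_label):
        child = config.add_neuron(child_label, spikes=0, reopen_at=0)
        for dst in parents_out:
            config.add_synapse(child.id, dst)
        for src in parents_in:
            config.add_synapse(src, child.id)
        config.instantiate_dictionary(spec.syn, child)
        children.append(child)
    return children


def apply_dissolution(config: Configuration, neuron: NeuronState) -> None:
    """Remove ``neuron`` and all incident synapses (mutates ``config``).

    Emissions already scheduled resolve their targets at delivery time,
    so anything addressed here is lost from now on.
    """
    config.remove_neuron(neuron.id)


def step(
    config: Configuration,
    spec: SystemSpec,
    trains: SpikeTrainSet | None = None,
    mode: str = STRICT,
    rng: random.Random | None = None,
) -> list[tr.TraceEvent]:
    """Execute one synchronous transition (mutates ``config``).

    Returns the trace events of this step, in phase order.
    """
    trains = trains or {}
    t = config.step + 1
    config.step = t
    events: list[tr.TraceEvent] = []

    # Phase 1: select, from start-of-step spike counts.
    selections: list[tuple[NeuronState, Rule]] = []
    for neuron_id in sorted(config.neurons):
        neuron = config.neurons[neuron_id]
        if not neuron.is_open(t):
            continue
        rule = select_rule(
            neuron.label, neuron.spikes, config, spec.resolver, mode, rng,
            neuron_id=neuron_id,
        )
        if rule is not None:
            selections.append((neuron, rule))

    # Phase 2: act.
    for neuron, rule in selections:
        if isinstance(rule, FiringRule):
            neuron.spikes -= rule.consume
            due = t + rule.delay
            config.pending.append((due, neuron.id, rule.produce))
            if rule.delay > 0:
                neuron.reopen_at = due
            events.append(
                tr.TraceEvent(t, tr.FIRE, neuron.id, neuron.label,
                              {"consumed": rule.consume, "produced": rule.produce,
                               "due": due, "rule": repr(rule)})
            )
        elif isinstance(rule, ForgettingRule):
            neuron.spikes -= rule.consume
            events.append(
                tr.TraceEvent(t, tr.FORGET, neuron.id, neuron.label,
                              {"consumed": rule.consume, "rule": repr(rule)})
            )
        elif isinstance(rule, DivisionRule):
            children = apply_division(config, neuron, rule, spec)
            events.append(
                tr.TraceEvent(t, tr.DIVIDE, neuron.id, neuron.label,
                              {"consumed": neuron.spikes,
                               "children": [{"id": c.id, "label": c.label} for c in children],
                               "rule": repr(rule)})
            )
        elif isinstance(rule, DissolutionRule):
            apply_dissolution(config, neuron)
            events.append(
                tr.TraceEvent(t, tr.DISSOLVE, neuron.id, neuron.label,
                              {"consumed": neuron.spikes, "rule": repr(rule)})
            )
        else:  # pragma: no cover - the four kinds above are exhaustive
            raise SpecError(f"unknown rule kind: {rule!r}")

    # Phase 3: deliver due emissions, then external inputs.
    still_pending: list[tuple[int, int, int]] = []
    due_now: list[tuple[int, int, int]] = []
    for entry in config.pending:
        (due_now if entry[0] == t else still_pending).append(entry)
    config.pending = still_pending
    for _, src, amount in sorted(due_now, key=lambda e: e[1]):
        if src not in config.neurons:
            # source dissolved or divided away while the emission was in flight
            events.append(tr.TraceEvent(t, tr.LOST, src, "?",
                                        {"amount": amount, "reason": "source gone"}))
            continue
        src_label = config.neurons[src].label
        for dst in sorted(config.out_edges[src]):
            target = config.neurons[dst]
            if target.is_open(t):
                target.spikes += amount
                events.append(tr.TraceEvent(t, tr.DELIVER, dst, target.label,
                                            {"amount": amount, "source": src,
                                             "source_label": src_label}))
            else:
                events.append(tr.TraceEvent(t, tr.LOST, dst, target.label,
                                            {"amount": amount, "source": src,
                                             "reason": "target closed"}))

    for label in sorted(trains):
        seq = trains[label]
        if t <= len(seq) and seq[t - 1] > 0:
            amount = seq[t - 1]
            targets = sorted(config.ids_with_label(label))
            for dst in targets:
                target = config.neurons[dst]
                if target.is_open(t):
                    target.spikes += amount
                    events.append(tr.TraceEvent(t, tr.INPUT, dst, label, {"amount": amount}))
                else:
                    events.append(tr.TraceEvent(t, tr.LOST, dst, label,
                                                {"amount": amount, "reason": "input neuron closed"}))
            if not targets:
                events.append(tr.TraceEvent(t, tr.LOST, -1, label,
                                            {"amount": amount, "reason": "input neuron gone"}))
    return events


def is_halted(config: Configuration, spec: SystemSpec, trains: SpikeTrainSet | None = None) -> bool:
    """True iff all neurons are open, no rule is applicable, no delayed
    emission is pending, and no future train entry carries spikes."""
    if config.pending:
        return False
    next_step = config.step + 1
    for label, seq in (trains or {}).items():
        for j in range(config.step, len(seq)):  # entries at steps > config.step
            if seq[j] > 0:
                return False
    for neuron in config.neurons.values():
        if not neuron.is_open(next_step):
            return False
        if applicable_rules(neuron.label, neuron.spikes, config, spec.resolver):
            return False
    return True


@dataclass
class RunResult:
    """Outcome of :func:`run`: the final configuration, the step at which
    the computuation halted, the labels of surviving output neurons, and
    the full trace."""

    config: Configuration
    halting_step: int
    surviving_out_labels: list[str]
    events: list[tr.TraceEvent] = field(repr=False, default_factory=list)


def run(
    spec: SystemSpec,
    trains: SpikeTrainSet | None = None,
    max_steps: int | None = None,
    mode: str = STRICT,
    seed: int | None = None,
) -> RunResult:
    """Iterate :func:`step` from the initial configuration until halting.

    Raises :class:`MaxStepsExceeded` if the system is still active after
    ``max_steps`` transitions (default: the spec's declared horizon x 10,
    or 10000 for generic systems).
    """
    trains = trains or {}
    validate_trains(trains, spec)
    if max_steps is None:
        max_steps = spec.default_max_steps()
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if mode == RANDOM and seed is None:
        raise SpecError("random mode requires an explicit seed")
    rng = random.Random(seed) if mode == RANDOM else None

    config = initial_configuration(spec)
    events: list[tr.TraceEvent] = []
    while not is_halted(config, spec, trains):
        if config.step >= max_steps:
            raise MaxStepsExceeded(
                f"no halt within {max_steps} steps (declared horizon "
                f"{spec.declared_horizon}); construction bug or non-halting system"
            )
        events.extend(step(config, spec, trains, mode, rng))
    config.halted = True
    surviving = sorted(
        n.label for n in config.neurons.values() if spec.is_out_label(n.label)
    )
    return RunResult(config, config.step, surviving, events)
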