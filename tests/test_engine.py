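"""Core execution semantics: rule selection, the four rule kinds, synapse
inheritance, delays, closed neurons, halting, and trace replay."""

import pytest

from ddsnp import trace as tr
from ddsnp.engine import (
    applicable_rules,
    division_allowed,
    is_halted,
    run,
    select_rule,
    step,
)
from ddsnp.errors import AmbiguityError, MaxStepsExceeded, SpecError
from ddsnp.guards import at_least_every, singleton
from ddsnp.rules import (
    DissolutionRule,
    DivisionRule,
    FiringRule,
    ForgettingRule,
    RuleResolver,
)
from ddsnp.sat import build_sat_input, build_sat_system
from ddsnp.subsetsum import _output_rules
from ddsnp.system import SynapseDictionary, SystemSpec, initial_configuration


def make_spec(labels, syn, initial, rules, in_labels=(), out_pattern="(?!)"):
    return SystemSpec(
        labels=list(labels),
        syn=SynapseDictionary(list(syn)),
        initial=list(initial),
        resolver=RuleResolver(list(rules)),
        in_labels=list(in_labels),
        out_pattern=out_pattern,
    )


# ---------------------------------------------------------------------------
# rule selection
# ---------------------------------------------------------------------------


def test_select_rule_pacemaker_guard():
    # a neuron with 2m+1 = 7 spikes and rule a(a^2)^+/a^2 -> a selects it
    spec = make_spec(["d"], [], [("d", 7)], [("d", [FiringRule(at_least_every(3, 2), 2, 1)])])
    config = initial_configuration(spec)
    rule = select_rule("d", 7, config, spec.resolver)
    assert isinstance(rule, FiringRule) and rule.consume == 2


def test_select_rule_output_neuron_guards_are_disjoint():
    # among the four output-neuron rules only the a^2 dissolution admits 2 spikes
    spec = make_spec(["o"], [], [("o", 2)], [("o", _output_rules())])
    config = initial_configuration(spec)
    rule = select_rule("o", 2, config, spec.resolver)
    assert isinstance(rule, DissolutionRule)
    assert rule.guard.contains(2)
    # and exactly one rule is applicable at every count reachable in a run
    for spikes in range(0, 40):
        assert len(applicable_rules("o", spikes, config, spec.resolver)) <= 1


def test_strict_mode_raises_on_constructed_ambiguity():
    rules = [("x", [FiringRule(singleton(1), 1, 1), ForgettingRule(singleton(1), 1)])]
    spec = make_spec(["x"], [], [("x", 1)], rules)
    config = initial_configuration(spec)
    with pytest.raises(AmbiguityError) as exc:
        select_rule("x", 1, config, spec.resolver)
    assert exc.value.spikes == 1
    # random mode with a seed picks one deterministically instead
    import random

    rule = select_rule("x", 1, config, spec.resolver, mode="random", rng=random.Random(0))
    assert rule is not None


def test_random_mode_requires_seed():
    rules = [("x", [FiringRule(singleton(1), 1, 1), ForgettingRule(singleton(1), 1)])]
    spec = make_spec(["x"], [], [("x", 1)], rules)
    with pytest.raises(SpecError):
        run(spec, mode="random", seed=None)


# ---------------------------------------------------------------------------
# division: blocking condition, inheritance, dictionary instantiation
# ---------------------------------------------------------------------------


def test_division_blocked_by_existing_synapse(division_system):
    config = initial_configuration(division_system)
    blocked, allowed = division_system.resolver.resolve("3")
    # [a]_3 -> []_2 || []_3 is blocked by the existing synapse (2, 3)
    assert not division_allowed(config, "3", blocked)
    # [a]_3 -> []_3 || []_4 violates nothing
    assert division_allowed(config, "3", allowed)
    # so strict selection is unambiguous and picks the unblocked rule
    assert select_rule("3", 1, config, division_system.resolver) is allowed


def test_division_inherits_synapses(division_system):
    config = initial_configuration(division_system)
    events = step(config, division_system)
    assert sorted(n.label for n in config.neurons.values()) == ["1", "2", "3", "4"]
    label_edges = sorted(
        (config.neurons[u].label, config.neurons[v].label)
        for u, v in config.synapse_pairs()
    )
    # children of neuron 3 inherit (2, 3) as (2, 3) and (2, 4)
    assert label_edges == [("1", "2"), ("2", "3"), ("2", "4")]
    divide = [e for e in events if e.kind == tr.DIVIDE]
    assert len(divide) == 1 and divide[0].label == "3"
    children = {c["label"] for c in divide[0].data["children"]}
    assert children == {"3", "4"}
    # children start empty and the parent's spike was consumed
    assert all(n.spikes == 0 for n in config.neurons.values())


def test_division_with_nothing_to_inherit():
    spec = make_spec(
        ["p", "l", "r"], [], [("p", 1)],
        [("p", [DivisionRule(singleton(1), "l", "r")])],
    )
    config = initial_configuration(spec)
    step(config, spec)
    assert sorted(n.label for n in config.neurons.values()) == ["l", "r"]
    assert config.synapse_pairs() == []


def test_division_instantiates_dictionary_against_existing_neurons():
    # dictionary pair (w, l) only materialises when an l-labeled neuron appears
    spec = make_spec(
        ["p", "l", "r", "w"], [("w", "l")], [("p", 1), ("w", 0)],
        [("p", [DivisionRule(singleton(1), "l", "r")])],
    )
    config = initial_configuration(spec)
    assert config.synapse_pairs() == []  # not retroactive, not anticipatory
    step(config, spec)
    label_edges = sorted(
        (config.neurons[u].label, config.neurons[v].label)
        for u, v in config.synapse_pairs()
    )
    assert label_edges == [("w", "l")]


# ---------------------------------------------------------------------------
# dissolution
# ---------------------------------------------------------------------------


def test_dissolution_removes_neuron_and_incident_synapses(dissolution_system):
    config = initial_configuration(dissolution_system)
    assert len(config.synapse_pairs()) == 1
    events = step(config, dissolution_system)
    assert [n.label for n in config.neurons.values()] == ["2"]
    assert config.synapse_pairs() == []
    assert [e.kind for e in events] == [tr.DISSOLVE]


def test_dissolving_isolated_neuron_leaves_rest_untouched():
    spec = make_spec(
        ["iso", "a", "b"], [("a", "b")],
        [("iso", 1), ("a", 3), ("b", 2)],
        [("iso", [DissolutionRule(singleton(1))])],
    )
    config = initial_configuration(spec)
    before_edges = config.synapse_pairs()
    step(config, spec)
    assert sorted(n.label for n in config.neurons.values()) == ["a", "b"]
    assert {n.label: n.spikes for n in config.neurons.values()} == {"a": 3, "b": 2}
    assert config.synapse_pairs() == before_edges


# ---------------------------------------------------------------------------
# delays, closed neurons, delivery timing
# ---------------------------------------------------------------------------


def test_delayed_firing_closes_neuron_and_emits_on_time():
    # a fires with delay 2 at step 1 -> closed at steps 1-2, b receives at step 3
    spec = make_spec(
        ["a", "b"], [("a", "b")], [("a", 1), ("b", 0)],
        [("a", [FiringRule(singleton(1), 1, 1, delay=2)])],
    )
    config = initial_configuration(spec)
    step(config, spec)
    a = next(n for n in config.neurons.values() if n.label == "a")
    b = next(n for n in config.neurons.values() if n.label == "b")
    assert not a.is_open(1) and not a.is_open(2) and a.is_open(3)
    assert config.pending == [(3, a.id, 1)]
    step(config, spec)  # step 2: nothing due yet
    assert b.spikes == 0
    events = step(config, spec)  # step 3: emission lands
    assert b.spikes == 1
    assert any(e.kind == tr.DELIVER and e.label == "b" for e in events)


def test_spikes_sent_to_closed_neuron_are_lost():
    # a closes itself for 2 steps at step 1; b's same-step spike is lost
    spec = make_spec(
        ["a", "b"], [("a", "b"), ("b", "a")], [("a", 1), ("b", 1)],
        [
            ("a", [FiringRule(singleton(1), 1, 1, delay=2)]),
            ("b", [FiringRule(singleton(1), 1, 1)]),
        ],
    )
    config = initial_configuration(spec)
    events = step(config, spec)
    lost = [e for e in events if e.kind == tr.LOST]
    assert len(lost) == 1 and lost[0].label == "a"
    a = next(n for n in config.neurons.values() if n.label == "a")
    assert a.spikes == 0  # the in-flight spike never lands


def test_spikes_delivered_at_step_t_usable_at_t_plus_1():
    # chain a -> b: a fires at step 1, b only sees the spike at step 2
    spec = make_spec(
        ["a", "b"], [("a", "b")], [("a", 1), ("b", 0)],
        [
            ("a", [FiringRule(singleton(1), 1, 1)]),
            ("b", [FiringRule(singleton(1), 1, 1)]),
        ],
    )
    config = initial_configuration(spec)
    events1 = step(config, spec)
    assert not any(e.kind == tr.FIRE and e.label == "b" for e in events1)
    events2 = step(config, spec)
    assert any(e.kind == tr.FIRE and e.label == "b" for e in events2)


def test_external_input_to_dissolved_neuron_is_lost():
    spec = make_spec(
        ["gone"], [], [("gone", 1)],
        [("gone", [DissolutionRule(singleton(1))])],
        in_labels=["gone"],
    )
    trains = {"gone": [0, 5]}
    result = run(spec, trains)
    lost = [e for e in result.events if e.kind == tr.LOST]
    assert len(lost) == 1 and lost[0].data["amount"] == 5


# ---------------------------------------------------------------------------
# halting and run
# ---------------------------------------------------------------------------


def test_quiescent_system_is_halted_immediately():
    spec = make_spec(["a"], [], [("a", 0)], [("a", [FiringRule(singleton(1), 1, 1)])])
    config = initial_configuration(spec)
    assert is_halted(config, spec)
    result = run(spec)
    assert result.halting_step == 0 and result.events == []


def test_unmatchable_spikes_do_not_block_halting():
    # 1 spike against guard {3, 5, 7, ...}: no applicable rule, halted
    spec = make_spec(["d"], [], [("d", 1)], [("d", [FiringRule(at_least_every(3, 2), 2, 1)])])
    config = initial_configuration(spec)
    assert is_halted(config, spec)


def test_pending_emission_blocks_halting():
    spec = make_spec(
        ["a", "b"], [("a", "b")], [("a", 1), ("b", 0)],
        [("a", [FiringRule(singleton(1), 1, 1, delay=4)])],
    )
    config = initial_configuration(spec)
    step(config, spec)
    assert not is_halted(config, spec)


def test_future_train_entries_block_halting():
    spec = make_spec(["a"], [], [("a", 0)], [], in_labels=["a"])
    config = initial_configuration(spec)
    assert not is_halted(config, spec, {"a": [0, 0, 3]})
    assert is_halted(config, spec, {"a": [0, 0, 0]})


def test_max_steps_exceeded_raises():
    # a two-neuron oscillator never halts
    spec = make_spec(
        ["a", "b"], [("a", "b"), ("b", "a")], [("a", 1), ("b", 0)],
        [
            ("a", [FiringRule(singleton(1), 1, 1)]),
            ("b", [FiringRule(singleton(1), 1, 1)]),
        ],
    )
    with pytest.raises(MaxStepsExceeded):
        run(spec, max_steps=25)


# ---------------------------------------------------------------------------
# global invariants on a full construction run
# ---------------------------------------------------------------------------


def test_run_invariants_on_sat_construction(sat_instance):
    """Spike counts stay nonnegative, synapses reference live neurons and
    never self-loop, and closed neurons' counts stay frozen, at every step."""
    spec = build_sat_system(sat_instance.n, sat_instance.m)
    trains = build_sat_input(sat_instance)
    config = initial_configuration(spec)
    frozen: dict[int, int] = {}
    while not is_halted(config, spec, trains):
        step(config, spec, trains)
        live = set(config.neurons)
        for u, v in config.synapse_pairs():
            assert u in live and v in live and u != v
        for neuron in config.neurons.values():
            assert neuron.spikes >= 0
            if not neuron.is_open(config.step + 1):  # still closed next step
                if neuron.id in frozen:
                    assert neuron.spikes == frozen[neuron.id]
                frozen[neuron.id] = neuron.spikes
            else:
                frozen.pop(neuron.id, None)


def test_trace_replay_reproduces_final_counts(sat_instance):
    spec = build_sat_system(sat_instance.n, sat_instance.m)
    trains = build_sat_input(sat_instance)
    result = run(spec, trains)
    initial = {i + 1: spikes for i, (_, spikes) in enumerate(spec.initial)}
    replayed = tr.replay_spike_deltas(initial, result.events)
    actual = result.config.spikes_by_id()
    assert replayed == actual
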