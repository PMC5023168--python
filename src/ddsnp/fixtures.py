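"""Built-in micro-systems and worked instances, reconstructed from code.

``division_example_system`` is the canonical two-division-rule micro
example (one rule blocked by an existing synapse, the other applicable);
``dissolution_example_system`` is the matching dissolution micro
example.  ``worked_sat_instance`` and ``worked_subsetsum_instance`` are
the classic worked instances whose results the acceptance suite pins.
"""

from __future__ import annotations

from .guards import singleton
from .rules import DissolutionRule, DivisionRule, RuleResolver
from .sat import CNFInstance
from .subsetsum import SubsetSumInstance
from .system import SynapseDictionary, SystemSpec

#: an out-pattern that matches no label (micro-systems have no outputs)
NO_OUTPUT = "(?!)"


def division_example_system() -> SystemSpec:
    """Three neurons, synapses (1,2) and (2,3); neuron 3 holds one spike
    and two division rules.  ``[a]_3 -> []_2 || []_3`` is blocked by the
    existing synapse (2,3); only ``[a]_3 -> []_3 || []_4`` can apply, and
    the children inherit neuron 2's synapse as (2,3) and (2,4)."""
    one = singleton(1)
    return SystemSpec(
        labels=["1", "2", "3", "4"],
        syn=SynapseDictionary([("1", "2"), ("2", "3")]),
        initial=[("1", 0), ("2", 0), ("3", 1)],
        resolver=RuleResolver([
            ("3", [DivisionRule(one, "2", "3"), DivisionRule(one, "3", "4")]),
        ]),
        in_labels=[],
        out_pattern=NO_OUTPUT,
        name="division-example",
    )


def dissolution_example_system() -> SystemSpec:
    """Two neurons joined by synapse (1,2); neuron 1 holds one spike and
    dissolves, taking the synapse with it."""
    return SystemSpec(
        labels=["1", "2"],
        syn=SynapseDictionary([("1", "2")]),
        initial=[("1", 1), ("2", 0)],
        resolver=RuleResolver([
            ("1", [DissolutionRule(singleton(1))]),
        ]),
        in_labels=[],
        out_pattern=NO_OUTPUT,
        name="dissolution-example",
    )


def worked_sat_instance() -> CNFInstance:
    """(x1 ∨ x2) ∧ (¬x2 ∨ x3) ∧ (¬x1 ∨ x2 ∨ x3) — satisfied by exactly
    the assignments 111, 101 and 011."""
    return CNFInstance.from_lists(3, [{1, 2}, {-2, 3}, {-1, 2, 3}])


def worked_subsetsum_instance() -> SubsetSumInstance:
    """X = {1, 2, 3, 4}, S = 5 — solved by exactly {2, 3} and {1, 4}."""
    return SubsetSumInstance.from_lists([1, 2, 3, 4], 5)


def catalog() -> dict[str, object]:
    """Name -> constructor for every built-in fixture."""
    return {
        "division_example_system": division_example_system,
        "dissolution_example_system": dissolution_example_system,
        "worked_sat_instance": worked_sat_instance,
        "worked_subsetsum_instance": worked_subsetsum_instance,
    }
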