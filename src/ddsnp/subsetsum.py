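"""Uniform DDSN P system family enumerating Subset Sum solutions.

One system Π_n covers every instance (X = {x_1..x_n}, S) with n positive
integers.  Each x_i enters its input neuron as 3·x_i + 3 spikes at step
2n + 1; the target enters neuron ``s`` as 2S spikes (an even count no
rule in ``s`` can touch until neuron 4 adds the odd trigger spike).

Stages:

* **generation** (steps 1..2n): identical pacing to the SAT family; the
  2^n output neurons ``o_<t1..tn>`` enumerate the subsets (bit i = 1
  means x_i ∈ B).
* **input** (through step 2n + x_max + 4): input neuron i drips three
  spikes per step for x_i steps through d_i2 into exactly the subsets
  containing x_i, so each output neuron accumulates 3·Σ_{b∈B} b spikes;
  the closing single spike travels through d_i1 to neuron 4, which
  fires into ``s`` once all n inputs are done.
* **checking** (from step 2n + x_max + 5): neuron ``s`` holds 2S + 1
  spikes and pays the output neurons 2 spikes per step S times, then a
  final single spike.  Each payment funds one forgetting of 5 spikes
  (net −3 per step, one unit of the sum).  A neuron whose sum hits zero
  early is caught holding 2 spikes and dissolves; one still holding
  1 (mod 3) spikes when the single spike lands dissolves; only sums
  exactly equal to S survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .engine import STRICT, run
from .guards import at_least_every, singleton
from .rules import DissolutionRule, DivisionRule, FiringRule, ForgettingRule, RuleResolver
from .system import SpikeTrainSet, SynapseDictionary, SystemSpec


@dataclass(frozen=True)
class SubsetSumInstance:
    """A Subset Sum instance: positive integers X and a positive target S.

    x_i >= 1 is required by the encoding: 3·x_i + 3 >= 6 must trigger the
    drip rule ``a^3(a^3)^+/a^3 -> a^3`` at least once (x_i = 0 would skip
    it yet still emit the closing spike, corrupting the tally).
    """

    X: tuple[int, ...]
    S: int

    def __post_init__(self):
        if len(self.X) < 2:
            raise ValueError("n >= 2 required (the division chain degenerates at n = 1)")
        if any(x < 1 for x in self.X):
            raise ValueError("all x_i must be positive integers")
        if self.S < 1:
            raise ValueError("S must be a positive integer")

    @classmethod
    def from_lists(cls, X, S: int) -> "SubsetSumInstance":
        return cls(tuple(int(x) for x in X), int(S))

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def x_max(self) -> int:
        return max(self.X)


def _in_label(i: int) -> str:
    return f"in_{i}"


def _d_label(i: int, which: int) -> str:
    return f"d{i}_{which}"


# Guards shared with the closed-form checking-stage replay below.
OUT_FORGET_GUARD = at_least_every(5, 3)   # a^2(a^3)^+ : {5, 8, 11, ...}
OUT_DISSOLVE_HIGH = at_least_every(4, 3)  # a(a^3)^+   : {4, 7, 10, ...}
OUT_DISSOLVE_LOW = singleton(2)           # a^2


def _output_rules() -> list:
    return [
        ForgettingRule(OUT_FORGET_GUARD, 5),
        ForgettingRule(singleton(1), 1),
        DissolutionRule(OUT_DISSOLVE_HIGH),
        DissolutionRule(OUT_DISSOLVE_LOW),
    ]


def build_subsetsum_system(n: int) -> SystemSpec:
    """Construct Π_n: 3n + 6 initial neurons."""
    if n < 2:
        raise ValueError("build_subsetsum_system requires n >= 2")

    labels = ["0", "1", "2", "3", "4", "s"]
    labels += [_in_label(i) for i in range(1, n + 1)]
    labels += [_d_label(i, w) for i in range(1, n + 1) for w in (1, 2)]
    labels += [f"re:o_[01]{{1,{n}}}"]

    syn_pairs: list[tuple[str, str]] = [
        ("3", "2"), ("2", "1"), ("1", "2"), ("1", "0"), ("4", "s"), ("s", "0"),
    ]
    for i in range(1, n + 1):
        syn_pairs += [
            (_in_label(i), _d_label(i, 1)),
            (_in_label(i), _d_label(i, 2)),
            (_d_label(i, 1), "4"),
        ]
    syn_pairs.append((_d_label(1, 2), "o_1"))
    for i in range(2, n + 1):
        syn_pairs.append((_d_label(i, 2), f"re:o_[01]{{{i - 1}}}1"))

    one = singleton(1)
    rules: list[tuple[str, list]] = [
        ("1", [FiringRule(one, 1, 1)]),
        ("2", [FiringRule(one, 1, 1), ForgettingRule(singleton(2), 2)]),
        ("3", [FiringRule(one, 1, 1, delay=2 * n - 1)]),
        ("4", [FiringRule(singleton(n), n, 1)]),
        ("s", [FiringRule(at_least_every(3, 2), 2, 2), FiringRule(one, 1, 1)]),
    ]
    for i in range(1, n + 1):
        rules.append((_in_label(i), [
            FiringRule(at_least_every(6, 3), 3, 3),
            FiringRule(singleton(3), 3, 1),
        ]))
        rules.append((_d_label(i, 1), [
            FiringRule(one, 1, 1),
            ForgettingRule(singleton(3), 3),
        ]))
        rules.append((_d_label(i, 2), [
            FiringRule(singleton(3), 3, 3),
            ForgettingRule(singleton(1), 1),
        ]))
    rules.append(("0", [DivisionRule(one, "o_1", "o_0")]))
    rules.append((f"re:o_[01]{{1,{n - 1}}}",
                  [DivisionRule(one, "{label}1", "{label}0")]))
    rules.append((f"re:o_[01]{{{n}}}", _output_rules()))

    initial = [("0", 1), ("1", 0), ("2", 1), ("3", 1), ("4", 0), ("s", 0)]
    initial += [(_in_label(i), 0) for i in range(1, n + 1)]
    initial += [(_d_label(i, w), 0) for i in range(1, n + 1) for w in (1, 2)]

    return SystemSpec(
        labels=labels,
        syn=SynapseDictionary(syn_pairs),
        initial=initial,
        resolver=RuleResolver(rules),
        in_labels=[_in_label(i) for i in range(1, n + 1)] + ["s"],
        out_pattern=f"o_[01]{{{n}}}",
        name=f"subsetsum-{n}",
        declared_horizon=None,  # set per instance by solve_subsetsum
    )


def formula_horizon(inst: SubsetSumInstance) -> int:
    """The construction's declared step count 2n + x_max + S + 5."""
    return 2 * inst.n + inst.x_max + inst.S + 5


#: Constant offset of the simulated halting step from the declared
#: formula, pinned as a regression value: +1 whenever some subset sum
#: reaches S (the final single spike still has an output neuron to act
#: on), 0 when S exceeds every subset sum.
HALT_OFFSET = 1


def build_subsetsum_input(inst: SubsetSumInstance) -> SpikeTrainSet:
    """Trains of length 2n + 1: zeros, then 3·x_i + 3 into in_i and 2S
    into s, all at step 2n + 1."""
    n = inst.n
    trains: SpikeTrainSet = {
        _in_label(i): [0] * (2 * n) + [3 * inst.X[i - 1] + 3]
        for i in range(1, n + 1)
    }
    trains["s"] = [0] * (2 * n) + [2 * inst.S]
    return trains


def decode_subset(label_bits: str, inst: SubsetSumInstance) -> tuple[int, ...]:
    """Bitstring -> the subset's values (index-based; duplicates distinct)."""
    return tuple(inst.X[i] for i, bit in enumerate(label_bits) if bit == "1")


def solve_subsetsum(inst: SubsetSumInstance, max_steps: int | None = None) -> tuple[set[str], int]:
    """Run Π_n on the instance; return (solution bitstrings, halting step)."""
    spec = build_subsetsum_system(inst.n)
    spec.declared_horizon = formula_horizon(inst)
    trains = build_subsetsum_input(inst)
    result = run(spec, trains, max_steps=max_steps, mode=STRICT)
    return {l[2:] for l in result.surviving_out_labels}, result.halting_step


def brute_force_subsetsum(inst: SubsetSumInstance) -> set[str]:
    """Independent oracle: enumerate all 2^n subsets."""
    if inst.n > 20:
        raise ValueError("brute force limited to n <= 20")
    solutions = set()
    for bits in product("10", repeat=inst.n):
        total = sum(x for x, b in zip(inst.X, bits) if b == "1")
        if total == inst.S:
            solutions.add("".join(bits))
    return solutions


@dataclass(frozen=True)
class CheckingTrace:
    """Closed-form replay of the checking stage for one output neuron.

    ``counts[u]`` is the neuron's spike count at the start of offset u,
    where offset 0 is the step at which neuron ``s`` first fires; the
    neuron acts (forgets/dissolves) at offsets >= 1.  ``final_offset``
    is the offset of the dissolution (non-survivors) or of the last
    forgetting (survivors).
    """

    survives: bool
    final_offset: int
    counts: tuple[int, ...]


def checking_stage_trace(sum_b: int, S: int) -> CheckingTrace:
    """Replay the three-case checking-stage algebra for a neuron holding
    3·sum_b spikes, paid 2 spikes per step S times and then 1 spike.

    Independent of the engine: a direct loop over the output-neuron
    guards, used as the dual route against engine traces in tests.
    """
    if sum_b < 0 or S < 1:
        raise ValueError("sum_b >= 0 and S >= 1 required")
    spikes = 3 * sum_b
    counts = [spikes]
    spikes += 2  # delivery at offset 0 (s's first payment)
    for u in range(1, S + sum_b + 3):
        counts.append(spikes)
        # the four output-neuron rules are mutually exclusive by residue
        if OUT_DISSOLVE_LOW.contains(spikes) or OUT_DISSOLVE_HIGH.contains(spikes):
            return CheckingTrace(False, u, tuple(counts))
        acted = True
        if OUT_FORGET_GUARD.contains(spikes):
            spikes -= 5
        elif spikes == 1:
            spikes -= 1
        else:
            acted = False
        if u < S:
            spikes += 2
        elif u == S:
            spikes += 1  # s's closing single spike
        elif spikes == 0:
            return CheckingTrace(True, u, tuple(counts))
        elif not acted:
            # quiescent with leftover spikes no rule admits; cannot occur
            # on the reachable counts but terminates the replay regardless
            return CheckingTrace(True, u, tuple(counts))
    raise AssertionError("checking-stage replay failed to terminate")
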