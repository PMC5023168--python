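"""Uniform DDSN P system family solving SAT(n, m) in 2n + m + 3 steps.

One system Π_{n,m} covers every CNF with n variables and m clauses; the
instance enters as spike trains.  Clause i encodes each variable j as a
spike count α_{i,j}: one spike if x_j occurs, two if ¬x_j occurs, none
otherwise.  The run has three stages:

* **generation** (steps 1..2n): neuron 0 and its descendants divide once
  every other step, producing the 2^n output neurons ``o_<t1..tn>`` —
  one per truth assignment — while auxiliary neurons 1, 2, 3 pace the
  divisions and neuron 3's delayed spike shuts the pacemaker off.
* **input** (steps 2n+1..2n+m): clause c enters at step 2n+c, padded by
  the 2n-zero prefix.  Neuron d contributes one extra spike per clause,
  so each per-variable checker Cx_i1 / Cx_i0 sees 1, 2 or 3 spikes and
  emits one "this literal does not help you" spike to exactly the
  assignments where variable i fails the clause.
* **satisfiability** (through step 2n+m+3): an output neuron receiving
  all n failure spikes from one clause falsifies it and dissolves;
  fewer than n spikes are forgotten.  Survivors at halting are exactly
  the satisfying assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .engine import STRICT, run
from .errors import ComplementaryLiteralError
from .guards import at_least_every, singleton
from .rules import DissolutionRule, DivisionRule, FiringRule, ForgettingRule, RuleResolver
from .system import SpikeTrainSet, SynapseDictionary, SystemSpec


@dataclass(frozen=True)
class CNFInstance:
    """A CNF formula: n variables, clauses as sets of signed indices.

    A positive index +j stands for the literal x_j, a negative index -j
    for ¬x_j (variables are 1-indexed).  Duplicate literals collapse;
    clauses holding a complementary pair are rejected because the unary
    α encoding cannot represent them.
    """

    n: int
    clauses: tuple[frozenset[int], ...]

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(
                "n >= 2 required: at n = 1 the output-neuron rule schema "
                "degenerates (no forgetting rules, and the generation-stage "
                "cleanup spike would trigger the dissolution rule [a] -> δ)"
            )
        if len(self.clauses) < 1:
            raise ValueError("at least one clause required")
        for clause in self.clauses:
            for lit in clause:
                if lit == 0 or abs(lit) > self.n:
                    raise ValueError(f"literal {lit} out of range 1..{self.n}")
            for lit in clause:
                if -lit in clause:
                    raise ComplementaryLiteralError(
                        f"clause {sorted(clause)} contains both {abs(lit)} and its negation"
                    )

    @classmethod
    def from_lists(cls, n: int, clauses) -> "CNFInstance":
        return cls(n, tuple(frozenset(c) for c in clauses))

    @property
    def m(self) -> int:
        return len(self.clauses)


def encode_clause(clause: frozenset[int], n: int) -> tuple[int, ...]:
    """The α vector of one clause: spike count per variable 1..n."""
    alphas = []
    for j in range(1, n + 1):
        if j in clause and -j in clause:
            raise ComplementaryLiteralError(
                f"clause {sorted(clause)} contains both x_{j} and ¬x_{j}"
            )
        if j in clause:
            alphas.append(1)
        elif -j in clause:
            alphas.append(2)
        else:
            alphas.append(0)
    return tuple(alphas)


def _in_label(i: int) -> str:
    return f"in_x{i}"


def _cx_label(i: int, bit: int) -> str:
    return f"Cx{i}_{bit}"


def build_sat_system(n: int, m: int) -> SystemSpec:
    """Construct Π_{n,m}: 3n + 5 initial neurons, answer final at 2n+m+3."""
    if n < 2:
        raise ValueError("build_sat_system requires n >= 2 (see CNFInstance)")
    if m < 1:
        raise ValueError("build_sat_system requires m >= 1")

    labels = ["0", "1", "2", "3", "d"]
    labels += [_in_label(i) for i in range(1, n + 1)]
    labels += [_cx_label(i, b) for i in range(1, n + 1) for b in (1, 0)]
    labels += [f"re:o_[01]{{1,{n}}}"]

    syn_pairs: list[tuple[str, str]] = [("3", "2"), ("2", "1"), ("1", "2"), ("1", "0"), ("3", "d")]
    syn_pairs += [("d", _in_label(i)) for i in range(1, n + 1)]
    for i in range(1, n + 1):
        syn_pairs += [(_in_label(i), _cx_label(i, 1)), (_in_label(i), _cx_label(i, 0))]
    syn_pairs += [(_cx_label(1, 1), "o_1"), (_cx_label(1, 0), "o_0")]
    for i in range(2, n + 1):
        syn_pairs.append((_cx_label(i, 1), f"re:o_[01]{{{i - 1}}}1"))
        syn_pairs.append((_cx_label(i, 0), f"re:o_[01]{{{i - 1}}}0"))

    one = singleton(1)
    rules: list[tuple[str, list]] = [
        ("1", [FiringRule(one, 1, 1)]),
        ("2", [FiringRule(one, 1, 1), ForgettingRule(singleton(2), 2)]),
        ("3", [FiringRule(one, 1, 1, delay=2 * n - 1)]),
        ("d", [FiringRule(at_least_every(3, 2), 2, 1)]),
    ]
    for i in range(1, n + 1):
        rules.append((_in_label(i), [FiringRule(singleton(k), k, k) for k in (1, 2, 3)]))
    for i in range(1, n + 1):
        rules.append((_cx_label(i, 1), [
            FiringRule(one, 1, 1),
            FiringRule(singleton(3), 3, 1),
            ForgettingRule(singleton(2), 2),
        ]))
        rules.append((_cx_label(i, 0), [
            FiringRule(one, 1, 1),
            FiringRule(singleton(2), 2, 1),
            ForgettingRule(singleton(3), 3),
        ]))
    rules.append(("0", [DivisionRule(one, "o_1", "o_0")]))
    if n >= 2:
        rules.append((f"re:o_[01]{{1,{n - 1}}}",
                      [DivisionRule(one, "{label}1", "{label}0")]))
    leaf_rules: list = [ForgettingRule(singleton(k), k) for k in range(1, n)]
    leaf_rules.append(DissolutionRule(singleton(n)))
    rules.append((f"re:o_[01]{{{n}}}", leaf_rules))

    initial = [("0", 1), ("1", 0), ("2", 1), ("3", 1), ("d", 2 * m)]
    initial += [(_in_label(i), 0) for i in range(1, n + 1)]
    initial += [(_cx_label(i, b), 0) for i in range(1, n + 1) for b in (1, 0)]

    return SystemSpec(
        labels=labels,
        syn=SynapseDictionary(syn_pairs),
        initial=initial,
        resolver=RuleResolver(rules),
        in_labels=[_in_label(i) for i in range(1, n + 1)],
        out_pattern=f"o_[01]{{{n}}}",
        name=f"sat-{n}-{m}",
        declared_horizon=2 * n + m + 3,
    )


def build_sat_input(cnf: CNFInstance) -> SpikeTrainSet:
    """Per-variable spike trains: a 2n-zero prefix (the generation stage
    needs the time), then α_{c,j} for clause c at step 2n + c."""
    n = cnf.n
    alphas = [encode_clause(clause, n) for clause in cnf.clauses]
    return {
        _in_label(j): [0] * (2 * n) + [alpha[j - 1] for alpha in alphas]
        for j in range(1, n + 1)
    }


def decode_out_label(label: str) -> str:
    """``o_101`` -> bitstring ``101`` (bit i is the value of x_i)."""
    if not label.startswith("o_"):
        raise ValueError(f"not an output label: {label!r}")
    return label[2:]


def solve_sat(cnf: CNFInstance, max_steps: int | None = None) -> tuple[set[str], int]:
    """Run Π_{n,m} on ``cnf``; return (satisfying assignments, halting step).

    The returned set holds length-n bitstrings (1 = true); it is empty
    iff the formula is unsatisfiable.
    """
    spec = build_sat_system(cnf.n, cnf.m)
    trains = build_sat_input(cnf)
    result = run(spec, trains, max_steps=max_steps, mode=STRICT)
    return {decode_out_label(l) for l in result.surviving_out_labels}, result.halting_step


def brute_force_sat(cnf: CNFInstance) -> set[str]:
    """Independent oracle: enumerate all 2^n assignments."""
    if cnf.n > 20:
        raise ValueError("brute force limited to n <= 20")
    solutions = set()
    for bits in product("10", repeat=cnf.n):
        assignment = {j + 1: bits[j] == "1" for j in range(cnf.n)}
        if all(
            any(assignment[abs(l)] == (l > 0) for l in clause)
            for clause in cnf.clauses
        ):
            solutions.add("".join(bits))
    return solutions
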