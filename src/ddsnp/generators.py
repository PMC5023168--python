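"""Seeded random-instance generators powering the property tests.

Identical seed and configuration always yield the identical instance.
Generated CNFs never place a variable and its negation in one clause
(the unary encoding cannot represent such clauses), and every generated
instance satisfies the family preconditions (n >= 2, positive values).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .sat import CNFInstance
from .subsetsum import SubsetSumInstance


@dataclass(frozen=True)
class CNFGeneratorConfig:
    """Random-CNF configuration: n ~ U[n_range], m ~ U[m_range], clause
    width drawn uniformly from ``width_choices`` and clamped to <= n,
    variables sampled without replacement, fair random signs."""

    seed: int
    n_range: tuple[int, int] = (2, 8)
    m_range: tuple[int, int] = (1, 8)
    width_choices: tuple[int, ...] = (2, 3)


@dataclass(frozen=True)
class SubsetSumGeneratorConfig:
    """Random Subset Sum configuration: n ~ U[n_range], values
    ~ U[1, value_max]; the target is either uniform in [1, Σx]
    (``planted=False``) or the sum of a random nonempty subset
    (``planted=True``, guaranteeing at least one solution)."""

    seed: int
    n_range: tuple[int, int] = (2, 8)
    value_max: int = 8
    planted: bool = False


def random_cnf(config: CNFGeneratorConfig) -> CNFInstance:
    # string seeds hash via sha512 in random.seed, stable across processes
    rng = random.Random(f"cnf-{config.seed}")
    n = rng.randint(*config.n_range)
    m = rng.randint(*config.m_range)
    clauses = []
    for _ in range(m):
        width = min(n, rng.choice(config.width_choices))
        variables = rng.sample(range(1, n + 1), width)
        clauses.append({v if rng.random() < 0.5 else -v for v in variables})
    return CNFInstance.from_lists(n, clauses)


def random_subsetsum(config: SubsetSumGeneratorConfig) -> SubsetSumInstance:
    rng = random.Random(f"subsetsum-{config.seed}")
    n = rng.randint(*config.n_range)
    X = [rng.randint(1, config.value_max) for _ in range(n)]
    if config.planted:
        size = rng.randint(1, n)
        S = sum(rng.sample(X, size))
    else:
        S = rng.randint(1, sum(X))
    return SubsetSumInstance.from_lists(X, S)
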