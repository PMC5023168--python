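"""Closed-form step-count formulas and comparison tables.

Reference step complexities for uniform membrane-computing solutions to
SAT and Subset Sum.  The competitor systems are represented only by
their published step-count formulas; they are not simulated.

For the nondeterministic competitor systems, which check a single
candidate subset per computation, the traversal totals sum the
per-subset cost over all 2^n − 1 nonempty subsets B, using the closed
form ``Σ_{B≠∅} Σ_{b∈B} b = 2^(n-1) · Σ_i x_i`` (every element appears in
half of the subsets), so the tables stay exact at any n.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

#: formula names for the SAT comparison, by mechanism
SAT_FORMULAS = ("budding", "division", "ddsn")
#: formula names for the Subset Sum comparison, by mechanism/encoding
SUBSETSUM_FORMULAS = ("binary", "unary", "snpsp", "timefree", "ddsn")


def sat_steps(n: int, m: int) -> dict[str, int]:
    """Steps to solve SAT(n, m) under each uniform construction:
    neuron division + budding (2n + mn + 6), neuron division alone
    (4n + mn + 5), and division + dissolution (2n + m + 3)."""
    if n < 1 or m < 1:
        raise ValueError("n >= 1 and m >= 1 required")
    return {
        "budding": 2 * n + m * n + 6,
        "division": 4 * n + m * n + 5,
        "ddsn": 2 * n + m + 3,
    }


def binary_width(x_max: int, S: int) -> int:
    """Minimal k such that every x_i and S fits in k binary bits."""
    return max(x_max, S).bit_length()


def subsetsum_steps(X: Iterable[int], S: int) -> dict[str, int]:
    """Steps to enumerate all Subset Sum solutions under each system.

    The nondeterministic systems decide one candidate subset per run;
    their totals are summed over all 2^n − 1 nonempty subsets
    (``(2^n − 1)``-fold traversal).  The division + dissolution system
    needs a single run of 2n + x_max + S + 5 steps.
    """
    X = tuple(int(x) for x in X)
    if not X or any(x < 1 for x in X) or S < 1:
        raise ValueError("positive integers X and positive S required")
    n = len(X)
    k = binary_width(max(X), S)
    n_subsets = 2 ** n - 1
    # Σ over nonempty subsets of the subset sum (closed form)
    total_of_sums = 2 ** (n - 1) * sum(X)
    return {
        "binary": n_subsets * (3 * k + 2),
        "unary": 3 * total_of_sums + 6 * n_subsets,
        "snpsp": 2 * total_of_sums + 6 * n_subsets,
        "timefree": 3 * total_of_sums + 2 * n_subsets,
        "ddsn": 2 * n + max(X) + S + 5,
    }


def sat_step_table(n_max: int = 50, m_max: int = 50) -> pd.DataFrame:
    """All three SAT formulas on the (n, m) grid, one row per cell."""
    rows = [
        {"n": n, "m": m, **sat_steps(n, m)}
        for n in range(1, n_max + 1)
        for m in range(1, m_max + 1)
    ]
    return pd.DataFrame(rows, columns=["n", "m", *SAT_FORMULAS])


def subsetsum_step_table(n_max: int = 50, S: int = 5) -> pd.DataFrame:
    """The five Subset Sum formulas on the series X = {1..n}, fixed S."""
    rows = []
    for n in range(1, n_max + 1):
        X = range(1, n + 1)
        rows.append({"n": n, "S": S, **subsetsum_steps(X, S)})
    return pd.DataFrame(rows, columns=["n", "S", *SUBSETSUM_FORMULAS])


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
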