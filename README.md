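# ddsnp

An exact, deterministic simulator for **spiking neural P systems with
neuron division and dissolution** (DDSN P systems), together with the two
uniform constructions built on them that solve SAT and Subset Sum in
linearly many steps and *enumerate every solution* as the labels of the
output neurons that survive the computation.

## The model

A DDSN P system is a directed graph of neurons

```
Π = (O, H, syn, n_1, …, n_m, R, in, out)
```

over the singleton spike alphabet `O = {a}`: each neuron carries a label
from `H`, a spike count, and the rules its label resolves to.  `syn ⊆
H × H` is a *synapse dictionary* that both defines the initial wiring and
says which synapses to create whenever a neuron with a listed label comes
into existence.  Four rule kinds act on a neuron holding `h` spikes with
`a^h ∈ L(E)` (guards `E` are unary regular expressions, stored as unions
of arithmetic progressions):

* **firing** `[E/a^c → a^p; d]` — consume `c` spikes, emit `p` spikes to
  every synapse target after delay `d`; the neuron is closed (receives
  nothing, does nothing) until the emission leaves, and spikes sent to a
  closed neuron are lost;
* **forgetting** `[E/a^s → λ]` — consume `s` spikes silently;
* **division** `[E]_i → [ ]_j ‖ [ ]_k` — replace the neuron by two empty
  children that inherit all its synapses and gain the dictionary synapses
  for their new labels; blocked if a synapse already connects labels
  `i, j` or `i, k` (it would become a self-loop);
* **dissolution** `[E]_i → δ` — remove the neuron and every incident
  synapse (the computational analogue of neuron apoptosis).

Each step every open neuron applies at most one applicable rule; neurons
act in parallel, and spikes delivered during step *t* become usable at
step *t + 1*.  A computation halts when all neurons are open, no rule
applies, and nothing is in flight.

Division generates an exponential workspace in linear time — after step
2k−1 of the constructions exactly 2^k output neurons `o_<bitstring>`
exist, one per assignment/subset — and dissolution prunes every candidate
the instance rules out, so the surviving output labels *are* the solution
set:

* **SAT, system Π_{n,m}** (any CNF with `n` variables, `m` clauses):
  clause `c` enters at step `2n + c`, encoded per variable as 1 spike
  (positive literal), 2 (negated) or 0 (absent); the answer is final at
  step `2n + m + 3`.
* **Subset Sum, system Π_n** (any `X = {x_1..x_n}`, target `S`): each
  `x_i` enters as `3·x_i + 3` spikes and is dripped, 3 spikes a step,
  into exactly the subsets containing it; a paying neuron then feeds the
  output neurons `2` spikes per step `S` times plus a closing single
  spike, and only neurons holding exactly `3·S` spikes survive the
  resulting forgetting/dissolution algebra.  The answer is final at step
  `2n + x_max + S + 5`.

## Worked example

The classic three-variable instance `(x1 ∨ x2) ∧ (¬x2 ∨ x3) ∧ (¬x1 ∨ x2 ∨ x3)`:

```
$ ddsnp sat --dimacs worked.cnf --oracle
oracle agreement: ok
halted at step 12
011
101
111
```

The system halts after 12 = 2·3 + 3 + 3 steps with three output neurons
alive: the assignments 111, 101 and 011 (bit *i* is the value of `x_i`)
are exactly the satisfying assignments, as the built-in 2^n brute-force
oracle confirms.  Likewise for subsets of {1, 2, 3, 4} summing to 5:

```
$ ddsnp subsetsum --set 1,2,3,4 --target 5 --oracle
oracle agreement: ok
halted at step 23
0110  {2, 3}
1001  {1, 4}
```

The formula horizon here is 22 = 2·4 + 4 + 5 + 5; the literal halt lands
one bookkeeping step later (see `docs/methods.md`), with the two
surviving neurons naming the solutions {2, 3} and {1, 4}.

Arbitrary systems can be described as JSON and run directly, with traces
and Graphviz snapshots:

```
$ ddsnp fixtures emit division_example_system --out system.json
$ ddsnp run --system system.json --trace trace.jsonl --dot after.dot
$ ddsnp complexity sat --n-max 50 --m-max 50 --out sat_steps.tsv
```

The same functionality is available as a library:

```python
from ddsnp import CNFInstance, solve_sat

solutions, halting_step = solve_sat(CNFInstance.from_lists(3, [{1, 2}, {-2, 3}, {-1, 2, 3}]))
# solutions == {"111", "101", "011"}, halting_step == 12
```

## Layout

| module | contents |
| --- | --- |
| `ddsnp.guards` | spike-count guards as unions of arithmetic progressions |
| `ddsnp.rules` | the four rule kinds and the label-pattern resolver |
| `ddsnp.system` | system specs, configurations, the synapse dictionary |
| `ddsnp.engine` | the three-phase step semantics, halting, `run` |
| `ddsnp.sat`, `ddsnp.subsetsum` | the two uniform families + brute-force oracles |
| `ddsnp.complexity` | step-count formulas and comparison tables |
| `ddsnp.io`, `ddsnp.fixtures`, `ddsnp.generators` | DIMACS/JSON/DOT, built-in examples, seeded instance generators |
| `ddsnp.cli` | the `ddsnp` command |
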