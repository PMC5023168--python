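# Methods

## Step semantics

The engine executes one synchronous transition in three phases.

1. **Select.**  Every live, open neuron examines its start-of-step spike
   count against its label's rules and picks at most one applicable rule.
   Selection is simultaneous across neurons: no neuron sees any effect of
   the current step.  A division rule whose structural condition fails
   (a runtime synapse already connects the parent's label to a child
   label, in either direction) is simply inapplicable; other rules in the
   neuron stay eligible.  In the default *strict* mode two applicable
   rules raise `AmbiguityError` — the two solver families are
   deterministic, and strictness turns any accidental nondeterminism into
   a hard failure.  *Random* mode resolves ties with a caller-seeded RNG
   and refuses to run without a seed.
2. **Act.**  Firing consumes `c` spikes and schedules `p` spikes for
   phase 3 of step `t + d`; with `d ≥ 1` the neuron is closed during
   steps `t .. t+d−1` and open again (able to select and to receive) at
   `t + d`.  Division removes the parent and creates two empty children
   with fresh ids; children first inherit every incoming and outgoing
   synapse of the parent and then receive the synapse-dictionary
   instantiations for their new labels against every neuron existing at
   that moment.  Dictionary instantiation happens only at neuron creation
   (initially and on division), never retroactively.  Dissolution removes
   the neuron and all incident synapses.  When several neurons divide in
   one step they are processed in ascending id order; the families never
   wire two simultaneously dividing neurons together, so the order is
   unobservable there, but it makes arbitrary systems reproducible.
3. **Deliver.**  Emissions due this step travel along the *current*
   synapses of their source; external train entries for this step enter
   the input neurons.  Targets that are closed, dissolved, or divided
   away this very step do not receive — the spikes are logged as `lost`
   events, as are inputs addressed to a vanished input neuron.  Spikes
   delivered during step `t` become usable at step `t + 1`.

Halting holds when all neurons are open, no rule is applicable, no
delayed emission is pending, and no future train entry carries spikes.
`run` reports the index of the last step executed before that condition
first holds.  `max_steps` defaults to ten times the family's declared
horizon (10 000 for hand-written systems) and overrunning it raises
`MaxStepsExceeded`, which in practice means a construction bug.

Neurons carry unique integer ids; labels may repeat, and rules, the
dictionary, and the division-blocking condition all work on labels.  A
neuron that reopens at `t + d` may select a rule at `t + d` with whatever
spikes it retained; the two families never exercise this corner (their
delayed neuron is empty after firing), so the choice is a documented
engine convention rather than a family requirement.

## Guards

Every guard is a finite union of arithmetic progressions
`{offset + k·period}` — exactly the unary regular languages, and
sufficient for every expression the families use (`a^k`, `a(a²)⁺`,
`a³(a³)⁺`, `a²(a³)⁺`, `a(a³)⁺`).  Membership is O(#progressions).  The
test suite cross-checks every construction guard against a textbook
regex engine on unary strings up to length 200, and property-tests random
unions the same way.

## The two solver families

`build_sat_system(n, m)` and `build_subsetsum_system(n)` build one system
per problem *size*; the instance arrives purely as input spikes, so the
constructions are uniform.  Both generate the 2^n output neurons
`o_<bitstring>` by a division cascade paced two steps per bit (the
`(a⁰·)^{2n}` train prefix buys exactly that time), then let per-variable
checker neurons feed "this candidate fails" evidence into the output
family, where forgetting absorbs survivable evidence and dissolution
eliminates refuted candidates.  The exponential rule and dictionary
families are expressed with regex label patterns (`o_[01]{k}`) and a
`{label}`-template division rule, so a system description stays O(n).

Sizes used throughout: the worked instances (n = 3, m = 3 SAT;
X = {1,2,3,4}, S = 5), random sweeps with n ∈ [2, 8], m ∈ [1, 8],
values ≤ 8 (clause width uniform on {2, 3} clamped to n, fair literal
signs, targets uniform on [1, Σx]), 200 seeds per family in the
acceptance suite and 40 in the fast unit sweeps.  Every run is
cross-checked against an independent 2^n brute-force oracle, and both
families run in strict mode, so determinism is verified on every step of
every tested run.

### Halting step versus formula horizon

The SAT family's answer is final at step `2n + m + 3`: clause `m` enters
at `2n + m`, its checker spikes land during `2n + m + 2`, and output
neurons act on them at `2n + m + 3`.  The literal halt coincides with
that horizon whenever some output neuron has something to do at the
final step, which is the generic case.  Two instance classes settle one
step early: (a) the first `m − 1` clauses already refuted every
assignment (the last volley of checker spikes lands on no one), and
(b) the last clause mentions all `n` variables and every surviving
assignment satisfies all of its literals (no failure spikes are sent at
all).  The tests assert this characterization in both directions —
`halting = 2n + m + 3` exactly when an output neuron acts at that step,
`2n + m + 2` otherwise — and the surviving set is identical either way.

The Subset Sum family has a fixed off-by-one of the same flavour: the
paying neuron `s` holds `2S + 1` spikes when checking starts at
`2n + x_max + 5`, fires `S` times and then once more, so the last
output-neuron action lands at `2n + x_max + S + 6` — one step past the
`2n + x_max + S + 5` horizon — whenever some subset sum reaches `S`
(always true for targets within `Σx`).  The offset is pinned as the
regression constant `HALT_OFFSET = 1`; step-count comparisons quote the
formula.

### Target delivery to the paying neuron

The target enters as `2S` spikes at step `2n + 1`.  The paying neuron's
rules (`a(a²)⁺/a² → a²` and `a → a`) only match odd counts, so the even
balance is inert until the collector neuron (label `4`), having received
one unit spike per completed input stream, adds the odd trigger — making
the delivery timing of `S` independent of everything else.

### checking_stage_trace

`checking_stage_trace(sum_b, S)` replays the checking stage of a single
output neuron in closed form — start at `3·sum_b` spikes, add 2 per step
`S` times and then 1, apply the unique admissible output rule each step —
without touching the engine.  The three outcomes: exact sums forget five
spikes `S` times and the closing spike once (survive); undershoots run
dry after `sum_b` forgettings and are caught holding 2 spikes
(dissolve); overshoots hold `1 (mod 3)` spikes when the closing spike
lands (dissolve).  Tests compare it step for step against the engine on
an isolated payer/output pair over the full grid `sum_b, S ≤ 30` and
against every output neuron of the complete worked-instance run.

## Instance generators

The seeded generators exist to drive the oracle-equivalence sweeps, and
deliberately cover unsatisfiable/insoluble instances (the empty surviving
set ⇔ no solution direction matters).  `planted=True` for Subset Sum
draws the target as the sum of a random nonempty subset, guaranteeing at
least one survivor.  Seeding uses string keys (`random.Random` hashes
them with SHA-512), so instances are stable across processes and
platforms.  What these synthetic instances do *not* probe: clause widths
above 3, values or targets beyond 8/Σx, n beyond 8 (the engine is exact
at any size, but runtime grows with 2^n neurons), or systems outside the
two families — the engine-level tests cover arbitrary topologies,
delays, duplicate labels and lost-spike cases separately.

## Step-count formulas

`sat_steps` and `subsetsum_steps` evaluate the published closed forms
exactly (Python integers, no floats).  Two accounting choices, fixed
here: the bit width `k` is the minimal width holding both `x_max` and
`S` (`⌈log₂(max+1)⌉`), and the traversal totals for the
single-candidate nondeterministic systems sum their per-subset cost over
all nonempty subsets via `Σ_{B≠∅} Σ_{b∈B} b = 2^{n−1}·Σx` — the pairing
that reproduces the published comparison values (165, 330, 270 on the
worked instance) and stays exact for the n ≤ 50 series tables.

## Known limitations

* Guards are unary-regular only (by design: that is the whole guard
  language of the model); no multi-symbol alphabets, extended rules,
  budding, or asynchronous modes.
* `n = 1` instances are rejected by both families: the output-neuron
  rule schema degenerates (no forgetting rules exist, and the
  generation-stage cleanup spike would trigger the SAT dissolution
  guard `[a¹]`), so the constructions are ill-defined there.
* Clauses containing a variable and its negation are rejected rather
  than simplified to *true*: the per-variable spike alphabet {0, 1, 2}
  cannot express them.
* Solving is by the constructions plus a 2^n oracle; nothing here is a
  competitive SAT or pseudo-polynomial Subset Sum solver, and the
  comparison systems are represented only by their step formulas.
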