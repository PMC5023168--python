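"""Readers and writers: DIMACS CNF, JSON system specs and spike trains,
JSON-lines traces, and DOT snapshots of configurations.

JSON artifacts are written canonically (sorted keys, two-space indent,
integers only) so that specs and traces are diffable and round-trip
byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, TextIO

from .errors import CountMismatchError, ParseError, SpecError
from .guards import SpikeCountSet
from .rules import (
    DissolutionRule,
    DivisionRule,
    FiringRule,
    ForgettingRule,
    Rule,
    RuleResolver,
)
from .sat import CNFInstance
from .system import Configuration, SpikeTrainSet, SynapseDictionary, SystemSpec
from .trace import TraceEvent

# ---------------------------------------------------------------------------
# DIMACS CNF
# ---------------------------------------------------------------------------


def parse_dimacs(text: str) -> CNFInstance:
    """Parse a standard DIMACS CNF document.

    Accepts ``c`` comment lines, one ``p cnf <vars> <clauses>`` header,
    and zero-terminated clauses that may span lines.  A ``%`` token ends
    the document (SATLIB convention).
    """
    header: tuple[int, int] | None = None
    clauses: list[set[int]] = []
    current: set[int] = set()
    open_clause = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("c"):
            continue
        if stripped.startswith("p"):
            if header is not None:
                raise ParseError("duplicate header", lineno)
            fields = stripped.split()
            if len(fields) != 4 or fields[1] != "cnf":
                raise ParseError(f"malformed header {stripped!r}", lineno)
            try:
                header = (int(fields[2]), int(fields[3]))
            except ValueError:
                raise ParseError(f"non-integer header counts in {stripped!r}", lineno)
            continue
        if stripped.startswith("%"):
            break
        if header is None:
            raise ParseError("clause before 'p cnf' header", lineno)
        for token in stripped.split():
            if token == "%":
                break
            try:
                lit = int(token)
            except ValueError:
                raise ParseError(f"non-integer literal {token!r}", lineno)
            if lit == 0:
                clauses.append(current)
                current = set()
                open_clause = False
            else:
                current.add(lit)
                open_clause = True
    if header is None:
        raise ParseError("missing 'p cnf' header")
    if open_clause:
        # tolerate a final clause missing its terminating zero
        clauses.append(current)
    n_vars, n_clauses = header
    if len(clauses) != n_clauses:
        raise CountMismatchError(
            f"header declares {n_clauses} clauses, found {len(clauses)}"
        )
    max_var = max((abs(l) for c in clauses for l in c), default=1)
    if max_var > n_vars:
        raise CountMismatchError(
            f"header declares {n_vars} variables, found literal {max_var}"
        )
    return CNFInstance.from_lists(n_vars, clauses)


def cnf_to_dimacs(cnf: CNFInstance) -> str:
    lines = [f"p cnf {cnf.n} {cnf.m}"]
    for clause in cnf.clauses:
        lines.append(" ".join(str(l) for l in sorted(clause, key=abs)) + " 0")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# System spec JSON
# ---------------------------------------------------------------------------

_RULE_KINDS = ("fire", "forget", "divide", "dissolve")


def _rule_to_obj(pattern: str, rule: Rule) -> dict[str, Any]:
    guard = [list(p) for p in rule.guard.progressions]
    if isinstance(rule, FiringRule):
        return {"pattern": pattern, "kind": "fire", "guard": guard,
                "consume": rule.consume, "produce": rule.produce, "delay": rule.delay}
    if isinstance(rule, ForgettingRule):
        return {"pattern": pattern, "kind": "forget", "guard": guard,
                "consume": rule.consume}
    if isinstance(rule, DivisionRule):
        return {"pattern": pattern, "kind": "divide", "guard": guard,
                "children": [rule.child_left, rule.child_right]}
    if isinstance(rule, DissolutionRule):
        return {"pattern": pattern, "kind": "dissolve", "guard": guard}
    raise SpecError(f"unknown rule kind: {rule!r}")


def _rule_from_obj(obj: dict[str, Any]) -> tuple[str, Rule]:
    try:
        kind = obj["kind"]
        pattern = obj["pattern"]
        guard = SpikeCountSet(tuple(tuple(int(v) for v in p) for p in obj["guard"]))
        if kind == "fire":
            return pattern, FiringRule(guard, int(obj["consume"]),
                                       int(obj["produce"]), int(obj.get("delay", 0)))
        if kind == "forget":
            return pattern, ForgettingRule(guard, int(obj["consume"]))
        if kind == "divide":
            left, right = obj["children"]
            return pattern, DivisionRule(guard, str(left), str(right))
        if kind == "dissolve":
            return pattern, DissolutionRule(guard)
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed rule object {obj!r}: {exc}")
    raise ParseError(f"unknown rule kind {kind!r} (expected one of {_RULE_KINDS})")


def system_to_obj(spec: SystemSpec) -> dict[str, Any]:
    rules = []
    for pattern, entry_rules in spec.resolver.entries:
        for rule in entry_rules:
            rules.append(_rule_to_obj(pattern.raw, rule))
    obj: dict[str, Any] = {
        "name": spec.name,
        "labels": list(spec.labels),
        "syn": [list(p) for p in spec.syn.raw_pairs()],
        "initial": [{"label": l, "spikes": s} for l, s in spec.initial],
        "rules": rules,
        "in": list(spec.in_labels),
        "out_pattern": spec.out_pattern,
    }
    if spec.declared_horizon is not None:
        obj["declared_horizon"] = spec.declared_horizon
    return obj


def system_from_obj(obj: dict[str, Any]) -> SystemSpec:
    try:
        labels = [str(l) for l in obj["labels"]]
        syn = SynapseDictionary([(str(a), str(b)) for a, b in obj["syn"]])
        initial = [(str(e["label"]), int(e["spikes"])) for e in obj["initial"]]
        rule_objs = obj["rules"]
        in_labels = [str(l) for l in obj["in"]]
        out_pattern = str(obj["out_pattern"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed system spec: {exc}")
    # group consecutive rules sharing a pattern into one resolver entry
    entries: list[tuple[str, list[Rule]]] = []
    for rule_obj in rule_objs:
        pattern, rule = _rule_from_obj(rule_obj)
        if entries and entries[-1][0] == pattern:
            entries[-1][1].append(rule)
        else:
            entries.append((pattern, [rule]))
    return SystemSpec(
        labels=labels,
        syn=syn,
        initial=initial,
        resolver=RuleResolver(entries),
        in_labels=in_labels,
        out_pattern=out_pattern,
        name=str(obj.get("name", "ddsnp-system")),
        declared_horizon=obj.get("declared_horizon"),
    )


def canonical_json(obj: Any) -> str:
    return json.dumps(obj, sort_keys=True, indent=2) + "\n"


def write_system(spec: SystemSpec, path) -> None:
    Path(path).write_text(canonical_json(system_to_obj(spec)))


def read_system(path) -> SystemSpec:
    return system_from_obj(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


def trains_to_obj(trains: SpikeTrainSet) -> dict[str, list[int]]:
    return {label: list(seq) for label, seq in trains.items()}


def trains_from_obj(obj: dict[str, Any]) -> SpikeTrainSet:
    try:
        return {str(label): [int(c) for c in seq] for label, seq in obj.items()}
    except (TypeError, ValueError) as exc:
        raise ParseError(f"malformed spike trains: {exc}")


def write_trains(trains: SpikeTrainSet, path) -> None:
    Path(path).write_text(canonical_json(trains_to_obj(trains)))


def read_trains(path) -> SpikeTrainSet:
    return trains_from_obj(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Traces (JSON lines)
# ---------------------------------------------------------------------------


def write_trace(events: list[TraceEvent], target) -> None:
    if hasattr(target, "write"):
        _write_trace_fh(events, target)
    else:
        with open(target, "w") as fh:
            _write_trace_fh(events, fh)


def _write_trace_fh(events: list[TraceEvent], fh: TextIO) -> None:
    for ev in events:
        fh.write(json.dumps(ev.to_dict(), sort_keys=True) + "\n")


def read_trace(source) -> list[TraceEvent]:
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    events = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            events.append(TraceEvent.from_dict(json.loads(line)))
        except (json.JSONDecodeError, KeyError) as exc:
            raise ParseError(f"malformed trace line: {exc}", lineno)
    return events


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------


def configuration_to_dot(config: Configuration, name: str = "ddsnp") -> str:
    """A Graphviz DOT drawing of a configuration: one node per live
    neuron ("label : spikes"), one edge per synapse.  Node ids are
    ``label@id`` so duplicate labels stay distinct."""
    lines = [f'digraph "{name}" {{']
    ids = {}
    for neuron_id in sorted(config.neurons):
        neuron = config.neurons[neuron_id]
        node = f"{neuron.label}@{neuron.id}"
        ids[neuron_id] = node
        lines.append(f'  "{node}" [label="{neuron.label} : {neuron.spikes}"];')
    for src, dst in config.synapse_pairs():
        lines.append(f'  "{ids[src]}" -> "{ids[dst]}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
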