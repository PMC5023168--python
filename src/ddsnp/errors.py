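"""Exception hierarchy for the ddsnp simulator."""


class DDSNPError(Exception):
    """Base class for all ddsnp errors."""


class SpecError(DDSNPError):
    """A system specification, rule, or guard violates its invariants."""


class AmbiguityError(DDSNPError):
    """Two or more rules are applicable in one neuron under strict mode.

    Raised only in strict mode; it signals that a system claimed to be
    deterministic is not, at the offending neuron and step.
    """

    def __init__(self, step: int, neuron_id: int, label: str, spikes: int, rules):
        self.step = step
        self.neuron_id = neuron_id
        self.label = label
        self.spikes = spikes
        self.rules = list(rules)
        super().__init__(
            f"step {step}: neuron {label}@{neuron_id} with {spikes} spikes has "
            f"{len(self.rules)} applicable rules: {self.rules}"
        )


class MaxStepsExceeded(DDSNPError):
    """The computation did not halt within the allowed number of steps."""


class ComplementaryLiteralError(SpecError):
    """A clause contains both a variable and its negation.

    The unary spike encoding assigns one spike count per variable per
    clause and cannot represent a clause holding both x_j and its
    negation, so such clauses are rejected rather than simplified.
    """


class ParseError(DDSNPError):
    """A DIMACS or JSON artifact is malformed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CountMismatchError(ParseError):
    """DIMACS header counts disagree with the parsed clauses/variables."""
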