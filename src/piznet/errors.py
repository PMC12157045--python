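"""Error taxonomy shared by every pipeline stage.

The CLI maps these onto exit codes: format errors -> 2, impossible
evidence -> 3, invalid configuration/arguments -> 4.
"""


class PiznetError(Exception):
    """Base class for all piznet errors."""


class InvalidArgumentError(PiznetError, ValueError):
    """An argument violates an operation's precondition."""


class KeyNotFoundError(PiznetError, KeyError):
    """A gene, sample or variable name is unknown to the container."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep messages readable
        return Exception.__str__(self)


class FormatError(PiznetError):
    """An input file could not be parsed or fails validation."""


class DegenerateInputError(PiznetError):
    """The input is structurally valid but the operation is undefined on it
    (e.g. no gene with strictly positive counts in every sample)."""


class ImpossibleEvidenceError(PiznetError):
    """Evidence with probability zero under the model was clamped."""
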