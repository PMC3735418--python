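"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors exit 2, format errors 3,
consistency/degenerate-input errors 4.
"""


class SeqEvolveError(Exception):
    """Base class for all package errors."""


class FormatError(SeqEvolveError):
    """Input text does not conform to the expected file format."""


class AmbiguityError(FormatError):
    """Input admits more than one interpretation (e.g. multiple chains)."""


class DegenerateInputError(SeqEvolveError):
    """Input is syntactically valid but too small/degenerate to process."""


class ConsistencyError(SeqEvolveError):
    """Two inputs that must agree (lengths, labels) do not."""


class DerivationError(SeqEvolveError):
    """A statistical table cannot be derived from the given reference set."""


class CalibrationError(SeqEvolveError):
    """Normalizer or weight calibration failed (degenerate term)."""
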