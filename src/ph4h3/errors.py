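"""Exception hierarchy shared across the pipeline.

Errors are grouped so the command-line layer can map them to exit codes:
``ValidationError`` -> 2, ``InputIOError`` -> 3, non-convergence -> 4 under
``--strict``.
"""


class Ph4h3Error(Exception):
    """Base class for all package errors."""


class InputError(Ph4h3Error, ValueError):
    """Malformed or out-of-contract input to an operation."""


class ValidationError(Ph4h3Error):
    """A biological consistency check failed."""


class InputIOError(Ph4h3Error, OSError):
    """A required file is missing or unreadable."""


class ParseError(InputError):
    """A text format could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# --- locus_extract ---------------------------------------------------------

class HomologNotFoundError(ValidationError):
    """No proteome entry scored above the homology threshold for a query."""


class HomologAmbiguityError(ValidationError):
    """More than one gene exceeded the homology threshold and no tie-break
    was authorised."""


class DifferentContigError(ValidationError):
    """Candidate gene pair sits on different contigs."""


class OrientationError(ValidationError):
    """Candidate gene pair is not divergently oriented."""


class InterveningGeneError(ValidationError):
    """A third gene is annotated inside the candidate intergenic gap."""


class DegenerateLocusError(ValidationError):
    """The intergenic gap is empty (overlapping or abutting start codons)."""


# --- model fitting ---------------------------------------------------------

class DegenerateModelError(InputError):
    """An alignment yielded no match columns, so no profile can be built."""


class ConvergenceWarning(UserWarning):
    """Iterative refinement hit the iteration cap before the consensus
    stabilised."""
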