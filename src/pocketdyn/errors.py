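"""Exception hierarchy shared across the package.

Errors are grouped so the CLI can map them onto exit codes:
configuration problems, unreadable/inconsistent inputs, and
failures inside an analysis stage.
"""


class PocketdynError(Exception):
    """Base class for all package errors."""


class ConfigError(PocketdynError):
    """Invalid parameter or configuration value."""


class InputError(PocketdynError):
    """Input files missing, unreadable, or inconsistent."""


class AnalysisError(PocketdynError):
    """An analysis stage failed on otherwise valid inputs."""


class PDBParseError(InputError):
    """A PDB record could not be parsed; carries the line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class RosterError(InputError):
    """Models of a multi-model file (or frames of an ensemble) disagree in
    atom count or ordering."""


class EmptyStructureError(InputError):
    """A frame contains no atoms after filtering."""


class UnderdeterminedFitError(AnalysisError):
    """A superposition fit selection resolved to fewer than three atoms."""


class EmptyGridError(AnalysisError):
    """No lattice node falls inside the inclusion region."""


class UndefinedCorrelationError(AnalysisError):
    """Pearson correlation requested for a zero-variance input."""


class GeneratorError(PocketdynError):
    """A synthetic-data generator could not satisfy its own invariants."""
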