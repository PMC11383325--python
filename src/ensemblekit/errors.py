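"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`EnsembleKitError`
so callers can catch toolkit failures without masking programming errors.
"""


class EnsembleKitError(Exception):
    """Base class for all ensemblekit contract violations."""


class ParseError(EnsembleKitError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyInputError(EnsembleKitError):
    """A file or selection yielded zero atoms / zero frames."""


class FrameMismatchError(EnsembleKitError):
    """A trajectory frame disagrees with the expected atom count."""

    def __init__(self, frame_index: int, expected: int, found: int):
        super().__init__(
            f"frame {frame_index}: expected {expected} atoms, found {found}"
        )
        self.frame_index = frame_index


class SelectionError(EnsembleKitError):
    """An atom selection is empty or invalid for the given structure."""


class UnknownDomainError(EnsembleKitError):
    """A domain name is absent from the domain map."""


class DomainOverlapError(EnsembleKitError):
    """Two residue intervals in a domain map overlap."""


class DomainBoundsError(EnsembleKitError):
    """A domain interval lies outside the structure's residue span."""


class FitDegenerateError(EnsembleKitError):
    """Superposition target has < 3 atoms or (near-)collinear geometry."""


class InsufficientFramesError(EnsembleKitError):
    """An ensemble statistic needs more frames than the trajectory has."""


class MissingHydrogensError(EnsembleKitError):
    """H-bond detection requires explicit hydrogens bonded to donors."""


class UndefinedCorrelationError(EnsembleKitError):
    """A residue with zero self-variance makes its correlation undefined."""


class UnknownElementError(EnsembleKitError):
    """No van der Waals radius is bundled for an atom's element."""


class ComparisonIncompatibleError(EnsembleKitError):
    """Two ensembles cannot be compared (different residues or settings)."""
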