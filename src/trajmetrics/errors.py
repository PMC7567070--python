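"""Exception hierarchy shared across the package."""


class TrajmetricsError(Exception):
    """Base class for all package errors."""


class PDBParseError(TrajmetricsError):
    """File could not be interpreted as a PDB entry (e.g. no ATOM records)."""


class StructureError(TrajmetricsError):
    """Inconsistent structural data (ragged frames, model atom-count mismatch)."""


class FormatError(TrajmetricsError):
    """Output cannot be represented in the requested fixed-width format."""


class SelectionError(TrajmetricsError):
    """Selection expression is malformed or resolves to zero atoms."""


class DegenerateGeometryError(TrajmetricsError):
    """Point set too degenerate (collinear/coincident) for a rigid-body fit."""


class UndefinedAngleError(TrajmetricsError):
    """Torsion undefined because three consecutive points are collinear."""


class WindowError(TrajmetricsError):
    """Requested time window lies outside the trajectory or holds no frames."""


class WorkFileError(TrajmetricsError):
    """Work file malformed: unlabeled rows, missing direction, bad units."""


class ConvergenceError(TrajmetricsError):
    """Iterative estimator failed to converge within its iteration budget."""
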