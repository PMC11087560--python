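"""Exception hierarchy for the auricle measurement pipeline.

Every stage raises a subclass of :class:`AuriclometryError` so callers can
distinguish pipeline failures from programming errors; argument validation
uses plain :class:`ValueError` via :class:`ArgumentError`.
"""

from __future__ import annotations


class AuriclometryError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(AuriclometryError, ValueError):
    """Invalid argument (empty point set, bad bounds, missing reference)."""


class DegenerateGeometryError(AuriclometryError):
    """Input geometry is degenerate (collinear points, isotropic axes, ...)."""


class ConvergenceError(AuriclometryError):
    """An iterative optimizer failed to converge.

    Carries the best parameters and cost found so far in :attr:`best`.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class DegenerateFrameError(AuriclometryError):
    """Anatomical frame axes are (near-)parallel and no frame can be built."""


class InsufficientSurfaceError(AuriclometryError):
    """Too few qualifying grid lines to define an auricle surface."""


class MastoidProjectionError(AuriclometryError):
    """Too many mastoid projection rays failed to find a qualifying hit."""


class DegenerateInclinationError(AuriclometryError):
    """Length axis has no projection into the sagittal plane."""


class ConstructionError(AuriclometryError):
    """A synthetic phantom cannot be built from the requested parameters."""
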