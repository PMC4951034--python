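"""Exception and warning types used across the package."""


class GlenokinError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(GlenokinError, ValueError):
    """Input geometry does not determine the requested fit (too few points,
    collinear or coplanar configurations)."""


class FitFailureError(GlenokinError, RuntimeError):
    """A least-squares fit converged to a non-admissible solution
    (e.g. the conic fitted to a contour is not an ellipse)."""


class AmbiguousAxisError(GlenokinError, ValueError):
    """Point cloud has no dominant elongation direction, so a longitudinal
    axis cannot be defined."""


class RegistrationError(GlenokinError, RuntimeError):
    """Rigid registration failed (degenerate correspondence geometry)."""


class MissingRegionError(GlenokinError, KeyError):
    """A labelled frame lacks a region required by the requested operation."""


class MeshIOError(GlenokinError, IOError):
    """A surface file could not be read or failed validation."""


class NearCircularWarning(UserWarning):
    """Glenoid contour is nearly circular: the major/minor axis labelling is
    numerically fragile (kept deterministic via eigenvalue ordering)."""
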