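"""Least-squares geometric primitives for labelled shoulder anatomy.

All operations work on point sets in millimetres, in the world frame of the
reference scan.  The module provides

* total-least-squares plane fits (:func:`fit_plane`),
* the ellipse-derived glenoid coordinate system (:func:`fit_glenoid_cs`),
* algebraic + refined sphere fits for the humeral head (:func:`fit_sphere`),
* the principal-direction humeral shaft axis (:func:`fit_shaft_axis`).

The glenoid coordinate system follows the anatomical convention: the fitted
ellipse's minor axis is the anterior-posterior X axis, the major axis the
superior-inferior Y axis, and Z = X x Y.  The ellipse centre is the origin and
the X/Y axes span the glenoid plane.  Axis signs are fixed by explicit
superior and anterior hint points so that left and right shoulders are handled
uniformly without mirroring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    AmbiguousAxisError,
    DegenerateInputError,
    FitFailureError,
    NearCircularWarning,
)

__all__ = [
    "PlaneFit",
    "GlenoidCS",
    "SphereFit",
    "AxisFit",
    "fit_plane",
    "fit_glenoid_cs",
    "fit_sphere",
    "fit_shaft_axis",
]

#: ratio semi_major/semi_minor below which the contour counts as near-circular
NEAR_CIRCULAR_RATIO = 1.02

#: largest/second eigenvalue ratio below which a shaft cloud is "isotropic"
MIN_ELONGATION_RATIO = 4.0


def as_points(points, min_points: int = 1, name: str = "points") -> np.ndarray:
    """Validate and convert input to an (n, 3) float array of finite coords."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateInputError(f"{name} must be an (n, 3) array, got shape {pts.shape}")
    if pts.shape[0] < min_points:
        raise DegenerateInputError(
            f"{name} needs at least {min_points} points, got {pts.shape[0]}"
        )
    if not np.all(np.isfinite(pts)):
        raise DegenerateInputError(f"{name} contains non-finite coordinates")
    return pts


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise DegenerateInputError("zero-length direction vector")
    return v / n


def _deterministic_sign(v: np.ndarray) -> np.ndarray:
    """Flip ``v`` so its largest-magnitude component is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


@dataclass(frozen=True)
class PlaneFit:
    """Total-least-squares plane: point cloud centroid, unit normal and the
    RMS of signed point-to-plane distances (mm)."""

    centroid: np.ndarray
    normal: np.ndarray
    rms_residual: float


@dataclass(frozen=True)
class GlenoidCS:
    """Glenoid joint coordinate system derived from the rim ellipse.

    Attributes
    ----------
    center : (3,) ndarray
        Ellipse centre, origin of the coordinate system (mm).
    axis_x, axis_y, axis_z : (3,) ndarray
        Unit axes: X anterior-posterior (ellipse minor axis), Y
        superior-inferior (major axis), Z = X x Y.  X and Y span the glenoid
        plane.
    semi_minor, semi_major : float
        Ellipse semi-axis lengths (mm), ``semi_major >= semi_minor``.
    side : str
        ``"left"`` or ``"right"``.
    rms_residual : float
        In-plane RMS distance of the contour points from the fitted ellipse
        boundary (mm), a segmentation-quality indicator.
    """

    center: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray
    semi_minor: float
    semi_major: float
    side: str = "right"
    rms_residual: float = 0.0


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere: centre (mm), radius (mm) and RMS of
    ``| |p - c| - r |`` residuals."""

    center: np.ndarray
    radius: float
    rms_residual: float


@dataclass(frozen=True)
class AxisFit:
    """A 3D line: point on the line and unit direction."""

    point: np.ndarray
    direction: np.ndarray


def fit_plane(points, toward=None) -> PlaneFit:
    """Fit a total-least-squares plane to a 3D point set.

    The normal is the direction of least variance of the centred points
    (smallest right singular vector).  If ``toward`` is given, the normal is
    oriented so it points from the centroid toward that hint point; otherwise
    the sign is arbitrary but deterministic.

    Raises
    ------
    DegenerateInputError
        Fewer than 3 points, or all points collinear.
    """
    pts = as_points(points, min_points=3, name="plane points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] == 0 or s[1] / s[0] < 1e-12:
        raise DegenerateInputError("points are collinear; plane is undetermined")
    normal = vt[2]
    if toward is not None:
        hint = np.asarray(toward, dtype=float)
        if normal @ (hint - centroid) < 0:
            normal = -normal
    else:
        normal = _deterministic_sign(normal)
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return PlaneFit(centroid=centroid, normal=normal, rms_residual=rms)


def _fit_ellipse_conic(xy: np.ndarray) -> np.ndarray:
    """Direct ellipse-specific least squares (Halir & Flusser's numerically
    stable variant of Fitzgibbon's method).

    Returns conic coefficients ``(a, b, c, d, e, f)`` of
    ``a x^2 + b x y + c y^2 + d x + e y + f = 0`` with the ellipse constraint
    ``4ac - b^2 > 0`` enforced by construction.
    """
    x = xy[:, 0]
    y = xy[:, 1]
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise FitFailureError("ellipse fit: singular scatter matrix") from exc
    m = s1 + s2 @ t
    # premultiply by inv(C1) for constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    good = np.where((cond > 0) & np.isfinite(eigval))[0]
    if good.size == 0:
        raise FitFailureError("fitted conic is not an ellipse")
    a1 = np.real(eigvec[:, good[0]])
    return np.concatenate([a1, t @ a1])


def _conic_to_ellipse(coef: np.ndarray):
    """Convert conic coefficients to (center2d, semi_major, semi_minor,
    major_dir2d, minor_dir2d)."""
    a, b, c, d, e, f = coef
    m22 = np.array([[a, b / 2.0], [b / 2.0, c]])
    try:
        center = np.linalg.solve(2.0 * m22, -np.array([d, e]))
    except np.linalg.LinAlgError as exc:
        raise FitFailureError("degenerate conic (no finite centre)") from exc
    f0 = (
        a * center[0] ** 2
        + b * center[0] * center[1]
        + c * center[1] ** 2
        + d * center[0]
        + e * center[1]
        + f
    )
    lam, vec = np.linalg.eigh(m22)
    with np.errstate(divide="ignore", invalid="ignore"):
        axes_sq = -f0 / lam
    if not np.all(np.isfinite(axes_sq)) or np.any(axes_sq <= 0):
        raise FitFailureError("fitted conic is not a real ellipse")
    semi = np.sqrt(axes_sq)
    # smaller eigenvalue -> larger semi-axis (major)
    order = np.argsort(semi)[::-1]
    semi_major, semi_minor = semi[order]
    major_dir = vec[:, order[0]]
    minor_dir = vec[:, order[1]]
    return center, float(semi_major), float(semi_minor), major_dir, minor_dir


def _ellipse_inplane_rms(uv, center, semi_major, semi_minor, major_dir, minor_dir):
    """Approximate RMS distance of 2D points from the ellipse boundary."""
    rel = uv - center
    u = rel @ major_dir
    v = rel @ minor_dir
    # radial approximation: distance along the ray from the centre
    theta = np.arctan2(v / semi_minor, u / semi_major)
    bx = semi_major * np.cos(theta)
    by = semi_minor * np.sin(theta)
    return float(np.sqrt(np.mean((u - bx) ** 2 + (v - by) ** 2)))


def fit_glenoid_cs(contour, superior_hint, anterior_hint, side: str = "right") -> GlenoidCS:
    """Build the glenoid coordinate system from the rim contour.

    The contour is projected onto its total-least-squares plane, an
    ellipse-constrained algebraic least-squares fit is performed in-plane, and
    the in-plane axes are lifted back to 3D.  The major axis becomes the
    superior-inferior Y axis, the minor axis the anterior-posterior X axis and
    Z = X x Y.

    Parameters
    ----------
    contour : array-like (n, 3)
        Glenoid rim contour points (mm); at least 6 non-collinear points.
    superior_hint : array-like (3,)
        Any point on the superior side (e.g. acromion centroid); fixes the
        sign of Y via ``Y . (superior_hint - center) > 0``.
    anterior_hint : array-like (3,)
        Any point on the anterior side; fixes the sign of X likewise.
    side : str
        ``"left"`` or ``"right"`` (metadata; signs come from the hints).

    Warns
    -----
    NearCircularWarning
        If ``semi_major/semi_minor < 1.02`` the axis labelling is kept
        (eigenvalue ordering) but flagged: glenoids are normally elongated.
    """
    pts = as_points(contour, min_points=6, name="glenoid contour")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    plane = fit_plane(pts)
    # in-plane orthonormal basis from the plane's SVD frame
    _, _, vt = np.linalg.svd(pts - plane.centroid, full_matrices=False)
    e1, e2 = vt[0], vt[1]
    uv = (pts - plane.centroid) @ np.column_stack([e1, e2])
    coef = _fit_ellipse_conic(uv)
    c2d, semi_major, semi_minor, major2d, minor2d = _conic_to_ellipse(coef)
    rms = _ellipse_inplane_rms(uv, c2d, semi_major, semi_minor, major2d, minor2d)

    center = plane.centroid + c2d[0] * e1 + c2d[1] * e2
    axis_y = _unit(major2d[0] * e1 + major2d[1] * e2)
    axis_x = _unit(minor2d[0] * e1 + minor2d[1] * e2)

    sup = np.asarray(superior_hint, dtype=float)
    ant = np.asarray(anterior_hint, dtype=float)
    if axis_y @ (sup - center) < 0:
        axis_y = -axis_y
    if axis_x @ (ant - center) < 0:
        axis_x = -axis_x
    axis_z = np.cross(axis_x, axis_y)
    axis_z = _unit(axis_z)

    if semi_major / semi_minor < NEAR_CIRCULAR_RATIO:
        warnings.warn(
            "glenoid contour is nearly circular "
            f"(axis ratio {semi_major / semi_minor:.4f}); "
            "major/minor labelling kept from eigenvalue order",
            NearCircularWarning,
            stacklevel=2,
        )
    return GlenoidCS(
        center=center,
        axis_x=axis_x,
        axis_y=axis_y,
        axis_z=axis_z,
        semi_minor=semi_minor,
        semi_major=semi_major,
        side=side,
        rms_residual=rms,
    )


def fit_sphere(points, refine: bool = True, max_refine_iter: int = 10) -> SphereFit:
    """Least-squares sphere fit for the humeral head surface.

    Solves the linear algebraic system in centre and radius
    (``2 c . p + (r^2 - |c|^2) = |p|^2``), then optionally runs a few
    Gauss-Newton passes on the geometric residual ``|p - c| - r``.

    Raises
    ------
    DegenerateInputError
        Fewer than 4 points, or (near-)coplanar points.
    """
    pts = as_points(points, min_points=4, name="sphere points")
    centred = pts - pts.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[0] == 0 or s[2] / s[0] < 1e-9:
        raise DegenerateInputError("points are coplanar; sphere is undetermined")

    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts * pts, axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise FitFailureError("algebraic sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))

    if refine:
        for _ in range(max_refine_iter):
            diff = pts - center
            dist = np.linalg.norm(diff, axis=1)
            if np.any(dist == 0):
                break
            res = dist - radius
            jac = np.column_stack([-diff / dist[:, None], -np.ones(len(pts))])
            try:
                step, *_ = np.linalg.lstsq(jac, -res, rcond=None)
            except np.linalg.LinAlgError:
                break
            center = center + step[:3]
            radius = float(radius + step[3])
            if np.linalg.norm(step) < 1e-12:
                break

    dist = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return SphereFit(center=center, radius=radius, rms_residual=rms)


def fit_shaft_axis(shaft_points, toward=None) -> AxisFit:
    """Longitudinal axis of the humeral shaft as the first principal
    direction of the point cloud.

    Parameters
    ----------
    shaft_points : array-like (n, 3)
        At least 10 points with a dominant elongation direction.
    toward : array-like (3,), optional
        If given (typically the humeral head centre), the direction is
        oriented from the shaft centroid toward this point; otherwise the
        sign is deterministic (largest component positive).

    Raises
    ------
    AmbiguousAxisError
        If the largest/second eigenvalue ratio of the covariance is below
        ``MIN_ELONGATION_RATIO`` (nearly isotropic cloud).
    """
    pts = as_points(shaft_points, min_points=10, name="shaft points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    lam = s**2
    if lam[1] == 0:
        ratio = np.inf
    else:
        ratio = lam[0] / lam[1]
    if ratio < MIN_ELONGATION_RATIO:
        raise AmbiguousAxisError(
            f"no dominant elongation (eigenvalue ratio {ratio:.2f} < "
            f"{MIN_ELONGATION_RATIO})"
        )
    direction = vt[0]
    if toward is not None:
        hint = np.asarray(toward, dtype=float)
        if direction @ (hint - centroid) < 0:
            direction = -direction
    else:
        direction = _deterministic_sign(direction)
    return AxisFit(point=centroid, direction=direction)
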