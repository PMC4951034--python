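"""Rigid surface registration (iterative closest point).

Every motion frame is aligned to the 0-degree reference frame by registering
its scapula point cloud to the reference scapula; the recovered rigid
transform is then applied to that frame's humeral regions.  Registering on
the scapula (rather than the whole reconstruction) fixes the glenoid frame
across the abduction cycle, so humeral motion is expressed relative to the
glenoid, which is what glenohumeral kinematics requires.

ICP here is the classic point-to-point variant: nearest-neighbour
correspondences (scipy KD-tree) with a closed-form SVD (Kabsch) rigid update
per iteration.  Initialisation is deterministic: centroid alignment plus
principal-axes alignment, choosing among the four proper-rotation sign
combinations (and the identity) the one with the lowest starting RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import RegistrationError
from .geometry import as_points

__all__ = ["RigidTransform", "RegistrationReport", "kabsch", "register_rigid"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation matrix + mm translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-6):
            raise ValueError("rotation matrix determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)):
        """Rotation of ``angle_deg`` about ``axis`` (through the origin) plus
        a translation."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        th = np.deg2rad(angle_deg)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        r = np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)
        return cls(r, np.asarray(translation, dtype=float))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


@dataclass
class RegistrationReport:
    """Outcome of :func:`register_rigid`.

    ``rms_history`` holds the nearest-neighbour RMS after each accepted
    update and is non-increasing by construction.
    """

    transform: RigidTransform
    rms_before: float
    rms_after: float
    iterations: int
    converged: bool
    rms_history: list = field(default_factory=list)


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping ``moving`` onto
    ``fixed`` for known one-to-one correspondences (SVD / Kabsch).

    Raises
    ------
    RegistrationError
        If the correspondence cross-covariance is rank deficient (e.g. all
        points collinear), which leaves the rotation undetermined.
    """
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, s, vt = np.linalg.svd(h)
    if s[0] == 0 or s[1] / s[0] < 1e-12:
        raise RegistrationError("degenerate correspondence geometry (rank < 2)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cf - r @ cm
    return RigidTransform(r, t)


def _nn_rms(tree: cKDTree, points: np.ndarray) -> float:
    d, _ = tree.query(points)
    return float(np.sqrt(np.mean(d**2)))


def _principal_axes_candidates(moving: np.ndarray, fixed: np.ndarray):
    """Deterministic initial guesses: identity, centroid shift and the four
    proper principal-axes alignments."""
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    um = np.linalg.svd(moving - cm, full_matrices=False)[2].T
    uf = np.linalg.svd(fixed - cf, full_matrices=False)[2].T
    if np.linalg.det(um) < 0:
        um[:, 2] = -um[:, 2]
    if np.linalg.det(uf) < 0:
        uf[:, 2] = -uf[:, 2]
    cands = [RigidTransform.identity(), RigidTransform(np.eye(3), cf - cm)]
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        r = uf @ np.diag(signs) @ um.T
        cands.append(RigidTransform(r, cf - r @ cm))
    return cands


def register_rigid(
    moving,
    fixed,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    trim_fraction: float = 0.0,
) -> RegistrationReport:
    """Point-to-point ICP aligning ``moving`` onto ``fixed``.

    Parameters
    ----------
    moving, fixed : array-like (n, 3)
        Point clouds (>= 3 points each) with substantial overlap.
    init : RigidTransform, optional
        Starting transform.  If omitted, the best of a deterministic
        candidate set (identity, centroid shift, principal-axes alignments)
        is used.
    max_iter : int
        Iteration cap.
    tol : float
        Stop when the RMS improvement falls below this value (mm).
    trim_fraction : float
        Fraction of the worst correspondences discarded each iteration
        (0 = none; useful for partially overlapping noisy surfaces).

    Returns
    -------
    RegistrationReport
        With ``rms_after <= rms_before`` and a non-increasing
        ``rms_history``.
    """
    mov = as_points(moving, min_points=3, name="moving points")
    fix = as_points(fixed, min_points=3, name="fixed points")
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must be in [0, 1)")
    tree = cKDTree(fix)

    if init is None:
        cands = _principal_axes_candidates(mov, fix)
        scores = [_nn_rms(tree, c.apply(mov)) for c in cands]
        transform = cands[int(np.argmin(scores))]
    else:
        transform = init

    rms_before = _nn_rms(tree, transform.apply(mov))
    prev_rms = rms_before
    history: list[float] = []
    converged = False
    n_keep = max(3, int(round(len(mov) * (1.0 - trim_fraction))))

    iterations = 0
    for iterations in range(1, max_iter + 1):
        moved = transform.apply(mov)
        d, idx = tree.query(moved)
        if trim_fraction > 0.0:
            keep = np.argsort(d)[:n_keep]
        else:
            keep = slice(None)
        candidate = kabsch(mov[keep], fix[idx][keep])
        rms = _nn_rms(tree, candidate.apply(mov))
        if rms > prev_rms + 1e-12:
            # numerical stall; keep the previous (better) transform
            converged = True
            break
        transform = candidate
        history.append(rms)
        if prev_rms - rms < tol:
            converged = True
            prev_rms = rms
            break
        prev_rms = rms

    return RegistrationReport(
        transform=transform,
        rms_before=rms_before,
        rms_after=prev_rms,
        iterations=iterations,
        converged=converged,
        rms_history=history,
    )
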