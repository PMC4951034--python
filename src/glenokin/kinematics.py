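"""Per-frame glenohumeral kinematics and per-sequence "looseness" metrics.

Given labelled frames that have been rigidly aligned to the 0-degree
reference via the scapula, this module computes, for each motion frame:

* the humeral-head centre projected perpendicularly onto the glenoid plane,
  expressed in the glenoid coordinate system as ``(x, y)`` in mm
  (anterior-posterior / superior-inferior);
* the subacromial space width (WSS): the shortest distance between the
  superior proximal-humerus surface and the inferior acromion surface;
* the glenohumeral abduction angle: the angle between the humeral shaft
  axis and the glenoid plane.

Sequence-level looseness metrics are the mean and max-min range of each
quantity over the measured frames (for an 8-frame abduction cycle, the seven
non-reference frames).  A WSS range above 4 mm flags a torn cuff
(:func:`classify_tear`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import trimesh

from .exceptions import DegenerateInputError, MissingRegionError
from .geometry import (
    AxisFit,
    GlenoidCS,
    SphereFit,
    fit_glenoid_cs,
    fit_shaft_axis,
    fit_sphere,
)
from .registration import RegistrationReport, RigidTransform, register_rigid

__all__ = [
    "REGIONS",
    "LabelledFrame",
    "KinematicSample",
    "SequenceMetrics",
    "SequenceAnalysis",
    "project_head_center",
    "subacromial_width",
    "abduction_angle",
    "analyze_sequence",
    "apply_transform",
    "normalize_to_glenoid_percent",
    "classify_tear",
    "min_point_triangle_distance",
]

#: canonical region labels
REGIONS = (
    "glenoid_contour",
    "humeral_head",
    "humeral_shaft",
    "proximal_humerus_superior",
    "acromion_inferior",
    "scapula",
)

METRIC_NAMES = ("wss_avg", "wss_range", "y_avg", "y_range", "x_avg", "x_range")


def region_points(obj) -> np.ndarray:
    """Vertex array of a region, whether stored as mesh or point set."""
    if isinstance(obj, trimesh.Trimesh):
        return np.asarray(obj.vertices, dtype=float)
    if isinstance(obj, trimesh.PointCloud):
        return np.asarray(obj.vertices, dtype=float)
    return np.asarray(obj, dtype=float)


def _region_faces(obj):
    if isinstance(obj, trimesh.Trimesh) and len(obj.faces):
        return np.asarray(obj.faces)
    return None


@dataclass
class LabelledFrame:
    """One time point of a dynamic acquisition.

    ``regions`` maps region names (see :data:`REGIONS`) to either an (n, 3)
    point array or a :class:`trimesh.Trimesh`.  Coordinates are mm in the
    world frame of the scan.
    """

    frame_index: int
    time_s: float
    regions: Mapping[str, object]
    side: str = "right"

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.regions]
        if missing:
            raise MissingRegionError(
                f"frame {self.frame_index} lacks region(s): {', '.join(missing)}"
            )

    def points(self, name: str) -> np.ndarray:
        self.require(name)
        return region_points(self.regions[name])


@dataclass(frozen=True)
class KinematicSample:
    """Kinematic measurements of a single motion frame."""

    frame_index: int
    time_s: float
    x_mm: float
    y_mm: float
    wss_mm: float
    abduction_deg: float


@dataclass(frozen=True)
class SequenceMetrics:
    """Per-shoulder looseness summary over the measured frames.

    Averages are arithmetic means; ranges are max - min.
    """

    wss_avg: float
    wss_range: float
    y_avg: float
    y_range: float
    x_avg: float
    x_range: float
    n_samples: int

    @classmethod
    def from_samples(cls, samples: list[KinematicSample]) -> "SequenceMetrics":
        if not samples:
            raise ValueError("no samples to aggregate")
        x = np.array([s.x_mm for s in samples])
        y = np.array([s.y_mm for s in samples])
        w = np.array([s.wss_mm for s in samples])
        return cls(
            wss_avg=float(w.mean()),
            wss_range=float(w.max() - w.min()),
            y_avg=float(y.mean()),
            y_range=float(y.max() - y.min()),
            x_avg=float(x.mean()),
            x_range=float(x.max() - x.min()),
            n_samples=len(samples),
        )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES} | {
            "n_samples": self.n_samples
        }


@dataclass
class SequenceAnalysis:
    """Result bundle of :func:`analyze_sequence`; iterable as
    ``(samples, metrics, glenoid_cs)``."""

    samples: list[KinematicSample]
    metrics: SequenceMetrics
    glenoid_cs: GlenoidCS
    registrations: dict[int, RegistrationReport] = field(default_factory=dict)

    def __iter__(self) -> Iterator:
        return iter((self.samples, self.metrics, self.glenoid_cs))


def project_head_center(head: SphereFit, cs: GlenoidCS) -> tuple[float, float]:
    """Perpendicular projection of the humeral-head centre onto the glenoid
    plane, in glenoid coordinates (mm): ``x = d . X``, ``y = d . Y`` with
    ``d = head_centre - glenoid_centre``."""
    d = np.asarray(head.center, dtype=float) - cs.center
    return float(d @ cs.axis_x), float(d @ cs.axis_y)


def _closest_point_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Minimum distance from each point to a set of triangles.

    Vectorised closest-point-on-triangle (barycentric region walk).
    ``points`` is (n, 3); ``tri`` is (m, 3, 3).  Returns (n,) distances.
    """
    a = tri[:, 0][None, :, :]
    b = tri[:, 1][None, :, :]
    c = tri[:, 2][None, :, :]
    p = points[:, None, :]

    def dot(u, v):
        return (u * v).sum(axis=-1)

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = dot(ab, ap)
    d2 = dot(ac, ap)
    bp = p - b
    d3 = dot(ab, bp)
    d4 = dot(ac, bp)
    cp = p - c
    d5 = dot(ab, cp)
    d6 = dot(ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    def safe_div(num, den):
        den = np.where(np.abs(den) < 1e-300, 1.0, den)
        return num / den

    # interior (default)
    denom = va + vb + vc
    v = safe_div(vb, denom)[..., None]
    w = safe_div(vc, denom)[..., None]
    q = a + ab * v + ac * w

    # edge BC
    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    w_bc = safe_div(d4 - d3, (d4 - d3) + (d5 - d6))[..., None]
    q = np.where(m_bc[..., None], b + (c - b) * w_bc, q)
    # edge AC
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w_ac = safe_div(d2, d2 - d6)[..., None]
    q = np.where(m_ac[..., None], a + ac * w_ac, q)
    # edge AB
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    w_ab = safe_div(d1, d1 - d3)[..., None]
    q = np.where(m_ab[..., None], a + ab * w_ab, q)
    # vertex regions
    q = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, q)
    q = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, q)
    q = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, q)

    return np.linalg.norm(p - q, axis=-1).min(axis=1)


def min_point_triangle_distance(points, triangles, chunk: int = 200) -> float:
    """Minimum distance from any of ``points`` to a triangle soup
    ``triangles`` of shape (m, 3, 3), chunked to bound memory."""
    pts = np.asarray(points, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    best = np.inf
    for i in range(0, len(pts), chunk):
        d = _closest_point_triangles(pts[i : i + chunk], tri)
        best = min(best, float(d.min()))
    return best


def subacromial_width(humeral_superior, acromion_inferior) -> float:
    """Shortest distance (mm) between the superior proximal-humerus surface
    and the inferior acromion surface.

    For mesh inputs the distance is the symmetrised vertex-to-triangle
    minimum (humeral vertices vs acromion triangles and vice versa), which
    avoids the upward bias of a pure vertex-to-vertex search.  If either
    input is a bare point set, the minimum pairwise point distance is used.
    """
    hp = region_points(humeral_superior)
    ap = region_points(acromion_inferior)
    if hp.size == 0 or ap.size == 0:
        raise DegenerateInputError("empty region passed to subacromial_width")
    hf = _region_faces(humeral_superior)
    af = _region_faces(acromion_inferior)
    if hf is not None and af is not None:
        d1 = min_point_triangle_distance(hp, ap[af])
        d2 = min_point_triangle_distance(ap, hp[hf])
        return min(d1, d2)
    # point-set fallback: min pairwise distance, chunked
    best = np.inf
    for i in range(0, len(hp), 500):
        diff = hp[i : i + 500, None, :] - ap[None, :, :]
        best = min(best, float(np.sqrt((diff**2).sum(-1)).min()))
    return best


def abduction_angle(shaft: AxisFit, cs: GlenoidCS) -> float:
    """Glenohumeral abduction: the angle in degrees between the humeral
    longitudinal axis and the glenoid plane, ``arcsin(|d . Z|)`` in
    [0, 90]."""
    s = float(np.abs(np.asarray(shaft.direction) @ cs.axis_z))
    return float(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0))))


def apply_transform(frame: LabelledFrame, t: RigidTransform) -> LabelledFrame:
    """Map every region of a frame through a rigid transform, preserving
    labels, meshes' connectivity, time stamp and side."""
    new_regions = {}
    for name, obj in frame.regions.items():
        faces = _region_faces(obj)
        pts = t.apply(region_points(obj))
        if faces is not None:
            new_regions[name] = trimesh.Trimesh(vertices=pts, faces=faces, process=False)
        else:
            new_regions[name] = pts
    return LabelledFrame(
        frame_index=frame.frame_index,
        time_s=frame.time_s,
        regions=new_regions,
        side=frame.side,
    )


def _measure_frame(frame: LabelledFrame, cs: GlenoidCS) -> KinematicSample:
    frame.require(
        "humeral_head", "humeral_shaft", "proximal_humerus_superior", "acromion_inferior"
    )
    head = fit_sphere(frame.points("humeral_head"))
    x, y = project_head_center(head, cs)
    wss = subacromial_width(
        frame.regions["proximal_humerus_superior"], frame.regions["acromion_inferior"]
    )
    shaft = fit_shaft_axis(frame.points("humeral_shaft"), toward=head.center)
    abd = abduction_angle(shaft, cs)
    return KinematicSample(
        frame_index=frame.frame_index,
        time_s=frame.time_s,
        x_mm=x,
        y_mm=y,
        wss_mm=wss,
        abduction_deg=abd,
    )


def analyze_sequence(
    frames: list[LabelledFrame],
    reference_index: int = 0,
    superior_hint=None,
    anterior_hint=None,
    icp_max_iter: int = 100,
    icp_tol: float = 1e-4,
    trim_fraction: float = 0.0,
) -> SequenceAnalysis:
    """Run the whole kinematic analysis on one shoulder sequence.

    The glenoid coordinate system is built once from the reference frame's
    rim contour.  Each non-reference frame's scapula is ICP-registered to the
    reference scapula; the recovered transform is applied to the whole frame
    and the kinematic sample is measured in the fixed glenoid frame.  For an
    8-frame cycle this yields 7 samples (the reference is the registration
    target only).

    Parameters
    ----------
    frames : list of LabelledFrame
        At least two frames with strictly increasing time stamps.
    reference_index : int
        Which frame is the 0-degree reference.
    superior_hint, anterior_hint : array-like (3,), optional
        Sign hints for the glenoid axes, in reference-frame coordinates.
        The superior hint defaults to the reference acromion centroid; the
        anterior hint, if omitted, is derived from the superior direction,
        the glenoid normal oriented toward the humeral head, and the side
        flag (right: anterior = superior x lateral... computed as s x n;
        left: n x s).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    times = [f.time_s for f in frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("frame times must be strictly increasing")
    ref = frames[reference_index]
    ref.require("scapula", "glenoid_contour")

    contour = ref.points("glenoid_contour")
    if superior_hint is None:
        ref.require("acromion_inferior")
        superior_hint = ref.points("acromion_inferior").mean(axis=0)
    if anterior_hint is None:
        ref.require("humeral_head")
        head0 = fit_sphere(ref.points("humeral_head"))
        # lateral direction: glenoid normal pointing toward the humerus
        from .geometry import fit_plane

        plane = fit_plane(contour, toward=head0.center)
        s_dir = np.asarray(superior_hint, dtype=float) - plane.centroid
        s_dir = s_dir - (s_dir @ plane.normal) * plane.normal
        n = plane.normal
        ant = np.cross(s_dir, n) if ref.side == "right" else np.cross(n, s_dir)
        anterior_hint = plane.centroid + ant

    cs = fit_glenoid_cs(contour, superior_hint, anterior_hint, side=ref.side)

    ref_scapula = ref.points("scapula")
    samples: list[KinematicSample] = []
    reports: dict[int, RegistrationReport] = {}
    for i, frame in enumerate(frames):
        if i == reference_index:
            continue
        frame.require("scapula")
        report = register_rigid(
            frame.points("scapula"),
            ref_scapula,
            max_iter=icp_max_iter,
            tol=icp_tol,
            trim_fraction=trim_fraction,
        )
        reports[frame.frame_index] = report
        registered = apply_transform(frame, report.transform)
        samples.append(_measure_frame(registered, cs))

    metrics = SequenceMetrics.from_samples(samples)
    return SequenceAnalysis(
        samples=samples, metrics=metrics, glenoid_cs=cs, registrations=reports
    )


def normalize_to_glenoid_percent(x_mm: float, y_mm: float, cs: GlenoidCS):
    """Express a glenoid-plane position as a percentage of the rim ellipse,
    per axis, so that every glenoid rim maps onto the same circle spanning
    -100% to +100% in both directions."""
    return 100.0 * x_mm / cs.semi_minor, 100.0 * y_mm / cs.semi_major


def classify_tear(metrics: SequenceMetrics, threshold_mm: float = 4.0) -> str:
    """Tendon-tear flag from subacromial looseness: ``"tear"`` iff the WSS
    range strictly exceeds ``threshold_mm`` (default 4 mm), else
    ``"no_tear"``.  Shoulders with massive or full-thickness supraspinatus
    tears show WSS ranges above this threshold; normal and tendinopathy
    shoulders stay below it."""
    return "tear" if metrics.wss_range > threshold_mm else "no_tear"
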