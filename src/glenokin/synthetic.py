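"""Synthetic 8-frame shoulder abduction sequences with known ground truth.

The generator emulates the study conditions under which the kinematic
pipeline operates: per-frame labelled bone surfaces of a shoulder abducting
over a 28 s cycle, sampled once every 4 s (8 frames, frame 0 being the
0-degree reference), with group-specific humeral-head translation and
subacromial-space trajectories for four rotator cuff disease grades:

* ``N``   - normal,
* ``TA``  - tendinopathy without full-thickness tear,
* ``SST`` - isolated full-thickness supraspinatus tear,
* ``MCT`` - massive cuff tear (two or more tendons).

Anatomy is built from geometric primitives in a canonical glenoid frame
(X anterior, Y superior, Z lateral toward the humerus): the humeral head is
a 24 mm-radius sphere with a 12 mm-radius shaft cylinder, the glenoid rim an
ellipse with semi-axes 17.5 (superior-inferior) by 12.5 mm, the scapula an
asymmetric blade mesh rigidly attached to the glenoid, and the acromion a
plate above the head whose per-frame height realises the prescribed
subacromial width exactly (closed form: plate height minus head-top height).
Each non-reference frame is perturbed by a random whole-frame rigid motion
(so registration is exercised) and all vertices receive isotropic Gaussian
noise emulating segmentation error.

Head-centre and WSS trajectories are sinusoids affinely calibrated so that
the seven measured frames have exactly the prescribed mean and max-min
range: the group summary statistics of the emulated study are statistics of
those seven samples, so the calibration makes the generator's parameters
directly recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .kinematics import LabelledFrame, SequenceMetrics
from .registration import RigidTransform

__all__ = [
    "SyntheticProfile",
    "GroundTruth",
    "default_profiles",
    "generate_sequence",
    "simulate_cohort",
    "generate_cohort",
]

HEAD_RADIUS_MM = 24.0
GLENOID_SEMI_MAJOR_MM = 17.5
GLENOID_SEMI_MINOR_MM = 12.5
HEAD_STANDOFF_MM = 26.0  # head-centre height above the glenoid plane (+Z)
SHAFT_RADIUS_MM = 12.0
MIN_WSS_CLEARANCE_MM = 0.2

GROUPS = ("MCT", "SST", "TA", "N")

#: groups whose cuff has a full-thickness tendon tear
TEAR_GROUPS = frozenset({"MCT", "SST"})


@dataclass(frozen=True)
class SyntheticProfile:
    """Group-level trajectory parameters of a synthetic shoulder.

    ``*_mean``/``*_baseline`` and ``*_excursion`` are the per-sequence mean
    and max-min range (mm) that the seven measured frames realise exactly.
    """

    group: str
    wss_baseline_mm: float
    wss_excursion_mm: float
    y_mean_mm: float
    y_excursion_mm: float
    x_mean_mm: float
    x_excursion_mm: float
    abduction_max_deg: float
    n_frames: int = 8
    cycle_s: float = 28.0
    noise_sd_mm: float = 0.2
    seed: int = 0
    phase_rad: float = 0.0
    side: str = "right"

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("wss_excursion_mm", "y_excursion_mm", "x_excursion_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")

    def expected_metrics(self) -> SequenceMetrics:
        """The sequence metrics a noise-free measurement would recover."""
        return SequenceMetrics(
            wss_avg=self.wss_baseline_mm,
            wss_range=self.wss_excursion_mm,
            y_avg=self.y_mean_mm,
            y_range=self.y_excursion_mm,
            x_avg=self.x_mean_mm,
            x_range=self.x_excursion_mm,
            n_samples=self.n_frames - 1,
        )


def default_profiles() -> dict[str, SyntheticProfile]:
    """The four rotator-cuff disease group profiles.

    Trajectory parameters are the group means of the emulated study
    (subacromial width average/range, superior-inferior Y and
    anterior-posterior X translation average/range, all mm); peak abduction
    is the group-average maximal glenohumeral abduction in degrees.
    """
    rows = {
        # group: (wss_baseline, wss_exc, y_mean, y_exc, x_mean, x_exc, abd_max)
        "MCT": (4.3, 4.0, 3.8, 6.4, -0.8, 9.2, 38.0),
        "SST": (7.3, 5.3, 2.0, 5.0, 0.9, 9.3, 52.0),
        "TA": (10.4, 2.1, 0.3, 4.4, -1.6, 4.8, 49.0),
        "N": (7.7, 1.9, 1.0, 3.4, 1.1, 3.5, 43.0),
    }
    return {
        g: SyntheticProfile(
            group=g,
            wss_baseline_mm=v[0],
            wss_excursion_mm=v[1],
            y_mean_mm=v[2],
            y_excursion_mm=v[3],
            x_mean_mm=v[4],
            x_excursion_mm=v[5],
            abduction_max_deg=v[6],
        )
        for g, v in rows.items()
    }


@dataclass
class GroundTruth:
    """Analytic per-frame truth of a generated sequence (all frames,
    including the reference at index 0)."""

    times_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    wss_mm: np.ndarray
    abduction_deg: np.ndarray
    perturbations: list[RigidTransform]
    superior_hint: np.ndarray
    anterior_hint: np.ndarray
    side: str

    def metrics(self) -> SequenceMetrics:
        """Ground-truth looseness metrics over the measured frames 1..n-1."""
        x, y, w = self.x_mm[1:], self.y_mm[1:], self.wss_mm[1:]
        return SequenceMetrics(
            wss_avg=float(w.mean()),
            wss_range=float(w.max() - w.min()),
            y_avg=float(y.mean()),
            y_range=float(y.max() - y.min()),
            x_avg=float(x.mean()),
            x_range=float(x.max() - x.min()),
            n_samples=len(x),
        )


def _calibrated_path(mean, excursion, times, cycle_s, phase) -> np.ndarray:
    """Sinusoid sampled at ``times``, affinely adjusted so the measured
    frames (all but the first) have mean ``mean`` and range ``excursion``."""
    u = np.sin(2.0 * np.pi * np.asarray(times, dtype=float) / cycle_s + phase)
    meas = u[1:]
    span = meas.max() - meas.min()
    if excursion == 0 or span < 1e-12:
        return np.full(len(u), float(mean))
    return mean + (u - meas.mean()) * (excursion / span)


def _fibonacci_sphere_dirs(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _grid_faces(nu: int, nv: int) -> np.ndarray:
    """Triangulation of an nu x nv vertex grid (row-major)."""
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            b = a + 1
            c = a + nv
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return np.array(faces)


def _scapula_blade() -> trimesh.Trimesh:
    """Asymmetric blade mesh medial to the glenoid (fixed anatomy).

    The waviness terms break every mirror/rotation symmetry so ICP has a
    unique optimum.
    """
    u = np.linspace(0.0, 80.0, 17)
    v = np.linspace(-30.0, 50.0, 13)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (
        0.004 * uu**2
        - 0.003 * vv**2
        + 2.0 * np.sin(uu / 15.0)
        + 0.5 * np.cos(vv / 9.0)
        + 0.0008 * uu * vv
    )
    verts = np.column_stack([x.ravel(), vv.ravel(), -6.0 - uu.ravel()])
    return trimesh.Trimesh(vertices=verts, faces=_grid_faces(17, 13), process=False)


def _spherical_cap_mesh(center, radius, max_polar_deg=55.0, n_rings=5, n_seg=16):
    """Triangulated cap of a sphere around its +Y pole; the exact pole is a
    vertex, so the analytic sphere-plate gap is realised by the mesh."""
    center = np.asarray(center, dtype=float)
    verts = [center + radius * np.array([0.0, 1.0, 0.0])]
    for i in range(1, n_rings + 1):
        th = np.deg2rad(max_polar_deg * i / n_rings)
        for j in range(n_seg):
            ph = 2.0 * np.pi * j / n_seg
            d = np.array(
                [np.sin(th) * np.cos(ph), np.cos(th), np.sin(th) * np.sin(ph)]
            )
            verts.append(center + radius * d)
    faces = []
    for j in range(n_seg):
        faces.append([0, 1 + j, 1 + (j + 1) % n_seg])
    for i in range(n_rings - 1):
        base = 1 + i * n_seg
        nxt = base + n_seg
        for j in range(n_seg):
            j2 = (j + 1) % n_seg
            faces.append([base + j, nxt + j, nxt + j2])
            faces.append([base + j, nxt + j2, base + j2])
    return trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces), process=False)


def _acromion_plate(center_x, center_z, height_y, half=30.0, n=9) -> trimesh.Trimesh:
    g = np.linspace(-half, half, n)
    xx, zz = np.meshgrid(center_x + g, center_z + g, indexing="ij")
    verts = np.column_stack([xx.ravel(), np.full(xx.size, height_y), zz.ravel()])
    return trimesh.Trimesh(vertices=verts, faces=_grid_faces(n, n), process=False)


def _shaft_points(head_center, distal_dir, n_len=10, n_seg=16) -> np.ndarray:
    d = np.asarray(distal_dir, dtype=float)
    d = d / np.linalg.norm(d)
    e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 - (e1 @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    s = np.linspace(30.0, 150.0, n_len)
    ph = np.linspace(0.0, 2.0 * np.pi, n_seg, endpoint=False)
    ss, pp = np.meshgrid(s, ph, indexing="ij")
    pts = (
        np.asarray(head_center)[None, :]
        + ss.ravel()[:, None] * d[None, :]
        + SHAFT_RADIUS_MM * (np.cos(pp.ravel())[:, None] * e1 + np.sin(pp.ravel())[:, None] * e2)
    )
    return pts


def _canonical_frame_regions(x, y, wss, abd_deg, n_head_pts=700):
    """All regions of one frame in the canonical glenoid frame."""
    theta = np.linspace(0.0, 2.0 * np.pi, 72, endpoint=False)
    contour = np.column_stack(
        [
            GLENOID_SEMI_MINOR_MM * np.cos(theta),
            GLENOID_SEMI_MAJOR_MM * np.sin(theta),
            np.zeros_like(theta),
        ]
    )
    head_center = np.array([x, y, HEAD_STANDOFF_MM])
    dirs = _fibonacci_sphere_dirs(n_head_pts)
    cap = dirs[dirs[:, 2] <= -np.cos(np.deg2rad(80.0))]  # glenoid-facing cap
    head_pts = head_center + HEAD_RADIUS_MM * cap

    alpha = np.deg2rad(abd_deg)
    distal = np.array([0.0, -np.cos(alpha), np.sin(alpha)])
    shaft = _shaft_points(head_center, distal)

    sup_cap = _spherical_cap_mesh(head_center, HEAD_RADIUS_MM)
    plate = _acromion_plate(
        head_center[0], head_center[2], head_center[1] + HEAD_RADIUS_MM + wss
    )
    return {
        "glenoid_contour": contour,
        "scapula": _scapula_blade(),
        "humeral_head": head_pts,
        "humeral_shaft": shaft,
        "proximal_humerus_superior": sup_cap,
        "acromion_inferior": plate,
    }


def _mirror_x(obj):
    if isinstance(obj, trimesh.Trimesh):
        v = np.asarray(obj.vertices).copy()
        v[:, 0] = -v[:, 0]
        f = np.asarray(obj.faces)[:, ::-1]  # keep outward orientation
        return trimesh.Trimesh(vertices=v, faces=f, process=False)
    pts = np.asarray(obj).copy()
    pts[:, 0] = -pts[:, 0]
    return pts


def _random_rigid(rng, rot_sd_deg, trans_sd_mm) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, rot_sd_deg)
    t = rng.normal(0.0, trans_sd_mm / np.sqrt(3.0), size=3)
    return RigidTransform.from_axis_angle(axis, angle, t)


def _noisy(obj, rng, sd):
    if sd == 0:
        return obj
    if isinstance(obj, trimesh.Trimesh):
        v = np.asarray(obj.vertices) + rng.normal(0.0, sd, size=(len(obj.vertices), 3))
        return trimesh.Trimesh(vertices=v, faces=np.asarray(obj.faces), process=False)
    pts = np.asarray(obj)
    return pts + rng.normal(0.0, sd, size=pts.shape)


def generate_sequence(
    profile: SyntheticProfile,
    perturb_rot_sd_deg: float = 5.0,
    perturb_trans_sd_mm: float = 10.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[LabelledFrame], GroundTruth]:
    """Generate one labelled shoulder sequence plus its analytic truth.

    Frame times are ``t_k = k * cycle_s / (n_frames - 1)``.  Abduction ramps
    linearly from 0 to ``abduction_max_deg`` over the cycle; head-centre and
    WSS trajectories are calibrated sinusoids (see module docstring).  The
    reference frame (index 0) keeps the canonical pose; every other frame is
    perturbed by a random whole-frame rigid transform; all frames receive
    vertex noise of sd ``noise_sd_mm``.  Fully reproducible from
    ``profile.seed`` (or a supplied generator).

    Raises
    ------
    ValueError
        For invalid profiles, or a geometrically impossible one whose WSS
        trajectory would fall below the minimum clearance.
    """
    profile.validate()
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    n = profile.n_frames
    times = np.arange(n) * profile.cycle_s / (n - 1)
    x_t = _calibrated_path(profile.x_mean_mm, profile.x_excursion_mm, times, profile.cycle_s, 0.0)
    y_t = _calibrated_path(profile.y_mean_mm, profile.y_excursion_mm, times, profile.cycle_s, 0.0)
    wss_t = _calibrated_path(
        profile.wss_baseline_mm, profile.wss_excursion_mm, times, profile.cycle_s, profile.phase_rad
    )
    abd_t = profile.abduction_max_deg * times / profile.cycle_s
    if wss_t.min() < MIN_WSS_CLEARANCE_MM:
        raise ValueError(
            f"profile is geometrically impossible: WSS trajectory reaches "
            f"{wss_t.min():.2f} mm (< {MIN_WSS_CLEARANCE_MM} mm clearance)"
        )

    frames: list[LabelledFrame] = []
    perturbations: list[RigidTransform] = []
    for k in range(n):
        regions = _canonical_frame_regions(x_t[k], y_t[k], wss_t[k], abd_t[k])
        if profile.side == "left":
            regions = {name: _mirror_x(obj) for name, obj in regions.items()}
        if k == 0:
            pert = RigidTransform.identity()
        else:
            pert = _random_rigid(rng, perturb_rot_sd_deg, perturb_trans_sd_mm)
        out = {}
        for name, obj in regions.items():
            if isinstance(obj, trimesh.Trimesh):
                moved = trimesh.Trimesh(
                    vertices=pert.apply(obj.vertices), faces=np.asarray(obj.faces), process=False
                )
            else:
                moved = pert.apply(obj)
            out[name] = _noisy(moved, rng, profile.noise_sd_mm)
        perturbations.append(pert)
        frames.append(
            LabelledFrame(frame_index=k, time_s=float(times[k]), regions=out, side=profile.side)
        )

    x_sign = -1.0 if profile.side == "left" else 1.0
    truth = GroundTruth(
        times_s=times,
        x_mm=x_t,
        y_mm=y_t,
        wss_mm=wss_t,
        abduction_deg=abd_t,
        perturbations=perturbations,
        superior_hint=np.array([x_sign * x_t[0], 40.0, HEAD_STANDOFF_MM]),
        anterior_hint=np.array([x_sign * 30.0, 0.0, 0.0]),
        side=profile.side,
    )
    return frames, truth


def _jittered(profile: SyntheticProfile, rng, jitter_sd_mm: float, seed: int) -> SyntheticProfile:
    if jitter_sd_mm == 0:
        return replace(profile, seed=seed)
    j = lambda v: float(v + rng.normal(0.0, jitter_sd_mm))  # noqa: E731
    return replace(
        profile,
        wss_baseline_mm=max(j(profile.wss_baseline_mm), 1.0),
        wss_excursion_mm=max(j(profile.wss_excursion_mm), 0.0),
        y_mean_mm=j(profile.y_mean_mm),
        y_excursion_mm=max(j(profile.y_excursion_mm), 0.0),
        x_mean_mm=j(profile.x_mean_mm),
        x_excursion_mm=max(j(profile.x_excursion_mm), 0.0),
        abduction_max_deg=float(
            np.clip(profile.abduction_max_deg + rng.normal(0.0, 2.0), 10.0, 90.0)
        ),
        seed=seed,
    )


@dataclass
class CohortShoulder:
    """One synthetic shoulder of a cohort, kept in memory."""

    shoulder_id: str
    group: str
    profile: SyntheticProfile
    frames: list[LabelledFrame]
    truth: GroundTruth


def simulate_cohort(
    n_per_group: int = 5,
    profiles: dict[str, SyntheticProfile] | None = None,
    seed: int = 0,
    jitter_sd_mm: float = 0.3,
    noise_sd_mm: float | None = None,
    perturb_rot_sd_deg: float = 5.0,
    perturb_trans_sd_mm: float = 10.0,
) -> list[CohortShoulder]:
    """Generate an in-memory cohort of ``n_per_group`` shoulders per group.

    Between-subject variability is emulated by additive Gaussian jitter
    (sd ``jitter_sd_mm``) on the six trajectory parameters (2 degrees on
    peak abduction); ``jitter_sd_mm=0`` makes all same-group shoulders share
    the group profile exactly.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    cohort = []
    for group, profile in profiles.items():
        if noise_sd_mm is not None:
            profile = replace(profile, noise_sd_mm=noise_sd_mm)
        for i in range(n_per_group):
            sub_seed = int(rng.integers(2**31))
            p = _jittered(profile, rng, jitter_sd_mm, sub_seed)
            frames, truth = generate_sequence(
                p,
                perturb_rot_sd_deg=perturb_rot_sd_deg,
                perturb_trans_sd_mm=perturb_trans_sd_mm,
            )
            cohort.append(
                CohortShoulder(
                    shoulder_id=f"{group}{i + 1}",
                    group=group,
                    profile=p,
                    frames=frames,
                    truth=truth,
                )
            )
    return cohort


def generate_cohort(
    out_dir,
    n_per_group: int = 5,
    profiles: dict[str, SyntheticProfile] | None = None,
    seed: int = 0,
    jitter_sd_mm: float = 0.3,
    noise_sd_mm: float | None = None,
) -> Path:
    """Write a synthetic cohort to disk.

    Layout: ``<shoulder_id>/frame_<k>/<region>.ply`` (binary PLY, mm) plus a
    per-shoulder ``manifest.json`` (side, frame times, axis-sign hints) and
    a cohort-level ``ground_truth.csv`` / ``ground_truth_metrics.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(
        n_per_group=n_per_group,
        profiles=profiles,
        seed=seed,
        jitter_sd_mm=jitter_sd_mm,
        noise_sd_mm=noise_sd_mm,
    )
    truth_rows = []
    metric_rows = []
    for sh in cohort:
        sdir = out / sh.shoulder_id
        frame_entries = []
        for frame in sh.frames:
            fdir = sdir / f"frame_{frame.frame_index}"
            fdir.mkdir(parents=True, exist_ok=True)
            paths = {}
            for name, obj in frame.regions.items():
                path = fdir / f"{name}.ply"
                if isinstance(obj, trimesh.Trimesh):
                    obj.export(path)
                else:
                    trimesh.PointCloud(np.asarray(obj)).export(path)
                paths[name] = str(path.relative_to(sdir))
            frame_entries.append(
                {"index": frame.frame_index, "time_s": frame.time_s, "regions": paths}
            )
        manifest = {
            "shoulder_id": sh.shoulder_id,
            "group": sh.group,
            "side": sh.profile.side,
            "reference_index": 0,
            "superior_hint": sh.truth.superior_hint.tolist(),
            "anterior_hint": sh.truth.anterior_hint.tolist(),
            "frames": frame_entries,
        }
        (sdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for k in range(len(sh.frames)):
            truth_rows.append(
                {
                    "shoulder_id": sh.shoulder_id,
                    "group": sh.group,
                    "frame_index": k,
                    "time_s": sh.truth.times_s[k],
                    "x_mm": sh.truth.x_mm[k],
                    "y_mm": sh.truth.y_mm[k],
                    "wss_mm": sh.truth.wss_mm[k],
                    "abduction_deg": sh.truth.abduction_deg[k],
                }
            )
        metric_rows.append(
            {"shoulder_id": sh.shoulder_id, "group": sh.group}
            | sh.truth.metrics().as_dict()
        )
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    pd.DataFrame(metric_rows).to_csv(out / "ground_truth_metrics.csv", index=False)
    return out
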