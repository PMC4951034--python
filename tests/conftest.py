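"""Shared fixtures and independent geometric oracles for the test suite."""

import numpy as np
import pytest

from glenokin.registration import RigidTransform
from glenokin.synthetic import _scapula_blade


def make_ellipse_contour(semi_major=14.0, semi_minor=10.0, n=36):
    """Points on an axis-aligned ellipse in the z=0 plane (major axis = y)."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [semi_minor * np.cos(th), semi_major * np.sin(th), np.zeros(n)]
    )


def random_rigid(rng, max_angle_deg=180.0, trans_scale=20.0) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return RigidTransform.from_axis_angle(
        axis,
        rng.uniform(-max_angle_deg, max_angle_deg),
        rng.normal(0.0, trans_scale, size=3),
    )


def closest_point_triangle_oracle(p, tri):
    """Exact point-triangle distance via plane projection + edge clamping.

    Structured independently of the vectorised barycentric-region
    implementation in glenokin.kinematics.
    """
    a, b, c = (np.asarray(v, dtype=float) for v in tri)
    p = np.asarray(p, dtype=float)
    n = np.cross(b - a, c - a)
    candidates = []
    nn = np.linalg.norm(n)
    if nn > 0:
        n = n / nn
        proj = p - np.dot(p - a, n) * n
        v0, v1, v2 = b - a, c - a, proj - a
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        den = d00 * d11 - d01 * d01
        if den != 0:
            v = (d11 * (v2 @ v0) - d01 * (v2 @ v1)) / den
            w = (d00 * (v2 @ v1) - d01 * (v2 @ v0)) / den
            if v >= 0 and w >= 0 and v + w <= 1:
                candidates.append(proj)
    for p0, p1 in ((a, b), (a, c), (b, c)):
        seg = p1 - p0
        t = float(np.clip(np.dot(p - p0, seg) / np.dot(seg, seg), 0.0, 1.0))
        candidates.append(p0 + t * seg)
    return min(float(np.linalg.norm(p - q)) for q in candidates)


def mesh_gap_bruteforce(mesh_a, mesh_b):
    """Exhaustive symmetric vertex-to-triangle minimum over two meshes."""
    best = np.inf
    for src, dst in ((mesh_a, mesh_b), (mesh_b, mesh_a)):
        tris = np.asarray(dst.vertices)[np.asarray(dst.faces)]
        for p in np.asarray(src.vertices):
            for tri in tris:
                best = min(best, closest_point_triangle_oracle(p, tri))
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scapula_points():
    return np.asarray(_scapula_blade().vertices, dtype=float)
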