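"""Per-frame kinematics, subacromial width and sequence-level metrics."""

import dataclasses

import numpy as np
import pytest
import trimesh

from glenokin import (
    GlenoidCS,
    KinematicSample,
    MissingRegionError,
    SequenceMetrics,
    SphereFit,
    abduction_angle,
    analyze_sequence,
    apply_transform,
    classify_tear,
    normalize_to_glenoid_percent,
    project_head_center,
    subacromial_width,
)
from glenokin.geometry import AxisFit
from glenokin.synthetic import _grid_faces, default_profiles, generate_sequence
from conftest import mesh_gap_bruteforce, random_rigid


def make_cs(center=(0, 0, 0), semi_minor=12.5, semi_major=17.5):
    return GlenoidCS(
        center=np.asarray(center, float),
        axis_x=np.array([1.0, 0, 0]),
        axis_y=np.array([0, 1.0, 0]),
        axis_z=np.array([0, 0, 1.0]),
        semi_minor=semi_minor,
        semi_major=semi_major,
    )


def sphere_at(center, radius=24.0):
    return SphereFit(center=np.asarray(center, float), radius=radius, rms_residual=0.0)


def flat_plate(z, half=40.0, n=9):
    g = np.linspace(-half, half, n)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)])
    return trimesh.Trimesh(vertices=verts, faces=_grid_faces(n, n), process=False)


class TestProjection:
    def test_coincident_centres_project_to_origin(self):
        assert project_head_center(sphere_at([0, 0, 0]), make_cs()) == (0.0, 0.0)

    def test_construction_along_axes(self):
        cs = make_cs()
        c = cs.center + 3 * cs.axis_x + 2 * cs.axis_y + 5 * cs.axis_z
        x, y = project_head_center(sphere_at(c), cs)
        assert np.isclose(x, 3.0) and np.isclose(y, 2.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_point_to_plane_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = random_rigid(rng)
        cs = GlenoidCS(
            center=t.translation,
            axis_x=t.rotation[:, 0],
            axis_y=t.rotation[:, 1],
            axis_z=t.rotation[:, 2],
            semi_minor=12.5,
            semi_major=17.5,
        )
        p = rng.normal(0, 20, 3)
        x, y = project_head_center(sphere_at(p), cs)
        # oracle: project p onto the plane, then solve for in-plane coords
        d = p - cs.center
        p_proj = p - (d @ cs.axis_z) * cs.axis_z
        coeff, *_ = np.linalg.lstsq(
            np.column_stack([cs.axis_x, cs.axis_y]), p_proj - cs.center, rcond=None
        )
        assert np.allclose([x, y], coeff, atol=1e-9)

    def test_offset_along_z_is_invisible(self):
        cs = make_cs()
        base = np.array([3.0, -2.0, 1.0])
        x0, y0 = project_head_center(sphere_at(base), cs)
        x1, y1 = project_head_center(sphere_at(base + 7.3 * cs.axis_z), cs)
        assert abs(x1 - x0) < 1e-9 and abs(y1 - y0) < 1e-9


class TestSubacromialWidth:
    def test_sphere_vs_plate_analytic_gap(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=24.0)
        assert abs(subacromial_width(sph, flat_plate(30.0)) - 6.0) <= 0.05

    def test_tangent_plate_gives_zero(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=24.0)
        assert subacromial_width(sph, flat_plate(24.0)) <= 0.01

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_vertex_triangle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = trimesh.creation.icosphere(subdivisions=1, radius=5.0)
        a = trimesh.Trimesh(
            vertices=np.asarray(a.vertices) + rng.normal(0, 0.4, (len(a.vertices), 3)),
            faces=np.asarray(a.faces),
            process=False,
        )
        b = trimesh.creation.icosphere(subdivisions=1, radius=4.0)
        b = trimesh.Trimesh(
            vertices=np.asarray(b.vertices) + rng.normal(0, 0.4, (len(b.vertices), 3)) + [12, 3, -2],
            faces=np.asarray(b.faces),
            process=False,
        )
        assert np.isclose(subacromial_width(a, b), mesh_gap_bruteforce(a, b), atol=1e-9)

    def test_point_set_inputs_use_pairwise_minimum(self, rng):
        a = rng.normal(0, 1, (40, 3))
        b = rng.normal(0, 1, (30, 3)) + [10.0, 0, 0]
        expected = np.sqrt(((a[:, None] - b[None]) ** 2).sum(-1)).min()
        assert np.isclose(subacromial_width(a, b), expected, atol=1e-12)

    def test_empty_region_raises(self):
        with pytest.raises(Exception):
            subacromial_width(np.empty((0, 3)), np.ones((3, 3)))


class TestAbduction:
    def test_in_plane_axis_is_zero(self):
        axis = AxisFit(point=np.zeros(3), direction=np.array([0.0, 1.0, 0.0]))
        assert abduction_angle(axis, make_cs()) == 0.0

    def test_normal_axis_is_ninety(self):
        axis = AxisFit(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
        assert np.isclose(abduction_angle(axis, make_cs()), 90.0)

    def test_constructed_rotation_angle(self):
        th = np.deg2rad(38.0)
        axis = AxisFit(point=np.zeros(3), direction=np.array([0.0, np.cos(th), np.sin(th)]))
        assert np.isclose(abduction_angle(axis, make_cs()), 38.0, atol=1e-6)


class TestMetricsAndClassification:
    def test_metrics_arithmetic(self):
        samples = [
            KinematicSample(i, float(i), x_mm=0.0, y_mm=0.0, wss_mm=float(w), abduction_deg=0.0)
            for i, w in enumerate([1, 2, 3, 4, 5, 6, 7])
        ]
        m = SequenceMetrics.from_samples(samples)
        assert m.wss_avg == 4.0 and m.wss_range == 6.0 and m.n_samples == 7
        assert m.x_range == 0.0 and m.y_range == 0.0

    @pytest.mark.parametrize(
        "wss_range,expected",
        [(5.3, "tear"), (2.1, "no_tear"), (4.0, "no_tear"), (4.0001, "tear")],
    )
    def test_tear_rule_strict_threshold(self, wss_range, expected):
        m = SequenceMetrics(7.0, wss_range, 0, 0, 0, 0, 7)
        assert classify_tear(m) == expected

    @pytest.mark.parametrize(
        "xy,expected",
        [((0.0, 0.0), (0.0, 0.0)), ((0.0, 17.5), (0.0, 100.0)), ((6.25, -4.375), (50.0, -25.0))],
    )
    def test_percent_normalization_maps_rim_to_circle(self, xy, expected):
        cs = make_cs()
        assert np.allclose(normalize_to_glenoid_percent(*xy, cs), expected)


def _noiseless_sequence(group="N", **kwargs):
    profile = dataclasses.replace(default_profiles()[group], noise_sd_mm=0.0, **kwargs)
    return generate_sequence(profile, perturb_rot_sd_deg=0.0, perturb_trans_sd_mm=0.0)


class TestAnalyzeSequence:
    def test_static_sequence_has_zero_ranges(self):
        profile = dataclasses.replace(
            default_profiles()["N"],
            noise_sd_mm=0.0,
            wss_excursion_mm=0.0,
            x_excursion_mm=0.0,
            y_excursion_mm=0.0,
            abduction_max_deg=0.0,
        )
        frames, truth = generate_sequence(profile, perturb_rot_sd_deg=0, perturb_trans_sd_mm=0)
        res = analyze_sequence(
            frames, superior_hint=truth.superior_hint, anterior_hint=truth.anterior_hint
        )
        assert res.metrics.wss_range < 1e-9
        assert res.metrics.x_range < 1e-9
        assert res.metrics.y_range < 1e-9
        xs = [s.x_mm for s in res.samples]
        assert np.allclose(xs, xs[0], atol=1e-9)

    def test_noiseless_trajectory_recovery_matches_ground_truth(self):
        frames, truth = _noiseless_sequence("SST")
        res = analyze_sequence(
            frames, superior_hint=truth.superior_hint, anterior_hint=truth.anterior_hint
        )
        assert len(res.samples) == 7
        for i, s in enumerate(res.samples):
            k = i + 1
            assert abs(s.x_mm - truth.x_mm[k]) < 1e-3
            assert abs(s.y_mm - truth.y_mm[k]) < 1e-3
            assert abs(s.wss_mm - truth.wss_mm[k]) < 1e-3
            assert abs(s.abduction_deg - truth.abduction_deg[k]) < 0.1
        gt = truth.metrics()
        assert abs(res.metrics.x_range - gt.x_range) < 1e-3

    def test_recovery_with_frame_perturbations(self):
        """ICP must undo whole-frame rigid perturbations before measuring."""
        profile = dataclasses.replace(default_profiles()["MCT"], noise_sd_mm=0.0)
        frames, truth = generate_sequence(profile)  # default 5 deg / 10 mm perturbation
        res = analyze_sequence(
            frames, superior_hint=truth.superior_hint, anterior_hint=truth.anterior_hint
        )
        for i, s in enumerate(res.samples):
            assert abs(s.x_mm - truth.x_mm[i + 1]) < 1e-3
            assert abs(s.wss_mm - truth.wss_mm[i + 1]) < 1e-3

    def test_global_rigid_motion_invariance(self, rng):
        frames, truth = _noiseless_sequence()
        res0 = analyze_sequence(
            frames, superior_hint=truth.superior_hint, anterior_hint=truth.anterior_hint
        )
        t = random_rigid(rng)
        moved = [apply_transform(f, t) for f in frames]
        res1 = analyze_sequence(
            moved,
            superior_hint=t.apply(truth.superior_hint[None])[0],
            anterior_hint=t.apply(truth.anterior_hint[None])[0],
        )
        for s0, s1 in zip(res0.samples, res1.samples):
            assert abs(s0.x_mm - s1.x_mm) < 1e-6
            assert abs(s0.y_mm - s1.y_mm) < 1e-6
            assert abs(s0.wss_mm - s1.wss_mm) < 1e-6
            assert abs(s0.abduction_deg - s1.abduction_deg) < 1e-6

    def test_missing_region_raises_named_error(self):
        frames, truth = _noiseless_sequence()
        del frames[3].regions["acromion_inferior"]
        with pytest.raises(MissingRegionError, match="acromion_inferior"):
            analyze_sequence(
                frames, superior_hint=truth.superior_hint, anterior_hint=truth.anterior_hint
            )

    def test_unpacks_as_triple(self):
        frames, truth = _noiseless_sequence()
        samples, metrics, cs = analyze_sequence(
            frames, superior_hint=truth.superior_hint, anterior_hint=truth.anterior_hint
        )
        assert len(samples) == metrics.n_samples
        assert cs.semi_major >= cs.semi_minor
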