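"""Ring morphometry: plane fitting, fan-triangulated area, footprints,
signed plane distances, ratchet pulse decomposition, nuclear travel."""

import math

import numpy as np
import pytest

from midgut4d.extrusion import (
    detect_pulses,
    fit_basal_plane,
    nuclear_travel,
    plane_distance,
    ring_area,
    ring_centroid,
    ring_footprint,
)


def fan_area_oracle(vertices):
    """Independent re-summation of the centroid-fan triangle areas."""
    v = np.asarray(vertices, dtype=float)
    c = v.mean(axis=0)
    total = 0.0
    for i in range(len(v)):
        a = v[i] - c
        b = v[(i + 1) % len(v)] - c
        total += 0.5 * np.linalg.norm(np.cross(a, b))
    return total


def regular_polygon(n, side, z=0.0):
    rho = side / (2 * math.sin(math.pi / n))
    ang = 2 * math.pi * np.arange(n) / n
    return np.stack([rho * np.cos(ang), rho * np.sin(ang), np.full(n, z)], axis=1)


class TestBasalPlane:
    def test_axis_aligned_triangle(self):
        plane = fit_basal_plane((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert np.allclose(np.abs(plane.normal), [0, 0, 1])
        assert plane_distance((5, -3, 0), plane) == pytest.approx(0.0)

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(3, 3))
        shift = rng.normal(size=3)
        p1 = fit_basal_plane(*pts)
        p2 = fit_basal_plane(*(pts + shift))
        assert np.allclose(p1.normal, p2.normal)

    def test_contains_its_points(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(3, 3)) * 10
            plane = fit_basal_plane(*pts)
            for p in pts:
                assert abs(plane_distance(p, plane)) < 1e-9

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            fit_basal_plane((0, 0, 0), (1, 1, 1), (2, 2, 2))

    def test_orientation_toward_apical_point(self):
        plane = fit_basal_plane((0, 0, 0), (1, 0, 0), (0, 1, 0))
        plane = plane.oriented_toward((0, 0, 7))
        assert plane.normal[2] > 0


class TestRingArea:
    def test_unit_square(self):
        sq = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
        assert ring_area(sq) == pytest.approx(1.0, rel=1e-12)

    def test_regular_hexagon_side_2(self):
        # closed form (3*sqrt(3)/2) * s^2
        hexagon = regular_polygon(6, 2.0)
        assert ring_area(hexagon) == pytest.approx(6 * math.sqrt(3), rel=1e-12)

    @pytest.mark.parametrize("lifted", [False, True])
    def test_matches_fan_oracle_on_random_hexagons(self, rng, lifted):
        for _ in range(200):
            hexagon = regular_polygon(6, rng.uniform(0.5, 5.0))
            hexagon += rng.normal(scale=0.3, size=hexagon.shape)
            if lifted:
                hexagon[rng.integers(6), 2] += rng.uniform(0.5, 3.0)
            assert ring_area(hexagon) == pytest.approx(
                fan_area_oracle(hexagon), rel=1e-9
            )

    def test_rigid_motion_invariance_and_quadratic_scaling(self, rng):
        hexagon = regular_polygon(6, 2.0) + rng.normal(scale=0.2, size=(6, 3))
        a0 = ring_area(hexagon)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = hexagon @ q.T + rng.normal(size=3)
        assert ring_area(moved) == pytest.approx(a0, rel=1e-9)
        assert ring_area(3.0 * hexagon) == pytest.approx(9.0 * a0, rel=1e-9)

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            ring_area([(0, 0, 0), (1, 0, 0)])


class TestFootprint:
    def test_in_plane_ring_is_congruent(self):
        plane = fit_basal_plane((0, 0, 0), (1, 0, 0), (0, 1, 0))
        hexagon = regular_polygon(6, 2.0)
        fp = ring_footprint(hexagon, plane)
        d_3d = np.linalg.norm(np.diff(hexagon, axis=0), axis=1)
        d_2d = np.linalg.norm(np.diff(fp, axis=0), axis=1)
        assert np.allclose(d_3d, d_2d)

    def test_normal_translation_is_killed(self):
        plane = fit_basal_plane((0, 0, 0), (1, 0, 0), (0, 1, 0))
        hexagon = regular_polygon(6, 2.0)
        fp1 = ring_footprint(hexagon, plane)
        fp2 = ring_footprint(hexagon + np.array([0, 0, 10.0]), plane)
        assert np.allclose(fp1, fp2)

    def test_tilted_ring_area_follows_cosine(self):
        plane = fit_basal_plane((0, 0, 0), (1, 0, 0), (0, 1, 0))
        hexagon = regular_polygon(6, 2.0)
        tilt = math.radians(30)
        rot = np.array(
            [
                [1, 0, 0],
                [0, math.cos(tilt), -math.sin(tilt)],
                [0, math.sin(tilt), math.cos(tilt)],
            ]
        )
        tilted = hexagon @ rot.T
        fp = ring_footprint(tilted, plane)
        fp3d = np.column_stack([fp, np.zeros(len(fp))])
        assert ring_area(fp3d) == pytest.approx(
            ring_area(tilted) * math.cos(tilt), rel=1e-12
        )


class TestPlaneDistance:
    def test_signed_examples(self):
        plane = fit_basal_plane((0, 0, 0), (1, 0, 0), (0, 1, 0)).oriented_toward(
            (0, 0, 1)
        )
        assert plane_distance((0, 0, 5), plane) == pytest.approx(5.0)
        assert plane_distance((3, 2, 0), plane) == pytest.approx(0.0)

    def test_matches_least_squares_oracle(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(3, 3)) * 5
            plane = fit_basal_plane(*pts)
            q = rng.normal(size=3) * 10
            # oracle: minimal distance from q to any point of the plane
            n = plane.normal
            proj = q - np.dot(q - pts[0], n) * n
            assert abs(plane_distance(q, plane)) == pytest.approx(
                np.linalg.norm(q - proj), abs=1e-9
            )


class TestDetectPulses:
    def test_linear_decrease_is_one_constriction(self):
        t = np.arange(0, 100, 5.0)
        a = 80 - 0.5 * t
        dec = detect_pulses(t, a)
        assert len(dec.segments) == 1
        assert dec.segments[0].kind == "constriction"
        assert dec.segments[0].rate == pytest.approx(-0.5)
        assert dec.constriction_time == pytest.approx(t[-1] - t[0])

    def test_constant_series_is_one_stabilization(self):
        t = np.arange(0, 100, 5.0)
        dec = detect_pulses(t, np.full_like(t, 42.0))
        assert len(dec.segments) == 1
        assert dec.segments[0].kind == "relaxation"

    def test_alternation_and_time_conservation(self, rng):
        t = np.arange(0, 300, 5.0)
        a = 60 + 20 * np.sin(t / 30) + rng.normal(scale=1.0, size=t.shape)
        dec = detect_pulses(t, a)
        kinds = [s.kind for s in dec.segments]
        assert all(k1 != k2 for k1, k2 in zip(kinds, kinds[1:]))
        assert dec.constriction_time + dec.relaxation_time == pytest.approx(
            t[-1] - t[0]
        )
        # net change equals the rate-weighted segment sum
        net = sum(s.rate * s.duration for s in dec.segments)
        assert net == pytest.approx(a[-1] - a[0], rel=1e-9, abs=1e-9)

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            detect_pulses([0, 5, 10], [3, 2, 1], smoothing_window=10)


class TestNuclearTravel:
    def make_trajectory(self, start, peak, end=443.0, peak_d=30.0, plateau=12.0):
        t = np.arange(0.0, end + 1)
        d = np.interp(t, [0, start, peak, peak + 80, end], [0, 0, peak_d, plateau, plateau])
        return t, d

    def test_onset_peak_duration(self):
        # apical rise first apparent at 150 min, deepest at 263 min
        t, d = self.make_trajectory(150.0, 263.0)
        travel = nuclear_travel(t, d)
        assert travel.event
        assert travel.start == pytest.approx(150.0, abs=1.0)
        assert travel.peak == pytest.approx(263.0)
        assert travel.duration == pytest.approx(113.0, abs=1.0)
        assert travel.recoil == pytest.approx(18.0, abs=0.5)

    def test_frame_arithmetic(self):
        t = np.arange(0, 31) * 7.5
        d = np.interp(t, [0, 75, 150, 225], [0, 0, 20, 20])
        travel = nuclear_travel(t, d)
        assert travel.duration == pytest.approx(150.0 - 75.0, abs=7.5)

    def test_flat_series_is_no_event(self):
        t = np.arange(0, 200, 7.5)
        travel = nuclear_travel(t, np.zeros_like(t))
        assert not travel.event
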