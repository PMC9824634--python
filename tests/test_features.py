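"""Unit and oracle tests for the 13 trajectory features."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from msaccid.core import Microsaccade, ParameterError
from msaccid import features as ft

from conftest import random_event


def straight(n, dx=0.01, dy=0.0):
    return Microsaccade(
        np.column_stack([np.arange(n) * dx, np.arange(n) * dy])
    )


class TestDuration:
    @pytest.mark.parametrize("n,expected", [(50, 49.0), (2, 1.0), (11, 10.0)])
    def test_samples_minus_one_at_1khz(self, n, expected):
        assert ft.duration(straight(n)) == expected

    def test_scales_with_rate(self):
        m = Microsaccade(straight(11).points, dt_ms=2.0)
        assert ft.duration(m) == 20.0


class TestHeight:
    def test_apex_above_chord(self):
        m = Microsaccade(np.array([[0, 0], [1, 1], [2, 0]], float))
        assert ft.height(m) == pytest.approx(1.0)

    def test_collinear_is_zero(self):
        m = Microsaccade(np.array([[0, 0], [1, 0], [2, 0]], float))
        assert ft.height(m) == 0.0

    def test_closed_loop_uses_distance_to_start(self):
        m = Microsaccade(np.array([[0, 0], [0, 2], [1, 2], [0, 0]], float))
        assert ft.height(m) == pytest.approx(np.sqrt(5.0))

    def test_two_points_zero(self):
        assert ft.height(straight(2)) == 0.0

    def test_heron_equivalence_on_random_events(self):
        """The semi-perimeter (Heron) form and the cross-product
        perpendicular distance agree to 1e-9."""
        for seed in range(120):
            m = random_event(seed, n=15)
            assert ft.height(m) == pytest.approx(ft.height_heron(m), abs=1e-9)


class TestSelfIntersections:
    def test_symmetric_x(self):
        m = Microsaccade(np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float))
        hits = ft.self_intersections(m)
        assert len(hits) == 1
        c = hits[0]
        assert (c.k, c.l) == (0, 2)
        assert c.lam == pytest.approx(0.5)
        assert c.mu == pytest.approx(0.5)
        assert c.point == pytest.approx((0.5, 0.5))

    def test_parallel_segments_no_crossing(self):
        m = Microsaccade(
            np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        )  # edges 0 and 2 are parallel
        assert ft.self_intersections(m) == []

    def test_adjacent_edges_excluded(self):
        m = Microsaccade(np.array([[0, 0], [1, 0], [0.5, 0.5]], float))
        assert ft.self_intersections(m) == []

    def test_brute_force_oracle_equivalence(self):
        """Crossing sets match an independent shapely segment-pair oracle
        on 100 random polylines."""
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import LineString

        for seed in range(100):
            m = random_event(seed, n=20)
            got = {(c.k, c.l) for c in ft.self_intersections(m)}
            pts = m.points
            expected = set()
            for k in range(len(pts) - 1):
                for l in range(k + 2, len(pts) - 1):
                    a = LineString([pts[k], pts[k + 1]])
                    b = LineString([pts[l], pts[l + 1]])
                    inter = a.intersection(b)
                    if not inter.is_empty and inter.geom_type == "Point":
                        expected.add((k, l))
            assert got == expected
            # crossing coordinates agree too
            for c in ft.self_intersections(m):
                a = LineString([pts[c.k], pts[c.k + 1]])
                b = LineString([pts[c.l], pts[c.l + 1]])
                p = a.intersection(b)
                assert c.point == pytest.approx((p.x, p.y), abs=1e-9)


def star_shaped_polygon(rng):
    """A random simple polygon: vertices in angular order around the
    origin with bounded angular gaps (every gap < pi keeps it simple)."""
    n = int(rng.integers(4, 12))
    gaps = rng.uniform(0.6, 1.4, n)
    ang = 2 * np.pi * np.cumsum(gaps) / gaps.sum()
    rad = rng.uniform(0.5, 1.5, n)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])


def one_crossing_split_area(pts):
    """Independent oracle: area of a closed curve with exactly one
    self-crossing, split explicitly into its two loops."""
    m = pts.shape[0]
    closed = np.vstack([pts, pts[0]])
    hits = ft.self_intersections(
        Microsaccade(closed), closed=False
    )
    hits = [c for c in hits if not (c.k == 0 and c.l == m - 1)]
    assert len(hits) == 1
    c = hits[0]
    q = np.array(c.point)
    loop1 = np.vstack([q, closed[c.k + 1 : c.l + 1]])
    loop2 = np.vstack([q, closed[c.l + 1 : m], closed[:c.k + 1]])
    return ft._shoelace(loop1) + ft._shoelace(loop2)


class TestArea:
    def test_unit_square(self):
        m = Microsaccade(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert ft.area(m) == pytest.approx(1.0)

    def test_two_point_event(self):
        assert ft.area(straight(2)) == 0.0

    def test_bowtie_counts_both_triangles(self):
        m = Microsaccade(np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float))
        assert ft.area(m) == pytest.approx(0.5)

    def test_simple_polygons_match_shapely(self):
        """Random star-shaped (simple) polygons agree with the shapely
        polygon area to 1e-9."""
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Polygon

        rng = np.random.default_rng(3)
        for _ in range(120):
            pts = star_shaped_polygon(rng)
            assert ft.area(Microsaccade(pts)) == pytest.approx(
                Polygon(pts).area, abs=1e-9
            )

    def test_single_crossing_decomposition_oracle(self):
        """Random curves with exactly one self-crossing match an explicit
        two-loop split; at least 100 qualifying cases."""
        count = 0
        seed = 0
        while count < 100:
            seed += 1
            m = random_event(seed, n=6)
            pts = m.points
            closed = np.vstack([pts, pts[0]])
            hits = ft.self_intersections(Microsaccade(closed))
            hits = [
                c for c in hits if not (c.k == 0 and c.l == len(pts) - 1)
            ]
            if len(hits) != 1:
                continue
            count += 1
            assert ft.area(m) == pytest.approx(
                one_crossing_split_area(pts), abs=1e-9
            )

    def test_pentagram_counts_core_by_winding(self):
        """The five-pointed star splits into loops that cover the five
        tips once and the doubly-wound core pentagon twice; the expected
        value is assembled independently from the planar-arrangement
        faces (5 tips + 2 x core)."""
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import LineString
        from shapely.ops import polygonize, unary_union

        ang = np.pi / 2 + 2 * np.pi * np.arange(5) * 2 / 5  # skip-2 star
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        ring = np.vstack([pts, pts[0]])
        faces = list(polygonize(unary_union(LineString(ring))))
        assert len(faces) == 6
        core = max(f.area for f in faces)  # the pentagon is the largest face
        expected = sum(f.area for f in faces) + core
        assert ft.area(Microsaccade(pts)) == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 500))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = random_event(seed, n=10)
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = Microsaccade(m.points @ R.T + rng.normal(0, 5, 2))
        assert ft.area(moved) == pytest.approx(ft.area(m), abs=1e-9)


class TestSharpness:
    def test_ratio(self):
        assert ft.sharpness(1.0, 2.0) == 0.5

    def test_degenerate_zero(self):
        assert ft.sharpness(0.0, 0.0) == 0.0

    def test_compose_with_height_and_area(self):
        m = Microsaccade(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        H, S = ft.height(m), ft.area(m)
        assert ft.sharpness(H, S) == pytest.approx(H / 1.0)


class TestBaseLengthAndDiameter:
    def test_three_four_five(self):
        m = Microsaccade(np.array([[0, 0], [1, 1], [3, 4]], float))
        assert ft.base_length(m) == pytest.approx(5.0)

    def test_closed_loop_zero(self):
        m = Microsaccade(np.array([[0, 0], [1, 1], [0, 0]], float))
        assert ft.base_length(m) == 0.0

    def test_square_diameter(self):
        m = Microsaccade(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert ft.max_diameter(m) == pytest.approx(np.sqrt(2.0))

    def test_two_points_diameter_equals_base(self):
        m = straight(2, dx=0.3)
        assert ft.max_diameter(m) == ft.base_length(m)

    def test_diameter_dominates_base_and_height(self):
        for seed in range(50):
            m = random_event(seed)
            d = ft.max_diameter(m)
            assert d >= ft.base_length(m) - 1e-12
            assert d >= ft.height(m) - 1e-12


class TestDoubleClassify:
    @pytest.mark.parametrize(
        "base,dur,flag", [(0.4, 50.0, 1), (1.0, 50.0, 0), (0.5, 50.0, 0)]
    )
    def test_threshold_rule(self, base, dur, flag):
        ratio, got = ft.double_classify(base, dur)
        assert got == flag
        assert ratio == pytest.approx(base / dur)

    def test_tie_is_mono(self):
        _, flag = ft.double_classify(0.01 * 30.0, 30.0)
        assert flag == 0

    def test_zero_duration_rejected(self):
        with pytest.raises(ParameterError):
            ft.double_classify(0.1, 0.0)


class TestSpeedProfile:
    def test_constant_speed(self):
        m = straight(40, dx=0.1)
        v, v_av, v11, v21 = ft.speed_profile(m)
        assert v_av == pytest.approx(0.1)
        assert v11 == pytest.approx(0.1)
        assert v21 == pytest.approx(0.1)

    def test_spike_window_mean(self):
        # 30 unit steps except one double step: v = [..1..,2,..1..]
        steps = np.ones(30) * 0.0
        steps[15] = 1.0
        x = np.concatenate([[0.0], np.cumsum(steps)])
        m = Microsaccade(np.column_stack([x, np.zeros_like(x)]))
        _, v_av, v11, _ = ft.speed_profile(m)
        assert v11 == pytest.approx(1.0 / 11.0)

    def test_short_event_fallback(self):
        m = straight(8, dx=0.05)
        _, v_av, v11, v21 = ft.speed_profile(m)
        assert v11 == v_av
        assert v21 == v_av

    def test_sliding_mean_oracle(self):
        """Windowed max speed equals the brute-force sliding-window
        maximum on random events (1e-9)."""
        for seed in range(120):
            m = random_event(seed, n=35)
            v, _, v11, v21 = ft.speed_profile(m)
            for W, got in ((11, v11), (21, v21)):
                expected = max(
                    np.mean(v[i : i + W]) for i in range(len(v) - W + 1)
                )
                assert got == pytest.approx(expected, abs=1e-9)


class TestAccelProfile:
    def test_constant_speeds(self):
        assert ft.accel_profile(np.full(10, 0.3)) == (0.0, 0.0)

    def test_arithmetic(self):
        A_av, _ = ft.accel_profile(np.array([0.0, 1.0, 2.0, 3.0]))
        assert A_av == pytest.approx(1.0)

    def test_top10_magnitude_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            v = rng.normal(0, 1, 20)
            _, got = ft.accel_profile(v)
            mags = sorted(np.abs(np.diff(v)))[::-1]
            assert got == pytest.approx(np.mean(mags[:10]), abs=1e-12)

    def test_short_input(self):
        assert ft.accel_profile(np.array([0.5])) == (0.0, 0.0)


class TestExtractFeatures:
    def test_vector_contract(self):
        f = ft.extract_features(straight(50, dx=0.004))
        assert f.shape == (13,)
        assert f[0] == 49.0

    def test_collinear_event_degenerate_geometry(self):
        f = ft.extract_features(straight(20, dx=0.01))
        assert f[1] == 0.0  # height
        assert f[2] == 0.0  # area
        assert f[3] == 0.0  # sharpness

    @given(st.integers(0, 300))
    def test_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = random_event(seed)
        shifted = Microsaccade(m.points + rng.normal(0, 10, 2))
        np.testing.assert_allclose(
            ft.extract_features(shifted), ft.extract_features(m), atol=1e-9
        )

    @given(st.integers(0, 300))
    def test_rotation_invariance_of_distance_features(self, seed):
        rng = np.random.default_rng(seed + 1)
        m = random_event(seed)
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = Microsaccade(m.points @ R.T)
        fa, fb = ft.extract_features(m), ft.extract_features(rot)
        for idx in (0, 1, 2, 4, 5, 6, 7, 8, 9, 12):
            assert fb[idx] == pytest.approx(fa[idx], abs=1e-9)


class TestNormalizeFeatures:
    def test_unit_vector_scaling(self):
        train = np.array([[3.0], [4.0]]) * np.ones((1, 13))
        scaled, _, scales = ft.normalize_features(train)
        np.testing.assert_allclose(scaled[:, 0], [0.6, 0.8])

    def test_zero_column_untouched(self):
        train = np.ones((4, 13))
        train[:, 5] = 0.0
        scaled, _, scales = ft.normalize_features(train)
        assert scales[5] == 1.0
        assert np.all(scaled[:, 5] == 0.0)

    def test_scaled_columns_have_unit_norm(self, rng):
        train = rng.uniform(0.1, 3.0, (30, 13))
        scaled, _, _ = ft.normalize_features(train)
        np.testing.assert_allclose(
            np.linalg.norm(scaled, axis=0), np.ones(13), atol=1e-12
        )

    def test_same_scales_applied_to_others(self, rng):
        train = rng.uniform(0.1, 3.0, (10, 13))
        others = rng.uniform(0.1, 3.0, (6, 13))
        _, scaled_others, scales = ft.normalize_features(train, others)
        np.testing.assert_allclose(scaled_others, others / scales)
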