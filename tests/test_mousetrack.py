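"""Trajectory geometry: normalization, mirroring, a.u.c., proximity, runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from warpkit.mousetrack import (
    NormalizedTrack,
    normalize_coordinates,
    time_normalize,
    TrajectoryTimeNormalizer,
    mirror_track,
    mirror_pool,
    pooled_mean,
    compute_auc,
    proximity_curve,
    running_ttest,
)


class TestNormalizeCoordinates:
    @pytest.mark.parametrize("px,expected", [
        ((0, 0), (0.0, 0.0)),
        ((1919, 1079), (1.0, 1.0)),
        ((960, 135), (960 / 1919, 135 / 1079)),
    ])
    def test_pixel_division(self, px, expected):
        out = normalize_coordinates(np.array([px], dtype=float), (1920, 1080))
        np.testing.assert_allclose(out[0], expected)

    def test_offscreen_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = normalize_coordinates(np.array([[2000.0, -5.0]]),
                                        (1920, 1080))
        np.testing.assert_allclose(out[0], [1.0, 0.0])

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            normalize_coordinates(np.zeros((1, 2)), (0, 1080))


class TestTimeNormalize:
    def test_two_point_track_becomes_collinear_grid(self):
        track = time_normalize([0.0, 1.0], [0.0, 0.5])
        assert track.T == 101
        np.testing.assert_allclose(track.y, 0.5 * track.x, atol=1e-12)

    def test_track_already_on_grid_is_identity(self):
        x = np.linspace(0.2, 0.9, 101)
        y = np.sqrt(np.linspace(0.0, 1.0, 101))
        track = time_normalize(x, y)
        np.testing.assert_allclose(track.x, x, atol=1e-12)
        np.testing.assert_allclose(track.y, y, atol=1e-12)

    def test_analytic_path_interpolated_exactly_at_nodes(self):
        # piecewise-linear path sampled on a grid that contains the T-grid:
        # linear interpolation must reproduce the analytic form exactly
        s = np.linspace(0.0, 1.0, 201)
        x = 0.5 + 0.4 * s
        y = np.where(s < 0.5, s, 0.5 + 2 * (s - 0.5) ** 2)
        # piecewise linear reference on the same nodes
        track = time_normalize(x, y, T=101)
        np.testing.assert_allclose(track.x, 0.5 + 0.4 * np.linspace(0, 1, 101),
                                   atol=1e-9)

    def test_endpoints_always_preserved(self, rng):
        for _ in range(10):
            n = rng.integers(2, 40)
            x, y = rng.random(n), rng.random(n)
            tr = time_normalize(x, y, T=31)
            assert (tr.x[0], tr.y[0]) == (x[0], y[0])
            assert (tr.x[-1], tr.y[-1]) == (x[-1], y[-1])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            time_normalize([0.5], [0.5])

    def test_transformer_wrapper(self):
        tn = TrajectoryTimeNormalizer(T=51)
        assert tn.get_params() == {"T": 51}
        out = tn.fit([]).transform(
            [([0.0, 1.0], [0.0, 1.0], "right")])
        assert out[0].T == 51
        tn.set_params(T=11)
        assert tn.T == 11


class TestMirroring:
    def test_involution(self):
        tr = NormalizedTrack(np.array([0.5, 0.3, 0.1]),
                             np.array([0.1, 0.5, 0.9]), "left")
        back = mirror_track(mirror_track(tr))
        np.testing.assert_allclose(back.x, tr.x)
        assert back.target_side == "left"
        assert back.mirrored is False

    def test_pool_reflects_only_left(self):
        left = NormalizedTrack(np.array([0.5, 0.2, 0.1]),
                               np.array([0.1, 0.5, 0.9]), "left")
        right = NormalizedTrack(np.array([0.5, 0.8, 0.9]),
                                np.array([0.1, 0.5, 0.9]), "right")
        pooled = mirror_pool([left, right])
        assert all(t.target_side == "right" for t in pooled)
        np.testing.assert_allclose(pooled[0].x, 1.0 - left.x)
        np.testing.assert_allclose(pooled[1].x, right.x)

    def test_pooled_mean_of_mirror_images_is_either_one(self):
        x = np.array([0.5, 0.3, 0.2, 0.1])
        y = np.array([0.1, 0.4, 0.7, 0.9])
        left = NormalizedTrack(x, y, "left")
        right = NormalizedTrack(1.0 - x, y, "right")
        mean = pooled_mean([left, right])
        np.testing.assert_allclose(mean.x, 1.0 - x, atol=1e-12)
        np.testing.assert_allclose(mean.y, y, atol=1e-12)

    def test_pooled_mean_equals_brute_force(self, rng):
        tracks = []
        for _ in range(8):
            x, y = rng.random(21), rng.random(21)
            side = "left" if rng.random() < 0.5 else "right"
            tracks.append(NormalizedTrack(x, y, side))
        mean = pooled_mean(tracks)
        xs = np.stack([1 - t.x if t.target_side == "left" else t.x
                       for t in tracks])
        np.testing.assert_allclose(mean.x, xs.mean(axis=0), atol=1e-12)


class TestAuc:
    def test_straight_line_any_sampling_is_zero(self, rng):
        s = np.sort(np.concatenate([[0, 1], rng.random(30)]))
        tr = NormalizedTrack(0.5 + 0.4 * s, 0.1 + 0.8 * s, "right")
        stat = compute_auc(tr)
        assert stat.auc_signed == pytest.approx(0.0, abs=1e-12)
        assert stat.auc_absolute == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_toy_path_quarter_area(self):
        # path (0.5,0)->(0.5,1)->(1,1) vs chord (0.5,0)->(1,1): area 0.25,
        # bowing away from the right-side target => positive sign
        tr = NormalizedTrack(np.array([0.5, 0.5, 1.0]),
                             np.array([0.0, 1.0, 1.0]), "right")
        stat = compute_auc(tr)
        assert stat.auc_signed == pytest.approx(0.25, abs=1e-12)
        assert stat.auc_absolute == pytest.approx(0.25, abs=1e-12)

    def test_mirroring_negates_signed_preserves_absolute(self, rng):
        for _ in range(10):
            s = np.linspace(0, 1, 40)
            x = 0.5 + 0.4 * s + 0.1 * np.sin(np.pi * s) * rng.random()
            y = 0.1 + 0.8 * s + 0.05 * np.sin(2 * np.pi * s)
            tr = NormalizedTrack(x, y, "right")
            a = compute_auc(tr)
            # pure reflection (target held fixed) negates the signed area
            refl = NormalizedTrack(1.0 - x, y, "right")
            b = compute_auc(refl)
            assert b.auc_signed == pytest.approx(-a.auc_signed, abs=1e-12)
            assert b.auc_absolute == pytest.approx(a.auc_absolute, abs=1e-12)
            # mirror-pooling (reflection + target flip) keeps "away from
            # target" positive, so the signed area is invariant
            c = compute_auc(mirror_track(tr))
            assert c.auc_signed == pytest.approx(a.auc_signed, abs=1e-12)

    def test_degenerate_closed_path_flagged(self):
        theta = np.linspace(0, 2 * np.pi, 50)
        tr = NormalizedTrack(0.5 + 0.2 * np.cos(theta),
                             0.5 + 0.2 * np.sin(theta), "right")
        stat = compute_auc(tr)
        assert stat.degenerate
        assert abs(stat.auc_signed) == pytest.approx(np.pi * 0.04, rel=1e-2)

    def test_agrees_with_fine_grid_rasterization(self, rng):
        """Shoelace area matches a brute-force pixel count within 1%."""
        from matplotlib.path import Path as MplPath
        g = np.linspace(0, 1, 400)
        gx, gy = np.meshgrid(g, g)
        points = np.column_stack([gx.ravel(), gy.ravel()])
        cell = (g[1] - g[0]) ** 2
        for _ in range(20):
            s = np.linspace(0, 1, 60)
            amp = 0.05 + 0.25 * rng.random()
            x = 0.5 + 0.4 * s - amp * np.sin(np.pi * s)
            y = 0.12 + 0.8 * s
            tr = NormalizedTrack(x, y, "right")
            area = abs(compute_auc(tr).auc_signed)
            poly = MplPath(np.column_stack([np.append(x, x[0]),
                                            np.append(y, y[0])]))
            raster = poly.contains_points(points).sum() * cell
            assert raster == pytest.approx(area, rel=0.01, abs=5e-4)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            compute_auc(NormalizedTrack(np.array([0.0, 1.0]),
                                        np.array([0.0, 1.0]), "right"))


class TestProximity:
    def test_at_target_is_one_at_farthest_is_zero(self):
        tr = NormalizedTrack(np.array([0.5, 0.7, 0.925]),
                             np.array([0.125, 0.5, 0.925]), "right")
        curve = proximity_curve(tr, target=(0.925, 0.925))
        assert curve.proximity[0] == pytest.approx(0.0)   # farthest sample
        assert curve.proximity[-1] == pytest.approx(1.0)  # at the target

    def test_constant_speed_straight_approach_is_linear(self):
        s = np.linspace(0.0, 1.0, 101)
        tr = NormalizedTrack(0.5 + 0.425 * s, 0.125 + 0.8 * s, "right")
        curve = proximity_curve(tr, target=(0.925, 0.925))
        np.testing.assert_allclose(curve.proximity, s, atol=1e-12)

    def test_start_on_target_degenerate(self):
        tr = NormalizedTrack(np.full(5, 0.925), np.full(5, 0.925), "right")
        curve = proximity_curve(tr, target=(0.925, 0.925))
        assert curve.degenerate
        np.testing.assert_allclose(curve.proximity, 1.0)

    def test_shared_max_distance_option(self):
        tr = NormalizedTrack(np.array([0.5, 0.925]),
                             np.array([0.125, 0.925]), "right")
        curve = proximity_curve(tr, target=(0.925, 0.925), max_distance=2.0)
        assert curve.proximity[0] == pytest.approx(1 - 0.9056 / 2.0, abs=1e-3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_hold_for_random_tracks(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 80))
        tr = NormalizedTrack(r.random(n), r.random(n),
                             "left" if r.random() < 0.5 else "right")
        curve = proximity_curve(tr)
        assert np.all(curve.proximity >= 0.0)
        assert np.all(curve.proximity <= 1.0)
        assert np.isclose(curve.proximity.min(), 0.0) or curve.degenerate


class TestRunningTtest:
    def test_identical_conditions_nothing_significant(self, rng):
        a = rng.random((10, 101))
        t, p, runs = running_ttest(a, a.copy())
        assert runs == []
        assert (p == 1.0).all()

    def test_constant_offset_everything_significant(self, rng):
        a = rng.random((12, 101))
        b = a + 0.5
        t, p, runs = running_ttest(a, b, alpha=0.01)
        assert len(runs) == 1
        assert runs[0].start == 0 and runs[0].end == 100
        assert runs[0].t_start == 0.0 and runs[0].t_end == 1.0

    def test_zero_variance_nonzero_constant_is_certain(self, rng):
        a = rng.integers(0, 16, (8, 5)) / 16.0  # dyadic: +1.0 stays exact
        b = a.copy()
        b[:, 2] += 1.0  # exactly constant nonzero difference
        with pytest.warns(UserWarning, match="constant"):
            t, p, runs = running_ttest(a, b)
        assert p[2] == 0.0
        assert [(r.start, r.end) for r in runs] == [(2, 2)]

    def test_min_run_filters_short_runs(self, rng):
        a = rng.standard_normal((20, 50))
        b = a.copy()
        b[:, 10] += 10.0
        b[:, 30:35] += 10.0
        _, _, runs = running_ttest(a, b, min_run=3)
        assert [(r.start, r.end) for r in runs] == [(30, 34)]

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            running_ttest(rng.random((2, 10)), rng.random((2, 10)))

    def test_null_rejection_rate_is_nominal(self):
        """Type-I error at each sample stays at alpha under the null."""
        r = np.random.default_rng(2024)
        n_sims, n_subj, T = 400, 29, 101
        hits = 0
        for _ in range(n_sims):
            a = r.standard_normal((n_subj, T))
            b = r.standard_normal((n_subj, T))
            _, p, _ = running_ttest(a, b, alpha=0.01)
            hits += int((p < 0.01).sum())
        rate = hits / (n_sims * T)
        assert rate == pytest.approx(0.01, abs=0.003)
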