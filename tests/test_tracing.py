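"""Prediction-correction tracing, refinement and bundle diagnostics."""

import numpy as np
import pytest

import wormtrace as wt
from wormtrace import tracing
from wormtrace._geometry import chord_step_polyline, min_distance_to_polyline
from wormtrace.tracing import _prune_acute


def seeds_for(line, l0=3.5):
    direction = (line[-1] - line[0]) / np.linalg.norm(line[-1] - line[0])
    return np.vstack([line[0], line[0] + l0 * direction])


class TestInterpolateHeight:
    def test_exact_at_pixel_centers(self, rng):
        heights = rng.random((12, 15))
        image = wt.HeightImage(heights=heights, pixel_size=2.0)
        pts = np.array([[4.0, 6.0], [0.0, 0.0], [28.0, 22.0]])
        vals = tracing.interpolate_height(image, pts)
        assert vals[0] == heights[3, 2]
        assert vals[1] == heights[0, 0]
        assert vals[2] == heights[11, 14]

    def test_center_of_pixel_block_is_mean(self):
        heights = np.array([[1.0, 3.0], [5.0, 7.0]])
        image = wt.HeightImage(heights=heights, pixel_size=2.0)
        assert tracing.interpolate_height(image, np.array([[1.0, 1.0]]))[0] == 4.0

    def test_reproduces_affine_ramp_exactly(self, rng):
        ps = 1.5
        cols, rows = np.meshgrid(np.arange(20), np.arange(18))
        heights = 0.3 * cols * ps - 0.7 * rows * ps + 2.0
        image = wt.HeightImage(heights=heights, pixel_size=ps)
        pts = rng.uniform(1.0, 20.0, (50, 2))
        expected = 0.3 * pts[:, 0] - 0.7 * pts[:, 1] + 2.0
        np.testing.assert_allclose(tracing.interpolate_height(image, pts), expected, atol=1e-12)

    def test_outside_grid_rejected(self):
        image = wt.HeightImage(heights=np.zeros((5, 5)), pixel_size=1.0)
        with pytest.raises(ValueError):
            tracing.interpolate_height(image, np.array([[10.0, 1.0]]))


class TestCorrectionDirection:
    def test_symmetric_ridge_gives_no_lateral_correction(self):
        # centerline on a pixel row so the sampled ridge is exactly symmetric
        line = np.array([[15.0, 39.0], [185.0, 39.0]])
        image = wt.render_image(line, wt.RenderParams(), pixel_size=1.95)
        origin = np.array([50.0, 39.0])
        predicted = np.array([53.5, 39.0])
        x_vec, truncated = tracing.correction_direction(image, origin, predicted)
        assert not truncated
        assert abs(x_vec[1]) / abs(x_vec[0]) < 1e-9  # parallel to the ridge axis

    def test_offset_ridge_recovered_within_fifth_of_pixel(self, straight_ridge):
        image, _ = straight_ridge
        delta = 1.95  # start one pixel off the centerline
        prev = np.array([50.0, 40.0 + delta])
        pred = prev + np.array([3.5, 0.0])
        for _ in range(3):
            x_vec, _ = tracing.correction_direction(image, prev, pred)
            pred = prev + 3.5 * x_vec / np.linalg.norm(x_vec)
        assert abs(pred[1] - 40.0) < 0.2 * 1.95

    def test_midpoint_rule_matches_fine_riemann_sum(self, straight_ridge):
        image, _ = straight_ridge
        origin = np.array([60.0, 41.0])
        predicted = np.array([63.5, 40.5])
        coarse, _ = tracing.correction_direction(image, origin, predicted)
        fine, _ = tracing.correction_direction(
            image, origin, predicted, quad_step=image.pixel_size / 40.0
        )
        assert np.linalg.norm(coarse - fine) / np.linalg.norm(fine) < 1e-3


class TestTraceMolecule:
    def test_straight_ridge_recovered(self, straight_ridge):
        image, line = straight_ridge
        trace = tracing.trace_molecule(image, seeds_for(line), 3.5)
        chords = np.hypot(*np.diff(trace.vertices, axis=0).T)
        np.testing.assert_allclose(chords, 3.5, rtol=1e-9)
        lateral = np.abs(trace.vertices[:, 1] - 40.0)
        assert lateral.max() < 0.1 * image.pixel_size
        d = np.diff(trace.vertices, axis=0)
        angles = np.abs(np.diff(np.arctan2(d[:, 1], d[:, 0])))
        assert np.rad2deg(angles.max()) < 0.5
        assert trace.n_links * 3.5 == pytest.approx(170.0, rel=0.01)

    def test_arc_turning_angle(self, arc_ridge):
        image, arc, radius, center = arc_ridge
        trace = tracing.trace_molecule(image, np.vstack([arc[0], arc[10]]), 3.5)
        d = np.diff(trace.vertices, axis=0)
        u = d / np.hypot(d[:, 0], d[:, 1])[:, None]
        turn = np.arccos(np.clip((u[:-1] * u[1:]).sum(axis=1), -1, 1))
        expected = 2 * np.arcsin(3.5 / (2 * radius))
        assert turn.mean() == pytest.approx(expected, rel=0.10)

    def test_opposite_direction_retraces_same_centerline(self, arc_ridge):
        image, arc, _, _ = arc_ridge
        fwd = tracing.trace_molecule(image, np.vstack([arc[0], arc[10]]), 3.5)
        rev = tracing.trace_molecule(image, np.vstack([arc[-1], arc[-11]]), 3.5)
        dev = min_distance_to_polyline(rev.vertices[1:-1], fwd.vertices)
        assert dev.max() < image.pixel_size

    def test_reflection_equivariance(self, straight_ridge):
        # swapping x and y axes transforms the trace identically (grid-exact)
        image, line = straight_ridge
        swapped = wt.HeightImage(heights=image.heights.T.copy(), pixel_size=image.pixel_size)
        t1 = tracing.trace_molecule(image, seeds_for(line), 3.5)
        t2 = tracing.trace_molecule(swapped, seeds_for(line[:, ::-1]), 3.5)
        np.testing.assert_allclose(t1.vertices, t2.vertices[:, ::-1], atol=1e-9)

    def test_bad_seed_shape_rejected(self, straight_ridge):
        image, _ = straight_ridge
        with pytest.raises(ValueError):
            tracing.trace_molecule(image, np.zeros((3, 2)), 3.5)


class TestRefineTrace:
    def test_near_idempotent_on_centerline(self, straight_ridge):
        image, line = straight_ridge
        trace = tracing.trace_molecule(image, seeds_for(line), 3.5)
        refined = tracing.refine_trace(image, trace)
        lateral = np.abs(refined.vertices[:, 1] - 40.0)
        assert lateral.max() < 0.05 * image.pixel_size
        chords = np.hypot(*np.diff(refined.vertices, axis=0).T)
        np.testing.assert_allclose(chords, 3.5, rtol=1e-9)

    def test_acute_vertex_pruned(self):
        # zig-zag with a 60-degree interior angle: turning = 120 deg > 90
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [6.0, 3.46], [8.0, 0.0], [12.0, 0.0]])
        pruned = _prune_acute(pts)
        assert len(pruned) == 4
        assert not any(np.allclose(p, [6.0, 3.46]) for p in pruned)

    def test_prune_keeps_gentle_bends(self):
        t = np.linspace(0, np.pi / 2, 30)
        pts = 50.0 * np.column_stack([np.cos(t), np.sin(t)])
        assert len(_prune_acute(pts)) == len(pts)

    def test_pulls_perturbed_trace_back_to_ridge(self, straight_ridge):
        image, line = straight_ridge
        trace = tracing.trace_molecule(image, seeds_for(line), 3.5)
        wobble = 1.5 * np.sin(np.arange(len(trace.vertices)) * 0.7)
        perturbed = tracing.Trace(
            vertices=trace.vertices + np.column_stack([np.zeros_like(wobble), wobble]),
            l0=3.5,
        )
        refined = tracing.refine_trace(image, perturbed)
        lateral = np.abs(refined.vertices[:, 1] - 40.0)
        assert lateral.max() < 0.1 * image.pixel_size

    def test_degenerate_trace_rejected(self, straight_ridge):
        image, _ = straight_ridge
        stub = tracing.Trace(vertices=np.array([[20.0, 40.0], [23.5, 40.0]]), l0=3.5)
        with pytest.raises(ValueError):
            tracing.refine_trace(image, stub)


class TestBundleSpread:
    def test_identical_traces_zero_spread(self, straight_ridge):
        image, line = straight_ridge
        trace = tracing.trace_molecule(image, seeds_for(line), 3.5)
        bundle = tracing.Bundle([trace, tracing.Trace(trace.vertices.copy(), 3.5)])
        spread = tracing.bundle_spread(bundle)
        assert spread.max_pairwise_nm.max() < 1e-9

    def test_parallel_offset_traces(self):
        a = np.column_stack([np.arange(30) * 3.5, np.zeros(30)])
        b = a + [0.0, 1.0]
        bundle = tracing.Bundle([tracing.Trace(a, 3.5), tracing.Trace(b, 3.5)])
        spread = tracing.bundle_spread(bundle)
        interior = spread.iloc[1:-1]
        np.testing.assert_allclose(interior.max_pairwise_nm, 1.0, atol=1e-9)

    def test_refinement_shrinks_perturbed_bundle(self):
        # a wiggly molecule; the bundle emulates divergent repeat traces
        rng = np.random.default_rng(42)
        cfg = wt.FixtureConfig(
            n_molecules=1, n_beads=900, lb=56.0, pixel_size=1.95,
            render=wt.RenderParams(noise_sigma=0.1),
        )
        fx = wt.make_fixture_set(cfg, rng)[0]
        base = tracing.trace_molecule(
            fx.image, np.vstack([fx.centerline[0], fx.centerline[10]]), 3.5
        )
        n = len(base.vertices)
        s = np.arange(n)
        perturbed, refined = [], []
        for _ in range(30):
            amp = rng.uniform(0.5, 2.0, 2)
            phase = rng.uniform(0, 2 * np.pi, 2)
            wob = amp[0] * np.sin(2 * np.pi * s / 25 + phase[0]) + amp[1] * np.sin(
                2 * np.pi * s / 11 + phase[1]
            )
            d = np.diff(base.vertices, axis=0)
            normal = np.vstack([[-d[0, 1], d[0, 0]], np.column_stack([-d[:, 1], d[:, 0]])])
            normal /= np.hypot(normal[:, 0], normal[:, 1])[:, None]
            tr = tracing.Trace(base.vertices + wob[:, None] * normal, 3.5, image_ref="m")
            perturbed.append(tr)
            refined.append(tracing.refine_trace(fx.image, tr))
        before = tracing.bundle_spread(tracing.Bundle(perturbed))
        after = tracing.bundle_spread(tracing.Bundle(refined))
        assert after.lateral_std_nm.mean() < before.lateral_std_nm.mean()
        assert (after.max_pairwise_nm < fx.image.pixel_size).mean() >= 0.90

    def test_single_trace_rejected(self, straight_ridge):
        image, line = straight_ridge
        trace = tracing.trace_molecule(image, seeds_for(line), 3.5)
        with pytest.raises(ValueError):
            tracing.Bundle([trace])


class TestChordStepping:
    def test_exact_chords_on_wavy_polyline(self, rng):
        x = np.linspace(0, 100, 500)
        pts = np.column_stack([x, 3.0 * np.sin(x / 5.0)])
        stepped = chord_step_polyline(pts, 4.0)
        chords = np.hypot(*np.diff(stepped, axis=0).T)
        np.testing.assert_allclose(chords, 4.0, rtol=1e-9)
        # every produced vertex lies on the source polyline
        assert min_distance_to_polyline(stepped, pts).max() < 1e-9
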