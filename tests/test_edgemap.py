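"""Edge windowing, velocity/activity maps, and NaN-aware smoothing."""

import numpy as np
import pytest
from scipy import signal

from conftest import circle_mask, make_activity_map
from edgepulse import edgemap
from edgepulse.movie import Calibration, RatioMovie

CAL = Calibration(0.33, 25.0)


def circle(radius_um=30.0, center=(110, 110), shape=(220, 220)):
    return circle_mask(shape, center, radius_um / CAL.um_per_px)


class TestWindows:
    def test_window_counts_fixed(self):
        fw = edgemap.make_windows(circle(), CAL)
        assert fw.points.shape == (900, 2)
        assert fw.window_centers.shape == (180, 2)

    def test_circle_arc_lengths_match_closed_form(self):
        fw = edgemap.make_windows(circle(30.0), CAL)
        arcs = fw.arc_lengths_px * CAL.um_per_px
        expected = 2 * np.pi * 30.0 / 900
        assert np.all(np.abs(arcs - expected) / expected < 0.01)

    def test_arc_lengths_sum_to_perimeter(self):
        fw = edgemap.make_windows(circle(), CAL)
        assert fw.arc_lengths_px.sum() == pytest.approx(
            fw.perimeter_px, rel=0.005
        )

    def test_circle_normals_radial(self):
        fw = edgemap.make_windows(circle(), CAL)
        radial = fw.points - np.array([110.0, 110.0])
        radial /= np.linalg.norm(radial, axis=1)[:, None]
        cosang = np.sum(fw.normals * radial, axis=1)
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))).max() < 1.0

    def test_holes_filled_before_tracing(self):
        holed = circle().copy()
        holed[100:120, 100:120] = False
        fw = edgemap.make_windows(holed, CAL)
        full = edgemap.make_windows(circle(), CAL)
        assert np.allclose(fw.points, full.points, atol=0.5)

    def test_multiple_components_rejected(self):
        two = circle(15.0, center=(70, 70)) | circle(15.0, center=(150, 150))
        with pytest.raises(ValueError, match="component"):
            edgemap.make_windows(two, CAL)

    def test_border_touching_rejected(self):
        mask = np.zeros((50, 50), bool)
        mask[0:20, 10:30] = True
        with pytest.raises(ValueError, match="border"):
            edgemap.make_windows(mask, CAL)

    def test_depth_bands_nested_and_shallow(self):
        fw = edgemap.make_windows(circle(), CAL, depths_um=(2.0, 6.5))
        n2 = fw.depth_pixels[2.0][0].size
        n65 = fw.depth_pixels[6.5][0].size
        assert 0 < n2 < n65
        # every 2.0-um pixel also appears at 6.5 um
        s2 = set(zip(*fw.depth_pixels[2.0][:2]))
        s65 = set(zip(*fw.depth_pixels[6.5][:2]))
        assert s2 <= s65


class TestVelocityMap:
    def test_static_sequence_zero_velocity(self):
        grid = edgemap.make_grid([circle()] * 4, CAL, (2.0,))
        vel = edgemap.edge_velocity_map(grid)
        assert np.nanmax(np.abs(vel.values[:, :-1])) < 0.2
        assert np.isnan(vel.values[:, -1]).all()

    def test_uniform_expansion_measured_everywhere(self):
        # analytic radii rasterized: 3 um/min uniform outward motion
        masks = [circle(20.0 + 3.0 * (t * 25 / 60)) for t in range(8)]
        grid = edgemap.make_grid(masks, CAL, (2.0,))
        vel = edgemap.smooth_map(edgemap.edge_velocity_map(grid))
        vals = vel.values[:, :-2]
        assert np.all(np.abs(vals - 3.0) < 0.3)

    def test_single_protrusion_peak_at_ground_truth(self):
        from edgepulse.synthetic import (
            BoundaryParams, CouplingParams, render_timelapse,
            simulate_activity_coupling, simulate_boundary_series,
        )

        params = BoundaryParams(base_radius=40.0, n_events=1,
                                event_amplitude=13.5, event_times=250.0,
                                event_angles=2.0, n_frames=25, seed=0)
        boundary = simulate_boundary_series(params)
        coupling = CouplingParams(noise_sd=0.0)
        fields = simulate_activity_coupling(boundary, coupling)
        rendered = render_timelapse(boundary, fields, coupling)
        grid = edgemap.make_grid(rendered.masks, rendered.movie.calibration,
                                 (2.0,))
        vel = edgemap.edge_velocity_map(grid)
        true = boundary.true_velocity_map()
        w_m, t_m = np.unravel_index(np.nanargmax(vel.values[:, :-1]),
                                    vel.values[:, :-1].shape)
        w_t, t_t = np.unravel_index(np.nanargmax(true[:, :-1]),
                                    true[:, :-1].shape)
        dw = min(abs(w_m - w_t), 180 - abs(w_m - w_t))
        assert dw <= 2 and abs(t_m - t_t) <= 1

    def test_area_consistency(self):
        # integral of velocity x arc length tracks dA/dt within 10%
        masks = [circle(20.0 + 3.0 * (t * 25 / 60)) for t in range(6)]
        grid = edgemap.make_grid(masks, CAL, (2.0,))
        vel = edgemap.edge_velocity_map(grid)
        areas = [m.sum() * CAL.um_per_px**2 for m in masks]
        dadt = np.diff(areas) / (25 / 60)
        for t in range(5):
            arcs = grid.frames[t].arc_lengths_px * CAL.um_per_px
            integral = float(np.sum(np.repeat(vel.values[:, t], 5) * arcs))
            assert integral == pytest.approx(dadt[t], rel=0.10)


class TestActivityMap:
    def test_constant_ratio_sampled_everywhere(self):
        masks = np.stack([circle()] * 3)
        ratio = RatioMovie(np.full(masks.shape, 2.0), masks.copy(), CAL)
        grid = edgemap.make_grid(masks, CAL, (0.98, 2.0, 6.5))
        for depth in (0.98, 2.0, 6.5):
            amap = edgemap.activity_map(grid, ratio, depth)
            assert np.allclose(amap.values, 2.0)

    def test_unknown_depth_rejected(self):
        masks = np.stack([circle()] * 2)
        ratio = RatioMovie(np.ones(masks.shape), masks.copy(), CAL)
        grid = edgemap.make_grid(masks, CAL, (2.0,))
        with pytest.raises(ValueError, match="depth"):
            edgemap.activity_map(grid, ratio, 3.3)

    def test_generator_activity_recovered_at_window_centers(self, noiseless_sim):
        rendered, boundary, fields, coupling = noiseless_sim
        from edgepulse.preprocess import (
            build_background_model, compute_ratio, subtract_background,
        )

        model = build_background_model(
            {c: [rendered.blank[c]] for c in rendered.movie.channels}
        )
        sub = subtract_background(rendered.movie, model)
        ratio = compute_ratio(sub, "FRET", "CFP", rendered.masks)
        grid = edgemap.make_grid(rendered.masks, rendered.movie.calibration,
                                 (2.0,))
        amap = edgemap.activity_map(grid, ratio, 2.0)
        cy, cx = rendered.center_px
        rate = 1 / 3000 - 1 / 6000
        checked = 0
        for t in (10, 30, 50):
            bleach = np.exp(-t * 25.0 * rate)
            for w in range(0, 180, 9):
                c = grid.frames[t].window_centers[w]
                phi = np.arctan2(c[0] - cy, c[1] - cx) % (2 * np.pi)
                expected = fields.activity_at(phi, t) * bleach
                measured = amap.values[w, t]
                assert measured == pytest.approx(expected, rel=0.05)
                checked += 1
        assert checked == 60

    def test_nm2_field_lags_velocity_by_configured_delay(self):
        from edgepulse.synthetic import (
            BoundaryParams, CouplingParams, RenderOptics, render_timelapse,
            simulate_activity_coupling, simulate_boundary_series,
        )

        params = BoundaryParams(base_radius=40.0, n_events=1,
                                event_amplitude=-13.5, event_times=300.0,
                                event_angles=1.0, n_frames=40, seed=0)
        coupling = CouplingParams(noise_sd=0.0, nm2_delay=150.0,
                                  bleach_tau_num=1e12, bleach_tau_den=1e12)
        boundary = simulate_boundary_series(params)
        fields = simulate_activity_coupling(boundary, coupling)
        rendered = render_timelapse(boundary, fields, coupling,
                                    RenderOptics(include_nm2=True))
        ratio_vals = np.where(
            rendered.masks,
            rendered.movie["NM2"] / np.maximum(rendered.movie["CFP"], 1e-6),
            np.nan,
        )
        ratio = RatioMovie(ratio_vals, rendered.masks.copy(),
                           rendered.movie.calibration)
        grid = edgemap.make_grid(rendered.masks, rendered.movie.calibration,
                                 (2.0, 6.5))
        vel = edgemap.edge_velocity_map(grid)
        nm2 = edgemap.activity_map(grid, ratio, 6.5)
        w = int(np.unravel_index(np.nanargmin(vel.values[:, :-1]),
                                 vel.values[:, :-1].shape)[0])
        t_vmin = int(np.nanargmin(vel.values[w, :-1]))
        t_nm2 = int(np.nanargmax(nm2.values[w]))
        # velocity min (map column t = t -> t+1 motion) vs NM2 peak:
        # activity lag (2 frames) + NM2 delay (6 frames), one-frame tolerance
        expected_lag = (coupling.activity_lag + coupling.nm2_delay) / 25.0
        assert abs((t_nm2 - t_vmin) - expected_lag) <= 1.5


class TestSmoothMap:
    def test_constant_map_imputes_missing(self):
        vals = np.full((180, 20), 4.0)
        vals[50, 10] = np.nan
        sm = edgemap.smooth_map(make_activity_map(vals))
        assert np.allclose(sm.values, 4.0)

    def test_interior_spike_mass_conserved(self):
        vals = np.zeros((180, 20))
        vals[90, 10] = 9.0
        sm = edgemap.smooth_map(make_activity_map(vals))
        assert sm.values.sum() == pytest.approx(9.0)
        assert sm.values[90, 10] == pytest.approx(1.0)

    def test_circular_wrap_on_window_axis(self):
        vals = np.zeros((180, 20))
        vals[0, 10] = 9.0
        sm = edgemap.smooth_map(make_activity_map(vals))
        assert sm.values[179, 10] == pytest.approx(1.0)
        assert sm.values[1, 10] == pytest.approx(1.0)

    def test_double_smoothing_equals_self_convolved_kernel(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(180, 40))
        twice = edgemap.smooth_map(
            edgemap.smooth_map(make_activity_map(vals))
        ).values
        k = np.ones((3, 3)) / 9.0
        kk = signal.convolve2d(k, k)  # 5x5 triangular kernel
        wrapped = np.concatenate([vals[-2:], vals, vals[:2]], axis=0)
        direct = signal.convolve2d(wrapped, kk, mode="same")[2:-2]
        interior = (slice(None), slice(4, 36))  # away from time edges
        assert np.allclose(twice[interior], direct[interior])
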