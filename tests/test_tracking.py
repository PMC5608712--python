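"""RF simulation and block-matching displacement estimation."""

import numpy as np
import pytest

from vasoelast.phantom import ScattererSet
from vasoelast.rf import FrameGeometry, RFFrame, simulate_rf
from vasoelast.tracking import (
    DisplacementGrid,
    TrackingConfig,
    TrackingError,
    block_match,
    grid_to_nodes,
    kernel_grid,
)


class TestSimulateRF:
    def test_single_scatterer_peak_at_position(self):
        geom = FrameGeometry.covering((-100, 100), (-100, 100))
        sc = ScattererSet(np.array([[0.0, 0.0]]), np.array([1.0]))
        frame = simulate_rf(sc, geom)
        iz, ix = np.unravel_index(np.abs(frame.samples).argmax(), frame.samples.shape)
        assert abs(geom.axial_positions_um[iz]) <= geom.axial_step_um
        assert abs(geom.lateral_positions_um[ix]) <= geom.beam_pitch_um

    def test_empty_scatterers_zero_frame_with_warning(self):
        geom = FrameGeometry.covering((-50, 50), (-50, 50))
        sc = ScattererSet(np.empty((0, 2)), np.empty(0))
        with pytest.warns(UserWarning):
            frame = simulate_rf(sc, geom)
        assert np.all(frame.samples == 0)

    def test_integer_sample_shift_is_discrete_delay(self, speckle_frames):
        geom, pos, amp = (speckle_frames[k] for k in ("geom", "pos", "amp"))
        dz = geom.axial_step_um
        pre = speckle_frames["pre"]
        shifted = simulate_rf(ScattererSet(pos + [3 * dz * 1e-3, 0.0], amp), geom)
        # interior rows clear of the window truncation at the frame edge
        guard = 30
        np.testing.assert_allclose(
            shifted.samples[3 + guard : -guard],
            pre.samples[guard : -guard - 3],
            atol=1e-9,
        )

    def test_sampling_invariant_enforced(self):
        with pytest.raises(ValueError):
            FrameGeometry(0, 0, 10, 10, sampling_hz=100e6, center_freq_hz=40e6)


class TestKernelGrid:
    def test_default_station_spacing(self):
        geom = FrameGeometry.covering((0, 1000), (0, 1000))
        cfg = TrackingConfig()
        za, xa = kernel_grid(cfg, geom)
        assert za[1] - za[0] == pytest.approx(20.0)
        assert xa[1] - xa[0] == pytest.approx(5.08)
        assert za.size == 46  # floor((1000 - 100)/20) + 1

    def test_zero_overlap_step_equals_kernel(self):
        geom = FrameGeometry.covering((0, 1000), (0, 1000))
        cfg = TrackingConfig(overlap_fraction=0.0)
        za, xa = kernel_grid(cfg, geom)
        assert za[1] - za[0] == pytest.approx(cfg.kernel_axial_um)
        assert xa[1] - xa[0] == pytest.approx(cfg.kernel_lateral_um)

    def test_frame_smaller_than_kernel_rejected(self):
        geom = FrameGeometry.covering((0, 50), (0, 50))
        with pytest.raises(TrackingError):
            kernel_grid(TrackingConfig(), geom)


class TestBlockMatch:
    def test_identical_frames_zero_displacement_unit_correlation(self, speckle_frames):
        pre = speckle_frames["pre"]
        grid = block_match(pre, pre, TrackingConfig())
        ok = np.isfinite(grid.correlation)
        assert np.all(grid.u_axial_um[ok] == 0)
        assert np.all(grid.u_lateral_um[ok] == 0)
        assert np.all(grid.correlation[ok] == pytest.approx(1.0, abs=1e-9))

    def test_integer_shift_recovered_exactly(self, speckle_frames):
        pre, post = speckle_frames["pre"], speckle_frames["post_int"]
        dz = speckle_frames["geom"].axial_step_um
        grid = block_match(pre, post, TrackingConfig())
        interior = np.zeros_like(grid.correlation, bool)
        interior[2:-2, 5:-5] = True
        sel = interior & np.isfinite(grid.correlation)
        assert sel.sum() > 100
        np.testing.assert_allclose(grid.u_axial_um[sel], 2 * dz, atol=1e-9)
        np.testing.assert_allclose(grid.u_lateral_um[sel], 0.0, atol=1e-9)

    def test_quarter_sample_subpixel_recovery(self, speckle_frames):
        pre, post = speckle_frames["pre"], speckle_frames["post_sub"]
        dz = speckle_frames["geom"].axial_step_um
        grid = block_match(pre, post, TrackingConfig())
        interior = np.zeros_like(grid.correlation, bool)
        interior[2:-2, 5:-5] = True
        est = grid.u_axial_um[interior & np.isfinite(grid.correlation)] / dz
        assert est.mean() == pytest.approx(0.25, abs=0.05)
        assert est.std() < 0.05

    def test_flat_frames_all_invalid(self):
        geom = FrameGeometry.covering((0, 300), (0, 300))
        flat = RFFrame(np.zeros((geom.n_axial, geom.n_lateral)), geom)
        grid = block_match(flat, flat, TrackingConfig())
        assert np.all(np.isnan(grid.correlation))
        assert np.all(np.isnan(grid.u_axial_um))

    def test_translation_equivariance(self, speckle_frames):
        """Rolling both frames by the same offset leaves interior estimates unchanged."""
        geom = speckle_frames["geom"]
        pre, post = speckle_frames["pre"], speckle_frames["post_int"]
        g0 = block_match(pre, post, TrackingConfig())
        roll = 13
        pre_r = RFFrame(np.roll(pre.samples, roll, axis=0), geom)
        post_r = RFFrame(np.roll(post.samples, roll, axis=0), geom)
        g1 = block_match(pre_r, post_r, TrackingConfig())
        # stations offset by exactly roll * dz / station_step — compare the
        # overlap where both grids see purely interior data
        step = 20.0  # um (defaults)
        k = int(round(roll * geom.axial_step_um / step))
        a0 = g0.u_axial_um[5:-8, 5:-5]
        a1 = g1.u_axial_um[5 + k : a0.shape[0] + 5 + k, 5:-5]
        ok = np.isfinite(a0) & np.isfinite(a1)
        assert ok.mean() > 0.8
        np.testing.assert_allclose(a0[ok], a1[ok], atol=0.5)

    def test_correlation_bounded(self, speckle_frames):
        grid = block_match(
            speckle_frames["pre"], speckle_frames["post_sub"], TrackingConfig()
        )
        finite = grid.correlation[np.isfinite(grid.correlation)]
        assert finite.max() <= 1 + 1e-9
        assert finite.min() >= -1 - 1e-9


class TestGridToNodes:
    def _grid(self, fz, fx):
        za = np.arange(-400.0, 401.0, 20.0)
        xa = np.arange(-400.0, 401.0, 10.0)
        ZZ, XX = np.meshgrid(za, xa, indexing="ij")
        return DisplacementGrid(
            axial_stations_um=za,
            lateral_stations_um=xa,
            u_axial_um=fz(ZZ, XX),
            u_lateral_um=fx(ZZ, XX),
            correlation=np.ones_like(ZZ),
        )

    def test_constant_field_interpolates_constant(self, homog_phantom):
        _, mesh, _ = homog_phantom
        grid = self._grid(lambda z, x: np.full_like(z, 3.0), lambda z, x: np.full_like(z, -1.0))
        field = grid_to_nodes(grid, mesh)
        np.testing.assert_allclose(field.values[:, 0], 3.0e-3, atol=1e-12)
        np.testing.assert_allclose(field.values[:, 1], -1.0e-3, atol=1e-12)
        assert field.provenance == "measured"

    def test_bilinear_reproduces_linear_fields_exactly(self, homog_phantom):
        _, mesh, _ = homog_phantom
        grid = self._grid(lambda z, x: 0.01 * x + 0.02 * z, lambda z, x: 0.03 * z)
        field = grid_to_nodes(grid, mesh)
        pts = mesh.nodes * 1e3
        expected_ax = (0.01 * pts[:, 1] + 0.02 * pts[:, 0]) * 1e-3
        np.testing.assert_allclose(field.values[:, 0], expected_ax, atol=1e-10)

    def test_all_below_threshold_raises(self, homog_phantom):
        _, mesh, _ = homog_phantom
        grid = self._grid(lambda z, x: np.zeros_like(z), lambda z, x: np.zeros_like(z))
        grid.correlation[:] = 0.1
        with pytest.raises(TrackingError):
            grid_to_nodes(grid, mesh, min_correlation=0.75)
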