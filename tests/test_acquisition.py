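import math

import numpy as np
import pytest
from scipy import integrate

from lightsweep.acquisition import (
    CameraModel,
    FrameStack,
    ImagingGrid,
    OpticsModel,
    ScanWaveform,
    StaticField,
    acquire_single_plane,
    acquire_structural_stack,
    acquire_volume_scan,
    render_subframe,
    support_width,
    time_averaged_excitation,
    z_position,
)
from lightsweep.errors import ConfigError
from lightsweep.phantom import Box, DendritePhantom, FluorescenceField

from conftest import make_sweep


def small_grid(bounds, optics, shape=(40, 40), dz=0.5):
    return ImagingGrid.from_bounds(bounds, optics, shape, dz=dz)


class TestScanWaveform:
    def test_zero_amplitude_is_constant(self):
        wf = ScanWaveform(frequency=50.0, amplitude=0.0, center_z=3.0)
        t = np.linspace(0, 0.1, 50)
        np.testing.assert_array_equal(z_position(wf, t), np.full(50, 3.0))

    def test_quarter_period_reaches_amplitude(self):
        wf = ScanWaveform(frequency=50.0, amplitude=10.0, center_z=2.0)
        assert z_position(wf, 0.005) == pytest.approx(12.0)

    def test_one_full_scan_per_20ms_period(self):
        # 50 Hz: one complete traverse of the Z axis in exactly 20 ms
        wf = ScanWaveform(frequency=50.0, amplitude=10.0)
        assert wf.period == pytest.approx(0.020)
        t = np.linspace(0.0, 0.020, 2001)
        z = z_position(wf, t)
        assert z.min() == pytest.approx(-10.0, abs=1e-6)
        assert z.max() == pytest.approx(10.0, abs=1e-6)
        assert z_position(wf, 0.020) == pytest.approx(z_position(wf, 0.0))

    def test_lag_shifts_phase(self):
        wf = ScanWaveform(frequency=50.0, amplitude=10.0)
        lagged = wf.with_lag(0.002)
        assert lagged.phase == pytest.approx(-2.0 * np.pi * 50.0 * 0.002)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            ScanWaveform(frequency=0.0, amplitude=1.0)
        with pytest.raises(ConfigError):
            ScanWaveform(frequency=50.0, amplitude=-1.0)


class TestRenderSubframe:
    def test_zero_field_renders_zero(self, small_optics):
        bounds = Box(lo=(-5, -5, -5), hi=(5, 5, 5))
        field = StaticField(lambda x, y, z: np.zeros_like(x), bounds)
        grid = small_grid(bounds, small_optics, shape=(16, 16))
        img = render_subframe(field, small_optics, 0.0, 0.0, grid)
        assert np.all(img == 0.0)

    def test_defocus_dims_point_emitter(self, small_optics):
        bounds = Box(lo=(-5, -5, -8), hi=(5, 5, 8))
        sig = 0.3
        field = StaticField(
            lambda x, y, z: np.exp(-(x**2 + y**2 + z**2) / (2 * sig**2)), bounds
        )
        grid = small_grid(bounds, small_optics, shape=(24, 24), dz=0.25)
        in_focus = render_subframe(field, small_optics, 0.0, 0.0, grid)
        off = 2.0 * small_optics.sheet_thickness_sigma
        defocused = render_subframe(field, small_optics, off, off, grid)
        assert in_focus.max() > defocused.max()

    def test_uniform_slab_matches_1d_quadrature(self, small_optics):
        # pixel value should equal the independent 1D integral of exc*det
        bounds = Box(lo=(-6, -6, -12), hi=(6, 6, 12))
        field = StaticField(lambda x, y, z: np.ones_like(x), bounds)
        grid = small_grid(bounds, small_optics, shape=(16, 16), dz=0.25)
        sheet_z, focus_z = 1.0, 1.5
        img = render_subframe(field, small_optics, sheet_z, focus_z, grid)
        ss, sd = small_optics.sheet_thickness_sigma, small_optics.dof_sigma
        oracle, _ = integrate.quad(
            lambda z: math.exp(-0.5 * ((z - sheet_z) / ss) ** 2)
            * math.exp(-0.5 * ((z - focus_z) / sd) ** 2),
            grid.z[0] - grid.dz / 2, grid.z[-1] + grid.dz / 2,
        )
        center = img[8, 8]
        assert center == pytest.approx(oracle, rel=1e-6)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            ImagingGrid(x=np.array([]), y=np.array([0.0]), z=np.array([0.0]),
                        pixel_size=0.5, dz=0.5)


class TestVolumeScan:
    def test_frame_is_mean_of_substep_renders(self, event_field, small_optics,
                                              small_camera, sweep_waveform):
        grid = small_grid(event_field.bounds, small_optics)
        stack = acquire_volume_scan(
            event_field, sweep_waveform, sweep_waveform, small_optics,
            small_camera, duration=0.04, grid=grid,
        )
        k = small_camera.substeps_per_exposure
        exposure = small_camera.exposure_s
        for i in range(stack.n_frames):
            times = (i + (np.arange(k) + 0.5) / k) * exposure
            oracle = np.mean([
                render_subframe(
                    event_field, small_optics,
                    sweep_waveform.z_position(t), sweep_waveform.z_position(t),
                    grid, t=t,
                )
                for t in times
            ], axis=0)
            np.testing.assert_allclose(stack.data[i], oracle, rtol=1e-12)

    def test_zero_amplitude_degenerates_to_single_plane(
        self, event_field, small_optics, small_camera
    ):
        grid = small_grid(event_field.bounds, small_optics)
        static = ScanWaveform(frequency=50.0, amplitude=0.0, center_z=2.0)
        vol = acquire_volume_scan(event_field, static, static, small_optics,
                                  small_camera, duration=0.06, grid=grid)
        sp = acquire_single_plane(event_field, 2.0, small_optics, small_camera,
                                  duration=0.06, grid=grid)
        np.testing.assert_array_equal(vol.data, sp.data)

    def test_ten_seconds_at_20ms_gives_500_frames(self, quiet_field, small_optics,
                                                  sweep_waveform):
        camera = CameraModel(exposure_ms=20.0, frame_shape=(12, 12),
                             photon_scale=None, substeps_per_exposure=8)
        grid = small_grid(quiet_field.bounds, small_optics, shape=(12, 12), dz=1.0)
        stack = acquire_volume_scan(quiet_field, sweep_waveform, sweep_waveform,
                                    small_optics, camera, duration=10.0, grid=grid)
        assert stack.n_frames == 500
        assert stack.frame_interval_ms == pytest.approx(20.0)

    def test_exposure_must_match_period(self, quiet_field, small_optics):
        camera = CameraModel(exposure_ms=25.0, frame_shape=(12, 12),
                             photon_scale=None)
        wf = make_sweep()
        with pytest.raises(ConfigError):
            acquire_volume_scan(quiet_field, wf, wf, small_optics, camera,
                                duration=0.1)

    def test_linearity_in_field_brightness(self, flat_phantom, small_optics,
                                           small_camera, sweep_waveform):
        f1 = FluorescenceField(flat_phantom, [])
        brighter = DendritePhantom(
            centerline=flat_phantom.centerline, radius=flat_phantom.radius,
            structural_density=2 * flat_phantom.structural_density,
            indicator_baseline=2 * flat_phantom.indicator_baseline,
            bounds=flat_phantom.bounds,
        )
        f2 = FluorescenceField(brighter, [])
        grid = small_grid(flat_phantom.bounds, small_optics)
        a = acquire_volume_scan(f1, sweep_waveform, sweep_waveform, small_optics,
                                small_camera, duration=0.02, grid=grid)
        b = acquire_volume_scan(f2, sweep_waveform, sweep_waveform, small_optics,
                                small_camera, duration=0.02, grid=grid)
        np.testing.assert_allclose(b.data, 2.0 * a.data, rtol=1e-12)

    def test_noise_is_seed_reproducible(self, quiet_field, small_optics,
                                        sweep_waveform):
        camera = CameraModel(exposure_ms=20.0, frame_shape=(20, 20),
                             photon_scale=30.0, read_noise_sigma=2.0,
                             substeps_per_exposure=8)
        grid = small_grid(quiet_field.bounds, small_optics, shape=(20, 20))
        a = acquire_volume_scan(quiet_field, sweep_waveform, sweep_waveform,
                                small_optics, camera, 0.06, seed=42, grid=grid)
        b = acquire_volume_scan(quiet_field, sweep_waveform, sweep_waveform,
                                small_optics, camera, 0.06, seed=42, grid=grid)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.data.dtype == np.uint16

    def test_high_photon_scale_converges_to_noiseless(self, quiet_field,
                                                      small_optics, sweep_waveform):
        grid = small_grid(quiet_field.bounds, small_optics, shape=(20, 20))
        scale = 2e5
        noisy_cam = CameraModel(exposure_ms=20.0, frame_shape=(20, 20),
                                photon_scale=scale, read_noise_sigma=0.0,
                                substeps_per_exposure=8)
        clean_cam = CameraModel(exposure_ms=20.0, frame_shape=(20, 20),
                                photon_scale=None, substeps_per_exposure=8)
        noisy = acquire_volume_scan(quiet_field, sweep_waveform, sweep_waveform,
                                    small_optics, noisy_cam, 0.02, seed=1, grid=grid)
        clean = acquire_volume_scan(quiet_field, sweep_waveform, sweep_waveform,
                                    small_optics, clean_cam, 0.02, grid=grid)
        bright = clean.data > 0.1 * clean.data.max()
        rel = np.abs(noisy.data[bright] / scale - clean.data[bright]) / clean.data[bright]
        assert np.median(rel) < 0.01


class TestSinglePlane:
    def test_distant_dendrite_contributes_under_2pct(self, small_optics,
                                                     small_camera):
        # straight rod at z = z_off, imaged at plane 0 vs at its own depth
        z_off = 3.0 * (small_optics.sheet_thickness_sigma + small_optics.dof_sigma)
        line = np.column_stack([
            np.linspace(-8, 8, 33), np.zeros(33), np.full(33, z_off)])
        rod = DendritePhantom(
            centerline=line, radius=0.8, structural_density=8.0,
            indicator_baseline=6.0,
            bounds=Box(lo=(-12, -6, -2), hi=(12, 6, z_off + 4)),
        )
        field = FluorescenceField(rod, [])
        grid = ImagingGrid.from_bounds(rod.bounds, small_optics, (24, 48), dz=0.25)
        in_focus = acquire_single_plane(field, z_off, small_optics, small_camera,
                                        0.02, grid=grid)
        out_focus = acquire_single_plane(field, 0.0, small_optics, small_camera,
                                         0.02, grid=grid)
        assert out_focus.data.sum() < 0.02 * in_focus.data.sum()

    def test_flat_phantom_frames_identical_noiseless(self, quiet_field,
                                                     small_optics, small_camera):
        grid = small_grid(quiet_field.bounds, small_optics)
        stack = acquire_single_plane(quiet_field, 0.0, small_optics, small_camera,
                                     duration=0.08, grid=grid)
        for i in range(1, stack.n_frames):
            np.testing.assert_array_equal(stack.data[i], stack.data[0])


class TestStructuralStack:
    def test_320_steps_of_half_micron_cover_160um(self, quiet_field, small_optics):
        camera = CameraModel(exposure_ms=200.0, frame_shape=(12, 12),
                             photon_scale=None, substeps_per_exposure=8)
        grid = small_grid(quiet_field.bounds, small_optics, shape=(12, 12), dz=1.0)
        stack = acquire_structural_stack(quiet_field, -80.0, 0.5, 320,
                                         small_optics, camera, grid=grid)
        assert stack.n_frames == 320
        assert stack.metadata["depth_um"] == pytest.approx(160.0)

    def test_single_step_equals_single_plane_frame(self, event_field, small_optics,
                                                   small_camera):
        grid = small_grid(event_field.bounds, small_optics)
        st = acquire_structural_stack(event_field, 1.0, 0.5, 1, small_optics,
                                      small_camera, grid=grid, channel="structural")
        sp_frame = render_subframe(event_field, small_optics, 1.0, 1.0, grid,
                                   t=0.0, channel="structural")
        np.testing.assert_allclose(st.data[0], sp_frame, rtol=1e-12)

    def test_mip_of_tilted_rod_recovers_projected_length(self, small_optics):
        # rod tilted through Z; oracle = rasterised projection of the tube
        n = 41
        line = np.column_stack([
            np.linspace(-8, 8, n), np.zeros(n), np.linspace(-6, 6, n)])
        rod = DendritePhantom(
            centerline=line, radius=0.8, structural_density=8.0,
            indicator_baseline=6.0, bounds=Box(lo=(-12, -5, -9), hi=(12, 5, 9)),
        )
        field = FluorescenceField(rod, [])
        camera = CameraModel(exposure_ms=20.0, frame_shape=(20, 56),
                             photon_scale=None, substeps_per_exposure=8)
        grid = ImagingGrid.from_bounds(rod.bounds, small_optics, (20, 56), dz=0.25)
        stack = acquire_structural_stack(field, -7.0, 0.5, 29, small_optics,
                                         camera, grid=grid)
        mip = stack.data.max(axis=0)
        # threshold at a quarter of the plateau: a blurred tube edge crosses
        # this close to the geometric boundary
        cols = np.nonzero(mip.max(axis=0) > 0.25 * mip.max())[0]
        measured = (cols.max() - cols.min() + 1) * small_optics.pixel_size
        # geometry oracle: rasterise the projected tube (pixel centers within
        # one radius of the 2D-projected polyline) and take its column extent
        xx, yy = np.meshgrid(grid.x, grid.y)
        d2 = np.full(xx.shape, np.inf)
        for px, py, _ in line:
            d2 = np.minimum(d2, (xx - px) ** 2 + (yy - py) ** 2)
        mask_cols = np.nonzero((d2 <= rod.radius**2).any(axis=0))[0]
        oracle = (mask_cols.max() - mask_cols.min() + 1) * small_optics.pixel_size
        assert abs(measured - oracle) <= small_optics.pixel_size


class TestEffectiveSheetProfile:
    def test_time_average_symmetric_about_center(self, sweep_waveform):
        z = np.linspace(-14, 14, 561)
        prof = time_averaged_excitation(sweep_waveform, 2.0, z)
        np.testing.assert_allclose(prof, prof[::-1], rtol=1e-9)

    def test_support_is_sweep_depth_plus_sheet_thickness(self, sweep_waveform):
        z = np.arange(-16, 16.001, 0.02)
        prof = time_averaged_excitation(sweep_waveform, 2.0, z)
        width = support_width(prof, z, 0.05)
        # peak-to-peak sweep 20 µm plus O(sheet sigma) spill at each edge
        assert 20.0 <= width <= 20.0 + 6 * 2.0

    def test_phase_mismatch_monotonically_degrades_signal(self, flat_phantom,
                                                          small_optics):
        field = FluorescenceField(flat_phantom, [])
        grid = small_grid(flat_phantom.bounds, small_optics)
        # dense substeps so the sweep samples the thin phantom's plane
        camera = CameraModel(exposure_ms=20.0, frame_shape=(40, 40),
                             photon_scale=None, substeps_per_exposure=32)
        sheet = make_sweep()
        totals = []
        for dphi in np.linspace(0.0, np.pi / 2, 6):
            focus = make_sweep(phase=dphi)
            stack = acquire_volume_scan(field, sheet, focus, small_optics,
                                        camera, 0.02, grid=grid)
            totals.append(stack.data.sum())
        assert all(a > b for a, b in zip(totals, totals[1:]))


class TestFrameStackIO:
    def test_tiff_round_trip(self, tmp_path, quiet_field, small_optics,
                             sweep_waveform):
        camera = CameraModel(exposure_ms=20.0, frame_shape=(16, 16),
                             photon_scale=30.0, substeps_per_exposure=8)
        grid = small_grid(quiet_field.bounds, small_optics, shape=(16, 16))
        stack = acquire_volume_scan(quiet_field, sweep_waveform, sweep_waveform,
                                    small_optics, camera, 0.06, seed=3, grid=grid)
        path = tmp_path / "stack.tif"
        stack.save(path)
        loaded = FrameStack.load(path)
        np.testing.assert_array_equal(loaded.data, stack.data)
        assert loaded.mode == "volume_scan"
        assert loaded.frame_interval_ms == stack.frame_interval_ms
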