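import numpy as np
import pytest

from oamrecon import (GridSpec, PerturbationSpec, Phantom, assemble_ctir,
                      estimate_focus, rasterize_phantom, simulate_calibration,
                      simulate_scan, simulate_tir, stacked_sphere_experiment)
from oamrecon.metrics import mirror_asymmetry
from oamrecon.synthetic import (apply_band_filter, resample_tir_spatial,
                                sensitivity_field)


@pytest.fixture(scope="module")
def cal_grid():
    return GridSpec(nx=9, ny=9, nz=11, dz=200e-6, lateral_radius=0.08e-3)


@pytest.fixture(scope="module")
def fine_tir(geom, acfg):
    grid = GridSpec(nx=11, ny=11, nz=21, dx=10e-6, dy=10e-6, dz=100e-6,
                    lateral_radius=0.1e-3)
    return simulate_tir(geom, grid, acfg)


@pytest.fixture(scope="module")
def recon_grid():
    return GridSpec(nx=15, ny=15, nz=11, dz=200e-6, lateral_radius=0.1e-3)


class TestRasterizePhantom:
    def test_partial_volume_weights_integrate_to_sphere_volume(self):
        """Summed voxel fractions times voxel volume approximate the sphere
        volume even for sub-voxel spheres."""
        grid = GridSpec(nx=9, ny=9, nz=9, dx=20e-6, dy=20e-6, dz=20e-6,
                        lateral_radius=1.0)
        for radius in (8e-6, 12.5e-6, 30e-6):
            vol = rasterize_phantom(
                Phantom.single((3e-6, -2e-6, 5e-6), radius), grid)
            voxel = grid.dx * grid.dy * grid.dz
            sphere = 4.0 / 3.0 * np.pi * radius**3
            assert vol.values.sum() * voxel == pytest.approx(sphere, rel=0.05)

    def test_amplitude_scales_linearly(self):
        grid = GridSpec(nx=5, ny=5, nz=5, lateral_radius=1.0)
        v1 = rasterize_phantom(Phantom.single((0, 0, 0), 15e-6, 1.0), grid)
        v2 = rasterize_phantom(Phantom.single((0, 0, 0), 15e-6, 2.5), grid)
        np.testing.assert_allclose(v2.values, 2.5 * v1.values, atol=1e-15)


class TestSimulateScan:
    def test_empty_phantom_gives_zero_scan(self, fine_tir, recon_grid):
        scan, pulses = simulate_scan(Phantom(), fine_tir, recon_grid)
        assert not scan.ascans.any()
        assert np.all(pulses.energies == 1.0)

    def test_seeded_runs_bitwise_identical(self, fine_tir, recon_grid):
        ph = Phantom.single((0, 0, 0), 12.5e-6)
        s1, _ = simulate_scan(ph, fine_tir, recon_grid, noise_std=0.3, seed=5)
        s2, _ = simulate_scan(ph, fine_tir, recon_grid, noise_std=0.3, seed=5)
        np.testing.assert_array_equal(s1.ascans, s2.ascans)
        s3, _ = simulate_scan(ph, fine_tir, recon_grid, noise_std=0.3, seed=6)
        assert not np.array_equal(s1.ascans, s3.ascans)

    def test_noise_std_matches_request(self, fine_tir):
        grid = GridSpec(nx=24, ny=24, nz=11, dz=200e-6, lateral_radius=0.1e-3)
        scan, _ = simulate_scan(Phantom(), fine_tir, grid,
                                noise_std=0.25, seed=3)
        assert scan.ascans.size >= 100_000
        assert np.std(scan.ascans) == pytest.approx(0.25, rel=0.05)

    def test_sphere_outside_axial_support_rejected(self, fine_tir, recon_grid):
        with pytest.raises(ValueError, match="axial support"):
            simulate_scan(Phantom.single((0, 0, 5e-3), 10e-6), fine_tir,
                          recon_grid)

    def test_fluence_taper_attenuates_deep_spheres(self, fine_tir, recon_grid):
        shallow = Phantom.single((0, 0, -0.8e-3), 12.5e-6)
        deep = Phantom.single((0, 0, 0.8e-3), 12.5e-6)
        amp = lambda ph, L: np.max(np.abs(
            simulate_scan(ph, fine_tir, recon_grid,
                          fluence_decay_length=L)[0].ascans))
        ratio_off = amp(deep, None) / amp(shallow, None)
        ratio_on = amp(deep, 1.0e-3) / amp(shallow, 1.0e-3)
        assert ratio_on < 0.5 * ratio_off


class TestSimulateCalibration:
    def test_null_perturbation_matches_ideal_stir(self, geom, acfg, cal_grid):
        frames = simulate_calibration(geom, PerturbationSpec(), cal_grid, acfg)
        ctir = assemble_ctir(frames)
        stir = simulate_tir(geom, cal_grid, acfg)
        izf = estimate_focus(stir)
        ideal = stir.values / np.max(np.abs(stir.on_axis_trace(izf)))
        err = np.linalg.norm(ctir.values - ideal) / np.linalg.norm(ideal)
        assert err < 1e-6

    def test_tilt_breaks_mirror_symmetry(self, geom, acfg, cal_grid):
        ideal = assemble_ctir(
            simulate_calibration(geom, PerturbationSpec(), cal_grid, acfg))
        tilted = assemble_ctir(simulate_calibration(
            geom, PerturbationSpec(lateral_tilt=np.deg2rad(3)), cal_grid,
            acfg))
        a_ideal = mirror_asymmetry(sensitivity_field(ideal), axis=0)
        a_tilted = mirror_asymmetry(sensitivity_field(tilted), axis=0)
        assert a_ideal < 1e-10
        assert a_tilted > 0.01
        assert a_tilted > a_ideal

    def test_seeded_generation_reproducible(self, geom, acfg, cal_grid):
        spec = PerturbationSpec(noise_std=0.01, seed=11)
        f1 = simulate_calibration(geom, spec, cal_grid, acfg)
        f2 = simulate_calibration(geom, spec, cal_grid, acfg)
        np.testing.assert_array_equal(f1.values, f2.values)

    def test_eir_band_filter_removes_high_frequencies(self, geom, acfg,
                                                      cal_grid):
        spec = PerturbationSpec(eir_center=20e6, eir_fractional_bandwidth=1.0)
        shaped = assemble_ctir(simulate_calibration(geom, spec, cal_grid, acfg))
        plain = assemble_ctir(simulate_calibration(geom, PerturbationSpec(),
                                                   cal_grid, acfg))
        izf = estimate_focus(plain)

        def high_band_fraction(tir):
            trace = tir.on_axis_trace(izf)
            spec_ = np.abs(np.fft.rfft(trace, 512))
            f = np.fft.rfftfreq(512, tir.grid.dt)
            return spec_[f > 60e6].sum() / spec_.sum()

        assert high_band_fraction(shaped) < 0.2 * high_band_fraction(plain)

    def test_invalid_perturbations_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(astigmatism=1.5)
        with pytest.raises(ValueError):
            PerturbationSpec(noise_std=-0.1)


class TestStackedSphereExperiment:
    def test_single_depth_equals_simulate_scan(self, fine_tir, recon_grid):
        z = 0.2e-3
        stacked = stacked_sphere_experiment(fine_tir, recon_grid, depths=[z],
                                            seed=9)
        single, _ = simulate_scan(Phantom.single((0, 0, z), 12.5e-6),
                                  fine_tir, recon_grid, seed=9)
        np.testing.assert_array_equal(stacked.ascans, single.ascans)

    def test_sum_linearity(self, fine_tir, recon_grid):
        depths = [-0.4e-3, 0.0, 0.4e-3]
        stacked = stacked_sphere_experiment(fine_tir, recon_grid,
                                            depths=depths, seed=2)
        total = np.zeros_like(stacked.ascans)
        for i, z in enumerate(depths):
            s, _ = simulate_scan(Phantom.single((0, 0, z), 12.5e-6),
                                 fine_tir, recon_grid, seed=2 + i)
            total += s.ascans
        np.testing.assert_array_equal(stacked.ascans, total)

    def test_default_depths_span_3mm_around_focus(self, geom, acfg):
        """With no explicit depth list the experiment covers +/-1.5 mm at a
        20 um-compatible spacing."""
        grid = GridSpec(nx=5, ny=5, nz=31, dx=40e-6, dy=40e-6, dz=100e-6,
                        lateral_radius=0.04e-3)
        tir = simulate_tir(geom, grid, acfg)
        recon = GridSpec(nx=7, ny=7, nz=16, dx=80e-6, dy=80e-6, dz=200e-6,
                         lateral_radius=0.04e-3)
        # default depths reach +/-1.5 mm: the 16-plane (3 mm) grid accepts them
        scan = stacked_sphere_experiment(tir, recon, seed=0)
        assert scan.ascans.any()


class TestResampleTir:
    def test_even_samples_preserved(self, geom, acfg):
        grid = GridSpec(nx=5, ny=5, nz=7, dz=200e-6, lateral_radius=0.05e-3)
        tir = simulate_tir(geom, grid, acfg)
        fine = resample_tir_spatial(tir)
        assert fine.grid.nx == 9 and fine.grid.nz == 13
        # original nodes keep their traces on the shared global axis
        for iz in range(grid.nz):
            k = int(round((tir.t0_per_z[iz] - fine.t0_per_z[0]) / grid.dt))
            np.testing.assert_allclose(
                fine.values[2 * 2, 2 * 2, 2 * iz, k:k + tir.grid.nt],
                tir.values[2, 2, iz, :], atol=1e-15)


def test_band_filter_is_zero_phase(acfg):
    from oamrecon import point_source_waveform
    w = point_source_waveform(acfg, 33)
    f = apply_band_filter(w, 30e6, 1.5)
    # the N-wave is odd around its centre; a zero-phase filter keeps it odd
    s = f.samples
    centre = np.argmin(np.abs(f.t0 + np.arange(s.size) * f.dt))
    k = min(centre, s.size - 1 - centre)
    seg = s[centre - k:centre + k + 1]
    np.testing.assert_allclose(seg, -seg[::-1], atol=1e-12 * np.abs(s).max())
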