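import numpy as np
import pytest

from oamrecon import (AcousticConfig, GridSpec, compute_sir,
                      make_virtual_elements, point_source_waveform,
                      simulate_tir)
from oamrecon.tir_store import center_index


def brute_force_sir(elements, field_point, cfg):
    """Independent double-loop oracle with the same interpolation rule."""
    fp = np.asarray(field_point, float)
    ds = [float(np.linalg.norm(c - fp)) for c in elements.centers]
    dt = cfg.dt
    taus = [d / cfg.speed_of_sound for d in ds]
    k0 = int(np.floor(min(taus) / dt)) - 1
    length = int(np.ceil(max(taus) / dt)) + 2 - k0
    hist = np.zeros(length)
    for d, tau, area in zip(ds, taus, elements.areas):
        w = area / d if cfg.spherical_spreading else area
        pos = tau / dt - k0
        j = int(np.floor(pos))
        frac = pos - j
        hist[j] += w * (1 - frac)
        hist[j + 1] += w * frac
    return hist, k0 * dt


class TestPointSourceWaveform:
    def test_zero_mean_and_unit_peak(self, acfg):
        w = point_source_waveform(acfg, 64)
        assert abs(np.mean(w.samples)) < 1e-6
        assert np.max(np.abs(w.samples)) == 1.0

    def test_peak_to_trough_separation_on_sample_grid(self):
        # 15 um source radius: direct evaluation of the piecewise-linear
        # N-wave on the centred sample grid.
        cfg = AcousticConfig(source_radius=15e-6, speed_of_sound=1490.0,
                             sampling_frequency=250e6)
        w = point_source_waveform(cfg, 64)
        sep = np.argmin(w.samples) - np.argmax(w.samples)
        expected = round(2 * 15e-6 / 1490.0 * 250e6)
        assert sep == expected == 5

    def test_antisymmetry(self, acfg):
        w = point_source_waveform(acfg, 65)
        np.testing.assert_allclose(w.samples, -w.samples[::-1], atol=1e-15)

    def test_window_too_short_rejected(self):
        cfg = AcousticConfig(source_radius=100e-6)
        with pytest.raises(ValueError, match="support"):
            point_source_waveform(cfg, 8)


class TestComputeSIR:
    def test_focal_point_mass_in_two_bins(self, elements, geom, acfg):
        sir = compute_sir(elements, (0.0, 0.0, 0.0), acfg)
        nz = np.flatnonzero(sir.samples)
        assert nz.size <= 2
        assert np.all(np.diff(nz) == 1)
        t_focal = geom.focal_distance / acfg.speed_of_sound
        lo = sir.t0 + nz[0] * sir.dt
        assert lo <= t_focal <= lo + sir.dt * nz.size

    @pytest.mark.parametrize("spreading", [True, False])
    def test_matches_brute_force_oracle(self, elements, spreading):
        cfg = AcousticConfig(spherical_spreading=spreading)
        fp = (0.31e-3, -0.17e-3, 0.83e-3)
        sir = compute_sir(elements, fp, cfg)
        hist, t0 = brute_force_sir(elements, fp, cfg)
        assert sir.t0 == pytest.approx(t0, abs=1e-15)
        np.testing.assert_allclose(sir.samples, hist, rtol=1e-12, atol=1e-18)

    def test_mass_conservation_without_spreading(self, elements):
        cfg = AcousticConfig(spherical_spreading=False)
        sir = compute_sir(elements, (0.1e-3, 0.0, -0.4e-3), cfg)
        assert sir.samples.sum() == pytest.approx(elements.total_area(), rel=1e-12)

    def test_out_of_range_field_point_rejected(self, elements, acfg):
        with pytest.raises(ValueError, match="max_range"):
            compute_sir(elements, (0.0, 0.0, 1.0), acfg)

    def test_coincident_field_point_rejected(self, elements, acfg):
        with pytest.raises(ValueError, match="coincides"):
            compute_sir(elements, elements.centers[3], acfg)

    def test_support_grows_away_from_focus(self, elements, acfg):
        """The spread of element distances increases monotonically with
        distance from the focus, axially and laterally."""
        def support(fp):
            s = compute_sir(elements, fp, acfg)
            nz = np.flatnonzero(s.samples)
            return nz[-1] - nz[0]

        axial = [support((0, 0, z)) for z in (0, 0.4e-3, 0.8e-3, 1.2e-3)]
        lateral = [support((x, 0, 0.2e-3)) for x in (0, 0.2e-3, 0.4e-3)]
        assert all(a < b for a, b in zip(axial, axial[1:]))
        assert all(a <= b for a, b in zip(lateral, lateral[1:]))

    def test_discretization_convergence(self, geom, acfg):
        """Focal SIR is exactly discretization-invariant (every element is
        equidistant from the focus), and the energy-weighted TIR change on
        doubling the angular discretization stays below 10%.

        Pointwise convergence away from the focus is intrinsically limited:
        on-axis, each polar ring contributes a single arrival, so the SIR is
        a comb whose teeth move when the ring count doubles."""
        coarse = make_virtual_elements(geom, 25, 40)
        fine = make_virtual_elements(geom, 50, 80)
        s1 = compute_sir(coarse, (0, 0, 0), acfg)
        s2 = compute_sir(fine, (0, 0, 0), acfg)
        assert s1.samples.sum() / s2.samples.sum() == pytest.approx(1.0, rel=1e-4)
        assert np.flatnonzero(s1.samples).size <= 2
        assert np.flatnonzero(s2.samples).size <= 2

        grid = GridSpec(nx=5, ny=5, nz=7, dz=300e-6, lateral_radius=0.05e-3)
        t1 = simulate_tir(geom, grid, acfg)
        t2 = simulate_tir(geom, grid, acfg, elements=fine)
        num = den = 0.0
        for iz in range(grid.nz):
            k = int(round((t2.t0_per_z[iz] - t1.t0_per_z[iz]) / grid.dt))
            off = max(0, -k)
            L = max(t1.grid.nt + off, t2.grid.nt + k + off) + 1
            a = np.zeros((5, 5, L))
            b = np.zeros((5, 5, L))
            a[:, :, off:off + t1.grid.nt] = t1.values[:, :, iz]
            b[:, :, off + k:off + k + t2.grid.nt] = t2.values[:, :, iz]
            num += np.sum((a - b) ** 2)
            den += np.sum(a**2)
        assert np.sqrt(num / den) < 0.10


class TestSimulateTIR:
    def test_focal_trace_is_delayed_n_wave(self, geom, acfg, small_tir):
        """At the focus the SIR is delta-like, so the TIR trace equals the
        N-wave delayed by F/c up to interpolation tolerance."""
        g = small_tir.grid
        iz = center_index(g.nz)
        trace = small_tir.on_axis_trace(iz)
        trace = trace / np.max(np.abs(trace))
        wave = point_source_waveform(acfg, 33)
        t_focal = geom.focal_distance / acfg.speed_of_sound
        t_trace = small_tir.t0_per_z[iz] + np.arange(trace.size) * g.dt
        t_wave = wave.t0 + t_focal + np.arange(wave.samples.size) * g.dt
        oracle = np.interp(t_trace, t_wave, wave.samples, left=0, right=0)
        # cross-correlation peak alignment: shapes agree to a few percent
        assert np.corrcoef(trace, oracle)[0, 1] > 0.98

    def test_mirror_symmetry_of_ideal_detector(self, small_tir):
        v = small_tir.values
        np.testing.assert_allclose(v, v[::-1, :, :, :], rtol=0, atol=1e-10)
        np.testing.assert_allclose(v, v[:, ::-1, :, :], rtol=0, atol=1e-10)

    def test_support_limits_enforced(self, geom, acfg):
        grid = GridSpec(nx=5, ny=5, nz=5, dz=1.0e-3, lateral_radius=0.05e-3)
        with pytest.raises(ValueError, match="axial"):
            simulate_tir(geom, grid, acfg)
        grid = GridSpec(nx=5, ny=5, nz=5, lateral_radius=2.0e-3)
        with pytest.raises(ValueError, match="lateral"):
            simulate_tir(geom, grid, acfg)

    def test_too_fine_grid_warns(self, geom, acfg):
        grid = GridSpec(nx=3, ny=3, nz=3, dx=2e-6, dy=2e-6, dz=2e-6,
                        lateral_radius=0.01e-3)
        with pytest.warns(UserWarning, match="step"):
            simulate_tir(geom, grid, acfg)

    def test_outside_lateral_support_is_zero(self, small_tir):
        g = small_tir.grid
        # corner offsets exceed the 0.11 mm radius on the 11x11 20 um grid
        assert not small_tir.values[0, 0].any()
        assert small_tir.values[center_index(g.nx), center_index(g.ny)].any()
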