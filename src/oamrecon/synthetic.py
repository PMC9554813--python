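"""Synthetic inputs: phantoms, forward-simulated scans, emulated calibration.

This module generates every input the pipeline needs without an instrument:
spherical-absorber phantoms rasterized with analytic partial-volume weights,
raster scans produced through the forward model (on a grid 2x finer than the
reconstruction grid, with a different sphere size, to avoid the inverse
crime), and calibration frames of a sub-resolution microsphere recorded by a
deliberately imperfect detector (tilted / warped element positions, band-pass
electrical response, white noise, repeat averaging).

All randomness flows from explicit seeds; identical configurations produce
bitwise-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .acoustics import (AcousticConfig, Waveform, point_source_waveform,
                        simulate_tir)
from .forward_model import AbsorptionVolume, build_model, forward
from .geometry import ElementSet, TransducerGeometry, make_virtual_elements
from .preprocess import PulseRecords, ScanVolume
from .tir_store import CalibrationFrames, GridSpec, TIR4D

__all__ = [
    "Phantom",
    "PerturbationSpec",
    "perturb_elements",
    "apply_band_filter",
    "rasterize_phantom",
    "resample_tir_spatial",
    "simulate_scan",
    "simulate_calibration",
    "stacked_sphere_experiment",
    "sensitivity_field",
]


@dataclass(frozen=True)
class Phantom:
    """List of spherical absorbers on zero background.

    Each sphere is (center (x, y, z) in metres relative to the focus,
    radius in metres, amplitude in a.u.).
    """

    spheres: tuple = ()

    def __post_init__(self) -> None:
        for center, radius, amplitude in self.spheres:
            if radius <= 0:
                raise ValueError("sphere radii must be positive")
            np.asarray(center, dtype=float).reshape(3)

    @staticmethod
    def single(center, radius: float, amplitude: float = 1.0) -> "Phantom":
        return Phantom(spheres=((tuple(center), radius, amplitude),))


@dataclass(frozen=True)
class PerturbationSpec:
    """Deviations of the emulated real detector from the ideal one.

    ``lateral_tilt`` rotates the element set about the y axis through the
    focus (rad); ``astigmatism`` scales element radii by 1 + a*cos(2*phi),
    emulating the asymmetric stretching of a foil formed into an approximate
    sphere; ``eir_center`` / ``eir_fractional_bandwidth`` shape a Gaussian
    band-pass electrical response; ``noise_std`` is the white-noise level of
    each calibration repeat (a.u.).
    """

    lateral_tilt: float = 0.0
    astigmatism: float = 0.0
    eir_center: float | None = None
    eir_fractional_bandwidth: float | None = None
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if abs(self.astigmatism) >= 1.0:
            raise ValueError("astigmatism magnitude must be < 1")
        if abs(self.lateral_tilt) >= np.pi / 2:
            raise ValueError("lateral tilt must be < pi/2")


def perturb_elements(elements: ElementSet, spec: PerturbationSpec) -> ElementSet:
    """Apply tilt and astigmatic warp to the virtual-element positions.

    The warp moves elements off the ideal sphere (as a stretched foil would);
    areas are kept, since the emulation targets geometric asymmetry of the
    sensitivity field, not a re-derivation of the surface measure.
    """
    centers = elements.centers.copy()
    if spec.astigmatism != 0.0:
        phi = np.arctan2(centers[:, 1], centers[:, 0])
        centers *= (1.0 + spec.astigmatism * np.cos(2.0 * phi))[:, None]
    if spec.lateral_tilt != 0.0:
        ct, st = np.cos(spec.lateral_tilt), np.sin(spec.lateral_tilt)
        rot = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
        centers = centers @ rot.T
    return ElementSet(centers=centers, areas=elements.areas,
                      focal_distance=elements.focal_distance)


def apply_band_filter(wave: Waveform, center: float,
                      fractional_bandwidth: float,
                      pad_factor: int = 6) -> Waveform:
    """Filter a waveform with a Gaussian band-pass (zero-phase).

    H(f) = exp(-(|f| - fc)^2 / (2 sigma^2)) with sigma set so the -6 dB
    full width equals ``fractional_bandwidth * fc``.  The waveform is padded
    symmetrically before the FFT so the linear-filter tails are kept; the
    output length is odd so its start time stays on the dt/1 grid used by
    the per-depth TIR windows.
    """
    n = wave.samples.size
    n_pad = n * pad_factor
    if n_pad % 2 == 0:
        n_pad += 1
    lead = (n_pad - n) // 2
    padded = np.zeros(n_pad)
    padded[lead:lead + n] = wave.samples
    freqs = np.fft.rfftfreq(n_pad, d=wave.dt)
    sigma = fractional_bandwidth * center / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    h = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    out = np.fft.irfft(np.fft.rfft(padded) * h, n=n_pad)
    return Waveform(samples=out, dt=wave.dt, t0=wave.t0 - lead * wave.dt)


def rasterize_phantom(phantom: Phantom, grid: GridSpec) -> AbsorptionVolume:
    """Rasterize spheres with analytic partial-volume weights.

    Each voxel's value is amplitude times the fraction of the voxel inside
    the sphere, estimated by 3-point Gauss-Legendre quadrature per axis
    (27 points): sub-resolution spheres neither vanish nor alias on the
    20 um grid this way.
    """
    nodes = np.array([-np.sqrt(0.6), 0.0, np.sqrt(0.6)])
    wts = np.array([5.0, 8.0, 5.0]) / 9.0 / 2.0  # integrates to 1 over [-1/2, 1/2]
    w3 = (wts[:, None, None] * wts[None, :, None] * wts[None, None, :]).ravel()
    offs = np.stack(np.meshgrid(nodes, nodes, nodes, indexing="ij"),
                    axis=-1).reshape(-1, 3) / 2.0

    xs, ys, zs = grid.x_offsets(), grid.y_offsets(), grid.z_values()
    steps = np.array([grid.dx, grid.dy, grid.dz])
    vol = np.zeros((grid.nx, grid.ny, grid.nz))
    for center, radius, amplitude in phantom.spheres:
        c = np.asarray(center, dtype=float)
        half_diag = 0.5 * np.linalg.norm(steps)
        ix = np.flatnonzero(np.abs(xs - c[0]) <= radius + half_diag)
        iy = np.flatnonzero(np.abs(ys - c[1]) <= radius + half_diag)
        iz = np.flatnonzero(np.abs(zs - c[2]) <= radius + half_diag)
        if not (ix.size and iy.size and iz.size):
            continue
        gx, gy, gz = np.meshgrid(xs[ix], ys[iy], zs[iz], indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1)  # (mx, my, mz, 3)
        quad = pts[..., None, :] + offs * steps  # (mx, my, mz, 27, 3)
        inside = np.sum((quad - c) ** 2, axis=-1) <= radius**2
        frac = np.einsum("...q,q->...", inside.astype(float), w3)
        vol[np.ix_(ix, iy, iz)] += amplitude * frac
    return AbsorptionVolume(values=vol, dx=grid.dx, dy=grid.dy, dz=grid.dz)


def _expand_global_time(tir: TIR4D):
    """Place per-depth windows on one common global time axis."""
    g = tir.grid
    rel = (tir.t0_per_z - tir.t0_per_z.min()) / g.dt
    idx = np.round(rel).astype(np.intp)
    if np.max(np.abs(rel - idx)) > 1e-6:
        raise ValueError("per-depth time offsets are not aligned to the grid")
    nt = int(idx.max()) + g.nt
    out = np.zeros((g.nx, g.ny, g.nz, nt))
    for iz in range(g.nz):
        out[:, :, iz, idx[iz]:idx[iz] + g.nt] = tir.values[:, :, iz, :]
    return out, float(tir.t0_per_z.min())


def _refine_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Linear 2x refinement along one axis: n -> 2n - 1 samples."""
    n = a.shape[axis]
    out_shape = list(a.shape)
    out_shape[axis] = 2 * n - 1
    out = np.zeros(out_shape, dtype=a.dtype)
    sl_even = [slice(None)] * a.ndim
    sl_even[axis] = slice(0, None, 2)
    out[tuple(sl_even)] = a
    lo = [slice(None)] * a.ndim
    hi = [slice(None)] * a.ndim
    odd = [slice(None)] * a.ndim
    lo[axis] = slice(0, n - 1)
    hi[axis] = slice(1, n)
    odd[axis] = slice(1, None, 2)
    out[tuple(odd)] = 0.5 * (a[tuple(lo)] + a[tuple(hi)])
    return out


def resample_tir_spatial(tir: TIR4D, factor: int = 2) -> TIR4D:
    """Refine the spatial axes of a TIR by linear interpolation (factor 2).

    Traces are first aligned on a global time axis so interpolation between
    depth planes with different windows is meaningful; the refined TIR keeps
    that single global axis (all per-depth offsets equal).
    """
    if factor != 2:
        raise NotImplementedError("only 2x refinement is supported")
    vals, t0 = _expand_global_time(tir)
    for axis in (0, 1, 2):
        vals = _refine_axis(vals, axis)
    g = tir.grid
    grid = g.replace(dx=g.dx / 2, dy=g.dy / 2, dz=g.dz / 2,
                     nx=2 * g.nx - 1, ny=2 * g.ny - 1, nz=2 * g.nz - 1,
                     nt=vals.shape[3])
    return TIR4D(values=vals, grid=grid,
                 t0_per_z=np.full(grid.nz, t0), provenance=tir.provenance,
                 meta=dict(tir.meta, resampled=True))


def _bin_lateral(fine: np.ndarray, axis: int) -> np.ndarray:
    """Tent-kernel ([1/4, 1/2, 1/4]) binning of a 2x-fine axis onto the
    coarse grid, centred on the coarse positions; edges renormalized."""
    a = np.moveaxis(fine, axis, 0)
    coarse = 0.5 * a[0::2]
    wsum = np.full(coarse.shape[0], 0.5)
    coarse[1:] += 0.25 * a[1::2]   # left fine neighbour of coarse i >= 1
    wsum[1:] += 0.25
    coarse[:-1] += 0.25 * a[1::2]  # right fine neighbour of coarse i <= n-2
    wsum[:-1] += 0.25
    coarse /= wsum.reshape((-1,) + (1,) * (coarse.ndim - 1))
    return np.moveaxis(coarse, 0, axis)


def simulate_scan(
    phantom: Phantom,
    tir_truth: TIR4D,
    recon_grid: GridSpec,
    noise_std: float = 0.0,
    seed: int = 0,
    *,
    fluence_decay_length: float | None = None,
    energy_jitter: float = 0.0,
    time_jitter: float = 0.0,
):
    """Forward-simulate a raster scan of a phantom.

    The phantom is rasterized on a grid 2x finer than the reconstruction
    grid and pushed through the forward model built from the truth TIR on
    that finer grid (supplied fine, or refined here by interpolation), then
    tent-binned back to the scan grid — reconstructions never see the exact
    discrete operator that generated their data.  Seeded white noise is
    added and per-A-scan pulse records are emitted (unit energy / zero
    jitter unless perturbations are requested, in which case the scan itself
    is perturbed consistently so the preprocessing can undo it).

    ``fluence_decay_length`` optionally applies an exponential per-depth
    amplitude taper exp(-(z - z_min)/L) to the rasterized phantom, emulating
    the reduced optical fluence reaching deeper layers under coaxial
    illumination; off by default so depth-uniformity experiments can include
    or exclude that confound.

    Returns ``(ScanVolume, PulseRecords)``.
    """
    fine = _fine_grid(recon_grid)
    tg = tir_truth.grid
    if _close(tg.dx, fine.dx) and _close(tg.dz, fine.dz):
        tir_fine = tir_truth
    elif _close(tg.dx, recon_grid.dx) and _close(tg.dz, recon_grid.dz):
        tir_fine = resample_tir_spatial(tir_truth)
    else:
        raise ValueError(
            "truth TIR grid steps match neither the fine nor the "
            "reconstruction grid"
        )
    if tir_fine.grid.nz != fine.nz:
        raise ValueError(
            f"truth TIR has {tir_fine.grid.nz} depth planes; the fine grid "
            f"needs {fine.nz}"
        )
    z_extent = fine.z_values()
    for center, radius, _ in phantom.spheres:
        cz = float(np.asarray(center, float)[2])
        if not (z_extent.min() - fine.dz / 2 <= cz <= z_extent.max() + fine.dz / 2):
            raise ValueError(
                f"sphere at z={cz:.3e} m lies outside the TIR axial support"
            )

    vol = rasterize_phantom(phantom, fine)
    if fluence_decay_length is not None:
        taper = np.exp(-(z_extent - z_extent.min()) / fluence_decay_length)
        vol = vol.copy_with(vol.values * taper[None, None, :])

    model = build_model(tir_fine)
    scan_fine = forward(model, vol)
    binned = _bin_lateral(_bin_lateral(scan_fine.ascans, 0), 1)

    rng = np.random.default_rng(seed)
    if noise_std > 0.0:
        binned = binned + rng.normal(0.0, noise_std, size=binned.shape)
    nx, ny = binned.shape[:2]
    energies = np.ones((nx, ny))
    offsets = np.zeros((nx, ny))
    if energy_jitter > 0.0:
        energies = np.clip(1.0 + rng.normal(0.0, energy_jitter, (nx, ny)),
                           1e-3, None)
        binned = binned * energies[:, :, None]
    if time_jitter > 0.0:
        offsets = rng.normal(0.0, time_jitter, (nx, ny))
        freqs = np.fft.rfftfreq(binned.shape[2], d=recon_grid.dt)
        spec = np.fft.rfft(binned, axis=2)
        spec *= np.exp(-2j * np.pi * freqs[None, None, :] * offsets[:, :, None])
        binned = np.fft.irfft(spec, n=binned.shape[2], axis=2)
    scan = ScanVolume(ascans=binned, dx=recon_grid.dx, dy=recon_grid.dy,
                      dt=recon_grid.dt, t_start=scan_fine.t_start)
    return scan, PulseRecords(energies=energies, time_offsets=offsets)


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= 1e-9 * max(abs(a), abs(b))


def _fine_grid(recon_grid: GridSpec) -> GridSpec:
    return recon_grid.replace(
        dx=recon_grid.dx / 2, dy=recon_grid.dy / 2, dz=recon_grid.dz / 2,
        nx=2 * recon_grid.nx - 1, ny=2 * recon_grid.ny - 1,
        nz=2 * recon_grid.nz - 1, nt=0,
    )


def simulate_calibration(
    geom: TransducerGeometry,
    perturbation: PerturbationSpec,
    grid: GridSpec,
    cfg: AcousticConfig,
    n_avg: int = 3,
    sphere_diameter: float = 15.0e-6,
    n_polar: int = 25,
    n_azimuth: int = 40,
) -> CalibrationFrames:
    """Emulate the microsphere calibration scan of a (perturbed) detector.

    The perturbed virtual-element set responds to a sub-resolution sphere
    (default 15 um diameter) at every grid node; the trace is shaped by the
    Gaussian electrical response when one is specified, and ``n_avg`` noisy
    repeats per node are produced (white noise of ``perturbation.noise_std``,
    seeded).  Feed the result to :func:`oamrecon.tir_store.assemble_ctir`.
    """
    elements = perturb_elements(
        make_virtual_elements(geom, n_polar, n_azimuth), perturbation)
    cfg_cal = dataclasses.replace(cfg, source_radius=sphere_diameter / 2.0)
    n_wave = int(np.ceil(2 * cfg_cal.source_radius / cfg_cal.speed_of_sound
                         / cfg_cal.dt)) + 4
    if n_wave % 2 == 0:
        n_wave += 1
    wave = point_source_waveform(cfg_cal, n_wave)
    if perturbation.eir_center is not None:
        if perturbation.eir_fractional_bandwidth is None:
            raise ValueError("eir_center given without eir_fractional_bandwidth")
        wave = apply_band_filter(wave, perturbation.eir_center,
                                 perturbation.eir_fractional_bandwidth)
    tir = simulate_tir(geom, grid, cfg_cal, elements=elements, waveform=wave)
    rng = np.random.default_rng(perturbation.seed)
    clean = tir.values[:, :, :, None, :]
    if perturbation.noise_std > 0.0:
        reps = clean + rng.normal(
            0.0, perturbation.noise_std,
            size=clean.shape[:3] + (n_avg,) + clean.shape[4:])
    else:
        reps = np.broadcast_to(clean, clean.shape[:3] + (n_avg,)
                               + clean.shape[4:]).copy()
    return CalibrationFrames(values=reps, t0_per_z=tir.t0_per_z,
                             grid=tir.grid)


def stacked_sphere_experiment(
    tir_truth: TIR4D,
    recon_grid: GridSpec,
    depths=None,
    sphere_radius: float = 12.5e-6,
    amplitude: float = 1.0,
    noise_std: float = 0.0,
    seed: int = 0,
) -> ScanVolume:
    """Sum of single-sphere scans at several on-axis depths.

    Emulates the phantom protocol in which the time-resolved signals of one
    sphere measured at different axial positions are summed, so one scan
    volume carries identical absorbers spanning the depth range.  Default
    depths span +/-1.5 mm around the focus at 0.3 mm (20 um-compatible)
    spacing; the default sphere is the 25 um phantom sphere (radius
    12.5 um), larger than the calibration sphere by design.
    """
    if depths is None:
        depths = np.arange(-1.5e-3, 1.5e-3 + 1e-9, 0.3e-3)
    depths = np.asarray(depths, dtype=float)
    total = None
    for i, z in enumerate(depths):
        phantom = Phantom.single((0.0, 0.0, float(z)), sphere_radius, amplitude)
        scan, _ = simulate_scan(phantom, tir_truth, recon_grid,
                                noise_std=noise_std, seed=seed + i)
        total = scan if total is None else total.copy_with(
            total.ascans + scan.ascans)
    return total


def sensitivity_field(tir: TIR4D) -> np.ndarray:
    """Maximum-amplitude projection of |TIR| along time: the 3D sensitivity
    field used to visualize and compare calibrated vs simulated responses."""
    return np.max(np.abs(tir.values), axis=3)
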