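"""Point-absorber waveform, spatial impulse response, and TIR simulation.

The simulated TIR (sTIR) of the focused detector is built in two steps.
First the spatial impulse response (SIR) at a field point is formed as the
histogram of arrival times from every virtual element of the detector
surface, weighted by element area (and 1/distance spherical spreading by
default).  Second, the SIR is convolved with the theoretical optoacoustic
waveform of a uniformly heated sphere — the classical bipolar N-wave.

The simulation assumes a homogeneous medium with a single speed of sound and
a flat electrical response of the sensing element and amplification chain;
frequency-dependent attenuation and dispersion are deliberately absent (they
are exactly what the calibrated TIR captures and the simulated one cannot).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.spatial.distance import cdist

from .geometry import ElementSet, TransducerGeometry, make_virtual_elements
from .tir_store import GridSpec, TIR4D

__all__ = [
    "AcousticConfig",
    "Waveform",
    "point_source_waveform",
    "compute_sir",
    "simulate_tir",
]

#: Speed of sound in deionized water at ~22 C (m/s); not a measured system
#: constant but the standard coupling-medium value, configurable.
DEFAULT_SPEED_OF_SOUND = 1490.0
DEFAULT_SAMPLING_FREQUENCY = 250.0e6
#: Nominal calibration-sphere radius: 15 um diameter sphere.
DEFAULT_SOURCE_RADIUS = 7.5e-6


@dataclass(frozen=True)
class AcousticConfig:
    """Scalar acoustic/acquisition parameters shared across the pipeline."""

    speed_of_sound: float = DEFAULT_SPEED_OF_SOUND
    sampling_frequency: float = DEFAULT_SAMPLING_FREQUENCY
    source_radius: float = DEFAULT_SOURCE_RADIUS
    spherical_spreading: bool = True

    def __post_init__(self) -> None:
        if self.speed_of_sound <= 0 or self.sampling_frequency <= 0:
            raise ValueError("speed_of_sound and sampling_frequency must be positive")
        if self.source_radius <= 0:
            raise ValueError("source_radius must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_frequency


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled time signal: ``samples[i]`` at ``t0 + i * dt``."""

    samples: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")
        object.__setattr__(self, "samples", samples)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) * self.dt


def point_source_waveform(cfg: AcousticConfig, n_samples: int = 32) -> Waveform:
    """N-shaped pressure transient of a uniformly heated sphere.

    The far-field signal of an optically heated sphere of radius R is the
    antisymmetric linear ramp p(tau) = -tau / (R/c) for |tau| <= R/c and zero
    outside: a jump to positive peak at the leading edge, linear descent
    through zero, negative trough, jump back to zero.  Total duration 2R/c,
    centred in the window, peak normalized to 1 after sampling.
    """
    half = cfg.source_radius / cfg.speed_of_sound
    dt = cfg.dt
    if (n_samples - 1) * dt < 2.0 * half:
        raise ValueError(
            f"window of {n_samples} samples ({(n_samples - 1) * dt:.3e} s) cannot "
            f"contain the N-wave support 2R/c = {2.0 * half:.3e} s"
        )
    t = (np.arange(n_samples) - (n_samples - 1) / 2.0) * dt
    p = np.where(np.abs(t) <= half, -t / half, 0.0)
    peak = np.max(np.abs(p))
    if peak == 0.0:
        raise ValueError(
            "no sample falls inside the N-wave support; increase sampling rate"
        )
    return Waveform(samples=p / peak, dt=dt, t0=float(t[0]))


def _deposit_histogram(tau: np.ndarray, weights: np.ndarray, dt: float,
                       k0: int, length: int) -> np.ndarray:
    """Linear-interpolated arrival-time histogram on bins k0..k0+length-1.

    Each weight is split between the two adjacent time bins in proportion to
    its sub-bin position, which suppresses bin-quantization ringing relative
    to nearest-bin deposition.  Vectorized over leading axes of ``tau``.
    """
    pos = tau / dt - k0
    j = np.floor(pos).astype(np.intp)
    frac = pos - j
    if np.any(j < 0) or np.any(j + 1 >= length):
        raise ValueError("histogram window does not cover all arrival times")
    lead = tau.shape[:-1]
    rows = int(np.prod(lead)) if lead else 1
    j_flat = j.reshape(rows, -1)
    frac_flat = frac.reshape(rows, -1)
    w_flat = np.broadcast_to(weights, tau.shape).reshape(rows, -1)
    base = (np.arange(rows, dtype=np.intp) * length)[:, None]
    idx = (j_flat + base).ravel()
    hist = np.bincount(idx, weights=(w_flat * (1.0 - frac_flat)).ravel(),
                       minlength=rows * length)
    hist += np.bincount(idx + 1, weights=(w_flat * frac_flat).ravel(),
                        minlength=rows * length)
    return hist.reshape(*lead, length) if lead else hist.reshape(length)


def compute_sir(elements: ElementSet, field_point, cfg: AcousticConfig,
                max_range: float = 0.1) -> Waveform:
    """Spatial impulse response at one field point.

    Distances from the field point to every element center become arrival
    times d/c; each element deposits its area (divided by distance when
    spherical spreading is on, per the Rayleigh integral) into the
    arrival-time histogram with linear interpolation between adjacent bins.
    The output window covers [min(d), max(d)]/c padded by one bin each side.
    """
    fp = np.asarray(field_point, dtype=float).reshape(3)
    d = np.linalg.norm(elements.centers - fp, axis=1)
    if np.any(d == 0.0):
        raise ValueError("field point coincides with an element center")
    if np.max(d) > max_range:
        raise ValueError(
            f"field point at distance {np.max(d):.3e} m exceeds max_range {max_range:.3e} m"
        )
    c = cfg.speed_of_sound
    dt = cfg.dt
    tau = d / c
    w = elements.areas / d if cfg.spherical_spreading else elements.areas
    k0 = int(np.floor(tau.min() / dt)) - 1
    length = int(np.ceil(tau.max() / dt)) + 2 - k0
    hist = _deposit_histogram(tau, w, dt, k0, length)
    return Waveform(samples=hist, dt=dt, t0=k0 * dt)


def _plane_distance_bounds(elements: ElementSet, z: float, radius: float):
    """Exact min/max distance between the element set and the disc of the
    given lateral radius at depth z (bounds for buffer sizing)."""
    ex = elements.centers[:, 0]
    ey = elements.centers[:, 1]
    ez = elements.centers[:, 2]
    le = np.hypot(ex, ey)
    dz = z - ez
    dmin = np.sqrt(np.maximum(le - radius, 0.0) ** 2 + dz**2).min()
    dmax = np.sqrt((le + radius) ** 2 + dz**2).max()
    return float(dmin), float(dmax)


def simulate_tir(
    geom: TransducerGeometry,
    grid: GridSpec,
    cfg: AcousticConfig,
    elements: ElementSet | None = None,
    n_polar: int = 25,
    n_azimuth: int = 40,
    support_lateral_radius: float = 1.0e-3,
    support_axial_extent: float = 3.0e-3,
    waveform: Waveform | None = None,
) -> TIR4D:
    """Simulate the TIR on a centred (dx, dy, z) grid around the focus.

    For every voxel position relative to the transducer the SIR is computed
    from the virtual-element set and convolved with the point-absorber
    N-wave.  Voxels outside the configured lateral support radius are zero.
    The result is cylindrically symmetric for the ideal geometry; a perturbed
    ``elements`` set (tilt, warp) breaks that symmetry, which is the
    mechanism the synthetic calibration emulation uses.

    ``waveform`` overrides the default N-wave (e.g. to include an electrical
    response); it must share the grid's sampling interval.
    """
    if abs(grid.dt - cfg.dt) > 1e-15:
        raise ValueError("grid.dt must equal the acoustic sampling interval")
    xo = grid.x_offsets()
    yo = grid.y_offsets()
    zv = grid.z_values()
    r_extent = float(np.hypot(np.abs(xo).max(), np.abs(yo).max()))
    if grid.lateral_radius > support_lateral_radius * (1 + 1e-9):
        raise ValueError(
            f"grid lateral_radius {grid.lateral_radius:.3e} m exceeds the "
            f"simulation support {support_lateral_radius:.3e} m"
        )
    if np.abs(zv).max() > support_axial_extent / 2 * (1 + 1e-9):
        raise ValueError(
            f"grid axial extent exceeds the simulation support "
            f"(+/-{support_axial_extent / 2:.3e} m)"
        )
    if min(grid.dx, grid.dy, grid.dz) < 0.5 * cfg.speed_of_sound * cfg.dt:
        warnings.warn(
            "spatial step finer than half the acoustic path per time sample; "
            "arrival-time differences between neighbours are sub-sample"
        )

    if elements is None:
        elements = make_virtual_elements(geom, n_polar, n_azimuth)
    if waveform is None:
        n_wave = int(np.ceil(2 * cfg.source_radius / cfg.speed_of_sound / cfg.dt)) + 4
        waveform = point_source_waveform(cfg, n_wave)
    elif abs(waveform.dt - grid.dt) > 1e-15:
        raise ValueError("waveform sampling interval must match the grid")
    nw = waveform.samples.size

    c = cfg.speed_of_sound
    dt = grid.dt
    mask_r = min(grid.lateral_radius, r_extent) * (1 + 1e-12)
    gx, gy = np.meshgrid(xo, yo, indexing="ij")
    mask = np.hypot(gx, gy) <= mask_r
    pts_xy = np.stack([gx[mask], gy[mask]], axis=1)

    # Per-plane time windows from exact disc-to-element distance bounds.
    k0s = np.empty(grid.nz, dtype=np.intp)
    lens = np.empty(grid.nz, dtype=np.intp)
    for iz, z in enumerate(zv):
        dmin, dmax = _plane_distance_bounds(elements, z, mask_r)
        k0s[iz] = int(np.floor(dmin / c / dt)) - 1
        lens[iz] = int(np.ceil(dmax / c / dt)) + 2 - k0s[iz]
    nt = int(lens.max()) + nw - 1

    values = np.zeros((grid.nx, grid.ny, grid.nz, nt))
    t0_per_z = k0s * dt + waveform.t0
    pts = np.empty((pts_xy.shape[0], 3))
    pts[:, :2] = pts_xy
    for iz, z in enumerate(zv):
        pts[:, 2] = z
        d = cdist(pts, elements.centers)
        tau = d / c
        w = elements.areas / d if cfg.spherical_spreading else \
            np.broadcast_to(elements.areas, d.shape)
        sir = _deposit_histogram(tau, w, dt, int(k0s[iz]), int(lens[iz]))
        traces = fftconvolve(sir, waveform.samples[None, :], mode="full", axes=1)
        values[mask, iz, : traces.shape[1]] = traces

    meta = {
        "geometry": {
            "focal_distance": geom.focal_distance,
            "aperture_radius": geom.aperture_radius,
            "hole_radius": geom.hole_radius,
        },
        "acoustics": {
            "speed_of_sound": cfg.speed_of_sound,
            "sampling_frequency": cfg.sampling_frequency,
            "source_radius": cfg.source_radius,
            "spherical_spreading": cfg.spherical_spreading,
        },
        "n_elements": elements.count,
    }
    return TIR4D(values=values, grid=grid.replace(nt=nt), t0_per_z=t0_per_z,
                 provenance="simulated", meta=meta)
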