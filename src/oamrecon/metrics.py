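"""Reconstruction quality metrics: FWHM resolution, depth uniformity, SNR.

All metrics operate on the absolute value of the signed reconstruction
(consistent with maximum-amplitude-projection rendering); profiles are taken
through the discrete argmax with no sub-voxel refinement, and widths are
interpolated linearly between samples around the half-maximum crossings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forward_model import AbsorptionVolume
from .tir_store import center_index

__all__ = [
    "fwhm",
    "resolution_vs_depth",
    "depth_uniformity",
    "snr",
    "mirror_asymmetry",
]


def fwhm(profile: np.ndarray, spacing: float, strict: bool = True) -> float:
    """Full width at half maximum of a single-peaked 1D profile (m).

    The two half-maximum crossings adjacent to the global peak are located by
    linear interpolation.  The peak must be interior.  With ``strict`` (the
    default) no sample outside the bracketed lobe may reach half maximum
    again — profiles with several peaks above half maximum are ambiguous and
    rejected.  ``strict=False`` returns the main-lobe width regardless,
    which is how widths are read off artifact-ridden reconstructions whose
    side lobes would otherwise abort the measurement.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    k = int(np.argmax(p))
    peak = p[k]
    if k == 0 or k == p.size - 1:
        raise ValueError("peak lies at the profile boundary")
    half = peak / 2.0

    i = k
    while i > 0 and p[i - 1] >= half:
        i -= 1
    if i == 0 and p[0] >= half:
        raise ValueError("no half-maximum crossing on the left side")
    left = (i - 1) + (half - p[i - 1]) / (p[i] - p[i - 1])

    j = k
    while j < p.size - 1 and p[j + 1] >= half:
        j += 1
    if j == p.size - 1 and p[-1] >= half:
        raise ValueError("no half-maximum crossing on the right side")
    right = j + (half - p[j]) / (p[j + 1] - p[j])

    if strict and (np.any(p[:max(i - 1, 0)] >= half)
                   or np.any(p[j + 2:] >= half)):
        raise ValueError("multiple peaks above half maximum: non-unique maximum")
    return float((right - left) * spacing)


def resolution_vs_depth(
    vol: AbsorptionVolume,
    sphere_centers,
    window_radius: float = 150.0e-6,
) -> pd.DataFrame:
    """Lateral and axial FWHM for each reconstructed sphere.

    ``sphere_centers`` are (x, y, z) positions in metres relative to the
    volume center (focus).  For each sphere, the local maximum of |vol|
    within a window of ``window_radius`` is located; the lateral FWHM is
    measured on the x-profile and the axial FWHM on the z-profile through
    that peak, both restricted to the window.  The peak amplitude is reported
    alongside so depth uniformity can be evaluated on the same table.

    Spheres closer than twice the window radius (axially or laterally) are
    rejected as overlapping.
    """
    centers = np.asarray(sphere_centers, dtype=float).reshape(-1, 3)
    if centers.shape[0] == 0:
        raise ValueError("no sphere centers given")
    for a in range(centers.shape[0]):
        for b in range(a + 1, centers.shape[0]):
            if np.linalg.norm(centers[a] - centers[b]) < 2.0 * window_radius:
                raise ValueError(f"spheres {a} and {b} overlap within the window")
    v = np.abs(vol.values)
    if not v.any():
        raise ValueError("volume is identically zero: no peaks to measure")
    nx, ny, nz = v.shape
    cx, cy, cz = center_index(nx), center_index(ny), center_index(nz)
    steps = np.array([vol.dx, vol.dy, vol.dz])
    rows = []
    for sx, sy, sz in centers:
        ci = np.round(np.array([sx, sy, sz]) / steps).astype(int) + (cx, cy, cz)
        wi = np.maximum(np.round(window_radius / steps).astype(int), 1)
        lo = np.maximum(ci - wi, 0)
        hi = np.minimum(ci + wi + 1, (nx, ny, nz))
        sub = v[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        pk = np.unravel_index(np.argmax(sub), sub.shape)
        px, py, pz = lo + pk

        def lobe_width(profile, spacing):
            try:
                return fwhm(profile, spacing, strict=False)
            except ValueError:
                return np.nan  # peak at the window edge or no crossing

        rows.append({
            "z": sz,
            "lateral_fwhm": lobe_width(v[lo[0]:hi[0], py, pz], vol.dx),
            "axial_fwhm": lobe_width(v[px, py, lo[2]:hi[2]], vol.dz),
            "peak_amplitude": float(v[px, py, pz]),
        })
    return pd.DataFrame(rows)


def depth_uniformity(peak_amplitudes) -> float:
    """Intensity drop across depths: 100 * (max - min) / max, in percent.

    Smaller is better; 0% means perfectly uniform recovery of identical
    absorbers at different depths.
    """
    a = np.asarray(peak_amplitudes, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two per-depth amplitudes")
    if not np.all(np.isfinite(a)) or np.any(a < 0):
        raise ValueError("amplitudes must be finite and non-negative")
    if a.max() == 0:
        raise ValueError("all amplitudes are zero")
    # ratio first: (max - min)/max <= 1 exactly, so the result never
    # exceeds 100 by rounding
    return float(100.0 * ((a.max() - a.min()) / a.max()))


def snr(vol: AbsorptionVolume, signal_region, noise_region) -> float:
    """Peak-signal over noise-std ratio in dB: 20 log10(peak|s| / std(n)).

    Regions are index tuples/slices into the volume and must be disjoint.
    """
    s = np.abs(vol.values[signal_region])
    n = vol.values[noise_region]
    sd = float(np.std(n))
    if sd == 0.0:
        raise ValueError("noise region has zero variance")
    return float(20.0 * np.log10(np.max(s) / sd))


def mirror_asymmetry(values: np.ndarray, axis: int = 0) -> float:
    """Mirror-symmetry defect index about the center of one axis.

    ||V - flip(V)|| / ||V|| on a grid symmetric about the acoustic axis;
    ~0 for an ideally symmetric detector response, > 0 when tilt or warp
    breaks the symmetry (the side-lobe artifact analogue).
    """
    v = np.asarray(values, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ValueError("cannot measure asymmetry of an all-zero field")
    return float(np.linalg.norm(v - np.flip(v, axis=axis)) / norm)
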