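"""Virtual-detector delay-and-sum (SAFT) baseline reconstruction.

The focused detector is collapsed to a virtual point receiver at its focus.
A voxel at depth z (relative to the focal plane) and lateral distance r from
a scan position's axis is reached over the two-leg path focus->voxel, so its
signal appears at delay F/c + d/c for voxels deeper than the focal plane and
F/c - d/c for shallower ones, where d is the focus-to-voxel distance.  SAFT
averages, over all scan positions whose acceptance cone contains the voxel,
the recorded sample at that delay (linear interpolation in time).

Normalization is by the number of contributing A-scans, not a raw sum, so the
depth-dependent aperture size does not inflate amplitudes.  No apodization or
coherence-factor weighting is applied.  Because the cone narrows to a point
at the focal plane, few neighbours contribute near the focus — the origin of
the non-uniform SAFT noise background there.
"""

from __future__ import annotations

import numpy as np

from .acoustics import AcousticConfig
from .forward_model import AbsorptionVolume
from .geometry import TransducerGeometry
from .preprocess import ScanVolume

__all__ = ["saft_reconstruct"]


def saft_reconstruct(
    scan: ScanVolume,
    geom: TransducerGeometry,
    cfg: AcousticConfig,
    aperture_half_angle: float | None = None,
    *,
    z_values: np.ndarray,
    return_diagnostics: bool = False,
):
    """Delay-and-sum reconstruction onto the scan's lateral grid.

    Parameters
    ----------
    scan : ScanVolume
        Preprocessed (band-limited) A-scan raster.
    geom, cfg :
        Detector geometry and acoustic constants (focal delay F/c must lie
        inside the recorded window).
    aperture_half_angle : float, optional
        Half opening angle of the acceptance cone; defaults to
        arcsin(aperture_radius / focal_distance).
    z_values : array
        Voxel depths (m) relative to the focal plane, positive deeper.
    return_diagnostics : bool
        Also return ``{"empty_voxels": int}`` counting voxels with no
        contributing A-scan (set to 0).
    """
    if aperture_half_angle is None:
        aperture_half_angle = geom.acceptance_half_angle
    z_values = np.asarray(z_values, dtype=float)
    c = cfg.speed_of_sound
    t_focal = geom.focal_distance / c
    nt = scan.ascans.shape[2]
    if not (scan.t_start <= t_focal <= scan.t_start + (nt - 1) * scan.dt):
        raise ValueError("focal delay F/c lies outside the recorded time window")

    nx, ny, _ = scan.ascans.shape
    tan_a = np.tan(aperture_half_angle)
    out = np.zeros((nx, ny, z_values.size))
    counts = np.zeros((nx, ny, z_values.size))

    for iz, z in enumerate(z_values):
        r_max = abs(z) * tan_a
        mx = int(np.floor(r_max / scan.dx + 1e-9))
        my = int(np.floor(r_max / scan.dy + 1e-9))
        acc = np.zeros((nx, ny))
        cnt = np.zeros((nx, ny))
        for ox in range(-mx, mx + 1):
            for oy in range(-my, my + 1):
                r = np.hypot(ox * scan.dx, oy * scan.dy)
                if r > r_max * (1 + 1e-9) and (ox or oy):
                    continue
                d = np.hypot(r, z)
                tau = t_focal + np.sign(z) * d / c
                pos = (tau - scan.t_start) / scan.dt
                j = int(np.floor(pos))
                if j < 0 or j + 1 >= nt:
                    continue
                frac = pos - j
                sampled = (1.0 - frac) * scan.ascans[:, :, j] \
                    + frac * scan.ascans[:, :, j + 1]
                # voxel v takes scan position s = v - (ox, oy)
                vx0, vx1 = max(ox, 0), min(nx + ox, nx)
                vy0, vy1 = max(oy, 0), min(ny + oy, ny)
                if vx0 >= vx1 or vy0 >= vy1:
                    continue
                acc[vx0:vx1, vy0:vy1] += sampled[vx0 - ox:vx1 - ox,
                                                 vy0 - oy:vy1 - oy]
                cnt[vx0:vx1, vy0:vy1] += 1.0
        nonzero = cnt > 0
        acc[nonzero] /= cnt[nonzero]
        out[:, :, iz] = acc
        counts[:, :, iz] = cnt

    vol = AbsorptionVolume(values=out, dx=scan.dx, dy=scan.dy,
                           dz=float(np.median(np.diff(z_values)))
                           if z_values.size > 1 else scan.dx)
    if return_diagnostics:
        return vol, {"empty_voxels": int(np.count_nonzero(counts == 0)),
                     "contributors_per_voxel": counts}
    return vol
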