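"""Per-pulse energy/time correction and band-limiting of raw A-scans.

Raw A-scans fluctuate with the excitation laser: pulse energy varies shot to
shot and the emission instant jitters relative to the acquisition trigger.
Both are corrected per A-scan from the photodiode-derived pulse records.
Band-limiting to the detector's useful band (1-90 MHz at 250 MHz sampling)
then suppresses out-of-band noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = ["ScanVolume", "PulseRecords", "correct_pulses", "bandpass"]

DEFAULT_BAND = (1.0e6, 90.0e6)


@dataclass
class ScanVolume:
    """Raster of A-scans over scan positions (x, y) and time.

    ``ascans[ix, iy, it]`` is the amplitude at scan position
    (ix * dx, iy * dy) and time ``t_start + it * dt``.
    """

    ascans: np.ndarray
    dx: float
    dy: float
    dt: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.ascans = np.asarray(self.ascans, dtype=float)
        if self.ascans.ndim != 3:
            raise ValueError("ascans must be 3D (x, y, t)")
        if not np.all(np.isfinite(self.ascans)):
            raise ValueError("A-scan values must be finite")
        if min(self.dx, self.dy, self.dt) <= 0:
            raise ValueError("dx, dy, dt must be positive")

    @property
    def shape(self):
        return self.ascans.shape

    def copy_with(self, ascans: np.ndarray) -> "ScanVolume":
        return ScanVolume(ascans=ascans, dx=self.dx, dy=self.dy, dt=self.dt,
                          t_start=self.t_start)


@dataclass
class PulseRecords:
    """Per-A-scan laser-pulse metadata: energy and emission-time offset.

    One record per scan position; shapes match the scan's lateral grid.
    """

    energies: np.ndarray       # (nx, ny), a.u., > 0
    time_offsets: np.ndarray = field(default=None)  # (nx, ny), s

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.time_offsets is None:
            self.time_offsets = np.zeros_like(self.energies)
        self.time_offsets = np.asarray(self.time_offsets, dtype=float)
        if self.time_offsets.shape != self.energies.shape:
            raise ValueError("energies and time_offsets must share a shape")


def correct_pulses(scan: ScanVolume, pulses: PulseRecords,
                   reference_energy: float = 1.0) -> ScanVolume:
    """Normalize pulse energy and remove emission-time jitter per A-scan.

    Each A-scan is divided by (energy / reference_energy), then advanced by
    its emission offset via a band-limited frequency-domain phase ramp
    (linear phase), so sub-sample jitter is corrected without nearest-sample
    rounding.  Identity records (all energies equal to the reference, zero
    offsets) return the input bitwise.
    """
    if pulses.energies.shape != scan.ascans.shape[:2]:
        raise ValueError("need exactly one pulse record per A-scan")
    bad = np.argwhere(pulses.energies <= 0)
    if bad.size:
        ix, iy = bad[0]
        raise ValueError(f"non-positive pulse energy at scan position (ix={ix}, iy={iy})")

    out = scan.ascans / (pulses.energies / reference_energy)[:, :, None]
    offsets = pulses.time_offsets
    if np.any(offsets != 0.0):
        nt = out.shape[2]
        freqs = np.fft.rfftfreq(nt, d=scan.dt)
        spec = np.fft.rfft(out, axis=2)
        # y(t) = x(t + offset): advance the trace so the arrival lands where a
        # jitter-free pulse would have put it.
        spec *= np.exp(2j * np.pi * freqs[None, None, :] * offsets[:, :, None])
        out = np.fft.irfft(spec, n=nt, axis=2)
    return scan.copy_with(out)


def bandpass(scan: ScanVolume, f_lo: float = DEFAULT_BAND[0],
             f_hi: float = DEFAULT_BAND[1], order: int = 4) -> ScanVolume:
    """Zero-phase Butterworth band-pass along the time axis.

    Forward-backward filtering keeps arrival times intact — essential for the
    delay-based SAFT and for consistency with the forward model.  Band edges
    must respect Nyquist.
    """
    fs = 1.0 / scan.dt
    if not (0.0 < f_lo < f_hi < fs / 2.0):
        raise ValueError(
            f"band edges must satisfy 0 < f_lo < f_hi < fs/2 "
            f"(got {f_lo:.3e}, {f_hi:.3e} at fs={fs:.3e})"
        )
    sos = butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return scan.copy_with(sosfiltfilt(sos, scan.ascans, axis=2))
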