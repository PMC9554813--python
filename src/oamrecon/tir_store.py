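"""4D total-impulse-response (TIR) container, calibration assembly and HDF5 I/O.

The TIR tabulates the detected waveform of a point-like absorber as a
function of its position relative to the transducer: lateral offsets
(dx, dy), depth z (relative to the focal plane, positive deeper) and time.
Two provenances exist: ``simulated`` (geometric virtual-element model) and
``calibrated`` (assembled from microsphere-scan frames).

Time axes are stored per depth plane: plane iz uses ``nt`` local samples
starting at absolute time ``t0_per_z[iz]``, so near and far planes need not
share one long buffer.  All per-plane offsets are integer multiples of ``dt``
apart, which the forward model relies on.

Lateral offset sign convention (fixed here, used by the forward model):
``dx = (voxel x) - (scan position x)``.  Scanning the transducer over a fixed
sphere is stored as if the sphere moved relative to a fixed transducer.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "GridSpec",
    "TIR4D",
    "CalibrationFrames",
    "assemble_ctir",
    "estimate_focus",
    "save_tir",
    "load_tir",
    "save_scan",
    "load_scan",
    "save_volume",
    "load_volume",
]

FORMAT_VERSION = 1

#: Default sampling interval: 4 ns at the 250 MHz acquisition rate.
DEFAULT_DT = 4.0e-9
#: Default isotropic spatial step of the calibration / reconstruction grids.
DEFAULT_STEP = 20.0e-6
#: Default lateral support radius of the TIR (m).
DEFAULT_LATERAL_RADIUS = 1.0e-3


def center_index(n: int) -> int:
    """Index of the on-axis / zero-offset sample of an n-point centred grid."""
    return (n - 1) // 2


@dataclass(frozen=True)
class GridSpec:
    """Spatial/temporal grid of a TIR (and of matching scan/recon volumes).

    Lateral offsets and depths are centred on the focus: index i maps to
    ``(i - center_index(n)) * step``.  ``nt`` is the per-plane time-sample
    count; absolute plane start times live on the TIR itself.
    """

    dx: float = DEFAULT_STEP
    dy: float = DEFAULT_STEP
    dz: float = DEFAULT_STEP
    nx: int = 101
    ny: int = 101
    nz: int = 151
    dt: float = DEFAULT_DT
    nt: int = 0
    lateral_radius: float = DEFAULT_LATERAL_RADIUS

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz, self.dt) <= 0:
            raise ValueError("all grid steps must be positive")
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid counts must be >= 1")

    def x_offsets(self) -> np.ndarray:
        return (np.arange(self.nx) - center_index(self.nx)) * self.dx

    def y_offsets(self) -> np.ndarray:
        return (np.arange(self.ny) - center_index(self.ny)) * self.dy

    def z_values(self) -> np.ndarray:
        return (np.arange(self.nz) - center_index(self.nz)) * self.dz

    def replace(self, **kw) -> "GridSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class TIR4D:
    """4D TIR tensor over (dx index, dy index, z index, t index).

    ``t0_per_z[iz]`` is the absolute start time (s) of plane iz's local time
    axis; all offsets differ by integer multiples of ``grid.dt``.
    """

    values: np.ndarray          # (nx, ny, nz, nt)
    grid: GridSpec
    t0_per_z: np.ndarray        # (nz,)
    provenance: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.t0_per_z = np.asarray(self.t0_per_z, dtype=float)
        g = self.grid
        expected = (g.nx, g.ny, g.nz, g.nt if g.nt else self.values.shape[3])
        if self.values.shape != expected:
            raise ValueError(
                f"TIR values shape {self.values.shape} does not match grid {expected}"
            )
        if self.t0_per_z.shape != (g.nz,):
            raise ValueError("t0_per_z must have one entry per depth plane")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TIR values must be finite")
        if g.nt == 0:
            self.grid = g.replace(nt=self.values.shape[3])
        if self.provenance not in ("simulated", "calibrated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def on_axis_trace(self, iz: int) -> np.ndarray:
        return self.values[center_index(self.grid.nx), center_index(self.grid.ny), iz, :]

    def energy(self) -> float:
        return float(np.sum(self.values**2))


@dataclass
class CalibrationFrames:
    """Repeated per-node A-scan frames of a microsphere calibration scan.

    ``values`` has shape (nx, ny, nz, n_repeat, nt); missing nodes/repeats are
    marked NaN.  Plane start times follow the TIR convention.
    """

    values: np.ndarray
    t0_per_z: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 5:
            raise ValueError("calibration frames must be 5D (nx, ny, nz, n_repeat, nt)")


def assemble_ctir(frames: CalibrationFrames, grid: GridSpec | None = None,
                  n_avg: int = 3) -> TIR4D:
    """Average repeated calibration frames into a calibrated TIR.

    Each grid node's ``n_avg`` repeats are averaged (3 by default, the
    SNR-improvement averaging of the calibration protocol), then a single
    global normalization scales the assembled tensor so the on-axis
    focal-plane trace has peak absolute amplitude exactly 1.  Per-depth
    scaling is never applied: it would destroy the depth-sensitivity falloff
    the model-based inversion corrects for.
    """
    vals = frames.values
    if vals.shape[3] != n_avg:
        raise ValueError(
            f"expected {n_avg} repeats per node, frames carry {vals.shape[3]}"
        )
    bad = np.isnan(vals)
    if bad.any():
        ix, iy, iz, rep, _ = np.argwhere(bad)[0]
        raise ValueError(
            f"missing data at grid node (ix={ix}, iy={iy}, iz={iz}), repeat {rep}"
        )
    mean = vals.mean(axis=3)
    g = grid if grid is not None else frames.grid
    g = g.replace(nt=mean.shape[3])
    tir = TIR4D(values=mean, grid=g, t0_per_z=frames.t0_per_z,
                provenance="calibrated")
    iz_focus = estimate_focus(tir)
    peak = np.max(np.abs(tir.on_axis_trace(iz_focus)))
    if peak == 0:
        raise ValueError("assembled TIR has an all-zero focal trace")
    tir.values = tir.values / peak
    tir.meta["focal_plane_index"] = int(iz_focus)
    return tir


def estimate_focus(tir: TIR4D) -> int:
    """Depth index of the focal plane, from the on-axis peak amplitude.

    The absolute axial position of the calibration sphere relative to the
    transducer is unknown in practice, so the focal plane is located from the
    TIR itself: the plane whose on-axis trace has the largest peak absolute
    amplitude.  Ties break toward the shallower plane (lower index).
    """
    g = tir.grid
    if g.nz < 3:
        raise ValueError("need at least 3 depth planes to estimate the focus")
    prof = np.max(np.abs(
        tir.values[center_index(g.nx), center_index(g.ny), :, :]), axis=1)
    if np.allclose(prof, prof[0]):
        warnings.warn("flat on-axis amplitude profile; returning the middle plane")
        return g.nz // 2
    return int(np.argmax(prof))


# ---------------------------------------------------------------------------
# HDF5 I/O.  One self-describing container family: /tir, /scan or /volume
# dataset plus grid attributes; memory-mappable layout (x fastest).
# ---------------------------------------------------------------------------

_GRID_ATTRS = ("dx", "dy", "dz", "nx", "ny", "nz", "dt", "nt", "lateral_radius")


def _write_grid(obj: h5py.Group, grid: GridSpec) -> None:
    for name in _GRID_ATTRS:
        obj.attrs[name] = getattr(grid, name)


def _read_grid(obj: h5py.Group) -> GridSpec:
    kw = {}
    for name in _GRID_ATTRS:
        if name not in obj.attrs:
            raise KeyError(f"file is missing required grid attribute {name!r}")
        kw[name] = obj.attrs[name]
    for name in ("nx", "ny", "nz", "nt"):
        kw[name] = int(kw[name])
    return GridSpec(**kw)


def _check_version(f: h5py.File, path) -> None:
    if "format_version" not in f.attrs:
        raise KeyError(f"{path}: missing required attribute 'format_version'")
    version = int(f.attrs["format_version"])
    if version != FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported format version {version} (expected {FORMAT_VERSION})"
        )


def save_tir(tir: TIR4D, path) -> None:
    """Write a TIR4D losslessly to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "tir"
        f.attrs["provenance"] = tir.provenance
        f.attrs["meta_json"] = json.dumps(tir.meta, default=str)
        _write_grid(f, tir.grid)
        f.create_dataset("tir", data=tir.values)
        f.create_dataset("t0_per_z", data=tir.t0_per_z)


def load_tir(path) -> TIR4D:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        if "tir" not in f:
            raise KeyError(f"{path}: missing dataset 'tir'")
        grid = _read_grid(f)
        return TIR4D(
            values=f["tir"][()],
            grid=grid,
            t0_per_z=f["t0_per_z"][()],
            provenance=str(f.attrs.get("provenance", "simulated")),
            meta=json.loads(f.attrs.get("meta_json", "{}")),
        )


def save_scan(scan, path) -> None:
    """Write a ScanVolume to the shared HDF5 container family."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "scan"
        f.attrs["dx"] = scan.dx
        f.attrs["dy"] = scan.dy
        f.attrs["dt"] = scan.dt
        f.attrs["t_start"] = scan.t_start
        f.create_dataset("scan", data=scan.ascans)


def load_scan(path):
    from .preprocess import ScanVolume

    with h5py.File(path, "r") as f:
        _check_version(f, path)
        if "scan" not in f:
            raise KeyError(f"{path}: missing dataset 'scan'")
        for name in ("dx", "dy", "dt", "t_start"):
            if name not in f.attrs:
                raise KeyError(f"{path}: missing required attribute {name!r}")
        return ScanVolume(
            ascans=f["scan"][()],
            dx=float(f.attrs["dx"]),
            dy=float(f.attrs["dy"]),
            dt=float(f.attrs["dt"]),
            t_start=float(f.attrs["t_start"]),
        )


def save_volume(vol, path) -> None:
    """Write an AbsorptionVolume to the shared HDF5 container family."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "volume"
        f.attrs["dx"] = vol.dx
        f.attrs["dy"] = vol.dy
        f.attrs["dz"] = vol.dz
        f.create_dataset("volume", data=vol.values)


def load_volume(path):
    from .forward_model import AbsorptionVolume

    with h5py.File(path, "r") as f:
        _check_version(f, path)
        if "volume" not in f:
            raise KeyError(f"{path}: missing dataset 'volume'")
        return AbsorptionVolume(
            values=f["volume"][()],
            dx=float(f.attrs["dx"]),
            dy=float(f.attrs["dy"]),
            dz=float(f.attrs["dz"]),
        )
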