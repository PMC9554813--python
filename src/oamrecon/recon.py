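"""Model/Results interface over the reconstruction algorithms.

``ModelBasedReconstruction`` and ``SAFT`` are built from data (a scan volume
plus, respectively, a TIR or the detector geometry); their ``fit()`` returns
a ``ReconstructionResult`` carrying the reconstructed volume, the residual
history and a ``summary()`` table.  The functional layer
(:func:`oamrecon.inversion.lsqr_solve`, :func:`oamrecon.saft.saft_reconstruct`)
remains the computational core; these classes organize it.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .acoustics import AcousticConfig
from .forward_model import AbsorptionVolume, ModelMatrix, build_model
from .geometry import TransducerGeometry
from .inversion import ReconConfig, lsqr_solve
from .preprocess import ScanVolume
from .saft import saft_reconstruct
from .tir_store import TIR4D

__all__ = ["ModelBasedReconstruction", "SAFT", "ReconstructionResult"]


@dataclass
class ReconstructionResult:
    """Fitted reconstruction: volume, diagnostics, and a summary table."""

    volume: AbsorptionVolume
    method: str
    n_iterations: int | None = None
    lam: float | None = None
    residual_norms: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)
    runtime_s: float = 0.0

    def map_projection(self, axis: int = 2) -> np.ndarray:
        """Maximum amplitude projection of |volume| along one axis."""
        return np.max(np.abs(self.volume.values), axis=axis)

    def summary(self) -> str:
        v = self.volume
        lines = [
            f"{self.method} reconstruction",
            "-" * 40,
            f"volume shape       : {v.values.shape}",
            f"voxel size (um)    : {v.dx * 1e6:.1f} x {v.dy * 1e6:.1f} x "
            f"{v.dz * 1e6:.1f}",
            f"peak |amplitude|   : {np.max(np.abs(v.values)):.4g}",
            f"runtime (s)        : {self.runtime_s:.2f}",
        ]
        if self.n_iterations is not None:
            lines.append(f"iterations         : {self.n_iterations}")
        if self.lam is not None:
            lines.append(f"regularization lam : {self.lam:.4g}")
        if self.residual_norms is not None and self.residual_norms.size:
            lines.append(
                f"residual norm      : {self.residual_norms[0]:.4g} -> "
                f"{self.residual_norms[-1]:.4g}"
            )
        for k, val in self.diagnostics.items():
            if np.isscalar(val):
                lines.append(f"{k:<19}: {val}")
        return "\n".join(lines)


class ModelBasedReconstruction:
    """Iterative model-based reconstruction (MBR) of one scan volume.

    Built from a scan and a TIR — calibrated (cMBR) or simulated (sMBR); the
    fit solves the damped least-squares problem with LSQR.
    """

    def __init__(self, scan: ScanVolume, tir: TIR4D | ModelMatrix,
                 n_iterations: int = 20, lam: float | None = None,
                 nonnegativity: bool = False):
        self.scan = scan
        self.model = tir if isinstance(tir, ModelMatrix) else build_model(tir)
        self.provenance = getattr(tir, "provenance", "simulated")
        self.config = ReconConfig(n_iterations=n_iterations, lam=lam,
                                  nonnegativity=nonnegativity)

    def fit(self) -> ReconstructionResult:
        import dataclasses

        from .forward_model import operator_norm
        from .inversion import LAMBDA_FRACTION

        t0 = time.perf_counter()
        cfg = self.config
        if cfg.lam is None:
            nx, ny, _ = self.scan.ascans.shape
            cfg = dataclasses.replace(
                cfg, lam=LAMBDA_FRACTION * operator_norm(
                    self.model, (nx, ny, self.model.nz), seed=cfg.seed))
        vol, hist = lsqr_solve(self.model, self.scan, cfg)
        lam = cfg.lam
        name = "cMBR" if self.provenance == "calibrated" else "sMBR"
        return ReconstructionResult(
            volume=vol,
            method=name,
            n_iterations=self.config.n_iterations,
            lam=lam,
            residual_norms=hist,
            runtime_s=time.perf_counter() - t0,
        )


class SAFT:
    """Synthetic-aperture (delay-and-sum) baseline for one scan volume."""

    def __init__(self, scan: ScanVolume, geom: TransducerGeometry,
                 cfg: AcousticConfig, z_values,
                 aperture_half_angle: float | None = None):
        self.scan = scan
        self.geom = geom
        self.cfg = cfg
        self.z_values = np.asarray(z_values, dtype=float)
        self.aperture_half_angle = aperture_half_angle

    def fit(self) -> ReconstructionResult:
        t0 = time.perf_counter()
        vol, diag = saft_reconstruct(
            self.scan, self.geom, self.cfg, self.aperture_half_angle,
            z_values=self.z_values, return_diagnostics=True)
        return ReconstructionResult(
            volume=vol,
            method="SAFT",
            diagnostics={"empty_voxels": diag["empty_voxels"]},
            runtime_s=time.perf_counter() - t0,
        )
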