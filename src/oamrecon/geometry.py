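"""Spherically focused detector geometry and virtual-element discretization.

The detector is a spherical cap of radius equal to the focal distance, with a
central circular hole for light delivery.  Its active surface is discretized
into virtual elements on a regular (polar, azimuthal) angular grid; each
element carries its exact spherical-patch area, which weights its contribution
to the spatial impulse response.

Coordinate convention (shared by every module): the acoustic axis is z, the
origin sits at the geometric focus, and z increases away from the detector
(deeper into the sample).  The detector surface therefore lies at z < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TransducerGeometry", "ElementSet", "make_virtual_elements"]

#: Defaults for the PVDF detector: 7 mm focal distance, 3.2 mm aperture
#: radius, 1.2 mm hole diameter.
DEFAULT_FOCAL_DISTANCE = 7.0e-3
DEFAULT_APERTURE_RADIUS = 3.2e-3
DEFAULT_HOLE_RADIUS = 0.6e-3


@dataclass(frozen=True)
class TransducerGeometry:
    """Spherically focused detector with a central hole.

    Parameters
    ----------
    focal_distance : float
        Radius of curvature of the detector surface, i.e. distance from every
        surface point to the geometric focus (m).
    aperture_radius : float
        Radius of the projection of the active surface onto the aperture
        plane (m).
    hole_radius : float
        Radius of the central hole in the aperture plane (m).
    """

    focal_distance: float = DEFAULT_FOCAL_DISTANCE
    aperture_radius: float = DEFAULT_APERTURE_RADIUS
    hole_radius: float = DEFAULT_HOLE_RADIUS

    def __post_init__(self) -> None:
        if not (0.0 <= self.hole_radius < self.aperture_radius < self.focal_distance):
            raise ValueError(
                "invalid transducer geometry: require "
                "0 <= hole_radius < aperture_radius < focal_distance, got "
                f"hole={self.hole_radius!r}, aperture={self.aperture_radius!r}, "
                f"focal={self.focal_distance!r}"
            )

    @property
    def hole_rim_angle(self) -> float:
        """Polar angle (from the acoustic axis) of the hole rim (rad)."""
        return float(np.arcsin(self.hole_radius / self.focal_distance))

    @property
    def aperture_rim_angle(self) -> float:
        """Polar angle of the outer aperture rim (rad)."""
        return float(np.arcsin(self.aperture_radius / self.focal_distance))

    @property
    def acceptance_half_angle(self) -> float:
        """Half opening angle of the acceptance cone, arcsin(a/F) (rad)."""
        return self.aperture_rim_angle

    def cap_area(self) -> float:
        """Analytic area of the active annular spherical cap (m^2).

        2*pi*F*(h_aperture - h_hole) with h = F - sqrt(F^2 - r^2).
        """
        f = self.focal_distance
        h_ap = f - np.sqrt(f**2 - self.aperture_radius**2)
        h_hole = f - np.sqrt(f**2 - self.hole_radius**2)
        return float(2.0 * np.pi * f * (h_ap - h_hole))


@dataclass(frozen=True)
class ElementSet:
    """Virtual elements covering the active detector surface.

    ``centers`` are 3D points (m) on the sphere of radius ``focal_distance``
    about the focus (origin); ``areas`` are the exact spherical-patch areas
    (m^2).  Elements live at z < 0 by the shared coordinate convention.
    """

    centers: np.ndarray  # (count, 3)
    areas: np.ndarray    # (count,)
    focal_distance: float = field(default=DEFAULT_FOCAL_DISTANCE)

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 3:
            raise ValueError("centers must have shape (count, 3)")
        if areas.shape != (centers.shape[0],):
            raise ValueError("areas must have shape (count,)")
        if np.any(areas <= 0):
            raise ValueError("all element areas must be positive")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "areas", areas)

    @property
    def count(self) -> int:
        return self.centers.shape[0]

    def total_area(self) -> float:
        return float(self.areas.sum())


def make_virtual_elements(
    geom: TransducerGeometry, n_polar: int = 25, n_azimuth: int = 40
) -> ElementSet:
    """Discretize the active surface into ``n_polar * n_azimuth`` elements.

    The polar angle between the hole rim and the aperture rim is divided
    uniformly, as is the azimuthal angle.  Each element center is placed at
    the area centroid of its spherical patch (projected back onto the
    sphere), and each element carries the exact patch area
    ``F^2 * dphi * (cos(theta_1) - cos(theta_2))``.  Uniform polar spacing
    means areas vary with polar angle; they must be carried per element.

    Parameters
    ----------
    geom : TransducerGeometry
    n_polar, n_azimuth : int
        Number of polar / azimuthal subdivisions (default 25 x 40 = 1000).
    """
    if n_polar < 1 or n_azimuth < 1:
        raise ValueError("n_polar and n_azimuth must be >= 1")
    f = geom.focal_distance
    theta_edges = np.linspace(geom.hole_rim_angle, geom.aperture_rim_angle, n_polar + 1)
    phi_edges = np.linspace(0.0, 2.0 * np.pi, n_azimuth + 1)

    t1 = theta_edges[:-1]
    t2 = theta_edges[1:]
    p1 = phi_edges[:-1]
    p2 = phi_edges[1:]
    dphi = p2 - p1  # constant, kept as array for clarity

    # Exact patch areas: F^2 * dphi * (cos t1 - cos t2), outer product (polar, azimuth)
    band = np.cos(t1) - np.cos(t2)  # (n_polar,)
    areas = (f**2) * np.outer(band, dphi)  # (n_polar, n_azimuth)

    # Area centroid of each patch, projected onto the sphere.  The centroid
    # direction components factor into polar and azimuthal integrals:
    #   z' ~ -int cos(t) sin(t) dt * dphi
    #   x' ~  int sin^2(t) dt * int cos(phi) dphi   (likewise y' with sin)
    iz = 0.5 * (np.sin(t2) ** 2 - np.sin(t1) ** 2)  # (n_polar,)
    ixy = 0.5 * (t2 - t1) - 0.25 * (np.sin(2.0 * t2) - np.sin(2.0 * t1))
    cphi = np.sin(p2) - np.sin(p1)  # (n_azimuth,)
    sphi = np.cos(p1) - np.cos(p2)

    cx = np.outer(ixy, cphi)
    cy = np.outer(ixy, sphi)
    cz = -np.outer(iz, dphi)  # detector lies at z < 0
    dirs = np.stack([cx, cy, cz], axis=-1).reshape(-1, 3)
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    centers = f * dirs / norms

    return ElementSet(centers=centers, areas=areas.reshape(-1), focal_distance=f)
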