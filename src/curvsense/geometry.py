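"""Analytic geometry of a sinusoidally buckled bilayer.

The synthetic membrane is a 1D buckle: the midplane is the graph
``z = A sin(q x)`` with ``q = 2*pi*mode/box_x``, invariant along *y*.  The two
leaflet phosphate surfaces are exact parallel (normal-offset) surfaces of the
midplane at distance ``half_thickness``:

    P_s(x, y) = (x - s t f'(x)/g(x),  y,  f(x) + s t/g(x)),
    g = sqrt(1 + f'^2),  s = +1 (upper) / -1 (lower).

Parallel surfaces reproduce the crest/trough area imbalance of a curved
bilayer — the outward-bent leaflet is stretched by the factor ``1 - s t k``
(``k`` the midplane curve curvature) — without modelling individual lipids.

All lengths are in nm, curvatures in 1/nm.  The signed mean curvature
convention is shared with :mod:`curvsense.surface`: positive curvature is
convex toward the aqueous phase bathing the leaflet in question, so a crest
is positive for the upper leaflet and negative for the lower one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError

__all__ = [
    "BuckleGeometry",
    "midplane_height",
    "midplane_slope",
    "midplane_curvature",
    "leaflet_surface_point",
    "leaflet_mean_curvature",
    "signed_membrane_curvature",
    "leaflet_area_element",
    "leaflet_inward_normal",
    "leaflet_lateral_position",
]

LEAFLET_SIGN = {"upper": 1.0, "lower": -1.0}


def _leaflet_sign(leaflet: str) -> float:
    try:
        return LEAFLET_SIGN[leaflet]
    except KeyError:
        raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}") from None


@dataclass(frozen=True)
class BuckleGeometry:
    """Parameters of the synthetic buckled membrane.

    Parameters
    ----------
    box_x, box_y : float
        Lateral box lengths (nm); the buckle runs along x.
    amplitude : float
        Buckle amplitude A (nm).
    mode : int
        Number of buckle periods across the box.
    half_thickness : float
        Midplane-to-phosphate offset t (nm).
    bead_density : float
        Phosphate beads per nm^2 per leaflet (projected area).
    """

    box_x: float = 20.0
    box_y: float = 10.0
    amplitude: float = 2.0
    mode: int = 1
    half_thickness: float = 2.0
    bead_density: float = 1.5

    def __post_init__(self):
        if self.box_x <= 0 or self.box_y <= 0:
            raise InvalidGeometryError("box lengths must be positive")
        if self.amplitude < 0:
            raise InvalidGeometryError("amplitude must be non-negative")
        if self.half_thickness <= 0:
            raise InvalidGeometryError("half_thickness must be positive")
        if self.mode < 1 or int(self.mode) != self.mode:
            raise InvalidGeometryError("mode must be a positive integer")
        if self.bead_density <= 0:
            raise InvalidGeometryError("bead_density must be positive")
        # offset must stay below the minimal radius of curvature of the
        # midplane (max |f''| = A q^2 at the extrema) or the inner parallel
        # surface self-intersects
        if self.half_thickness * self.max_midplane_curvature >= 1.0:
            raise InvalidGeometryError(
                "half_thickness * amplitude * (2*pi*mode/box_x)^2 must be < 1 "
                "(normal offset exceeds the minimal radius of curvature)"
            )

    @property
    def wavenumber(self) -> float:
        """q = 2*pi*mode/box_x (1/nm)."""
        return 2.0 * math.pi * self.mode / self.box_x

    @property
    def max_midplane_curvature(self) -> float:
        return self.amplitude * self.wavenumber**2

    @property
    def box_z(self) -> float:
        """A box height comfortably containing both leaflets (nm)."""
        return 2.0 * (self.amplitude + self.half_thickness) + 4.0

    @property
    def box(self) -> tuple[float, float, float]:
        return (self.box_x, self.box_y, self.box_z)


def midplane_height(geometry: BuckleGeometry, x) -> np.ndarray:
    """Midplane height ``A sin(q x)``; periodic in x."""
    return geometry.amplitude * np.sin(geometry.wavenumber * np.asarray(x, dtype=float))


def midplane_slope(geometry: BuckleGeometry, x) -> np.ndarray:
    q = geometry.wavenumber
    return geometry.amplitude * q * np.cos(q * np.asarray(x, dtype=float))


def _second_derivative(geometry: BuckleGeometry, x) -> np.ndarray:
    q = geometry.wavenumber
    return -geometry.amplitude * q * q * np.sin(q * np.asarray(x, dtype=float))


def midplane_curvature(geometry: BuckleGeometry, x) -> np.ndarray:
    """Signed curve curvature k = f'' / (1+f'^2)^(3/2) of the midplane.

    The sign refers to the upward midplane normal: negative at crests.
    """
    fp = midplane_slope(geometry, x)
    return _second_derivative(geometry, x) / (1.0 + fp**2) ** 1.5


def leaflet_surface_point(geometry: BuckleGeometry, x, y, leaflet: str) -> np.ndarray:
    """Point of the leaflet parallel surface over midplane parameter (x, y).

    Returns an array of shape ``(..., 3)``.  The y coordinate passes through
    unchanged (the buckle is y-invariant).
    """
    s = _leaflet_sign(leaflet)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fp = midplane_slope(geometry, x)
    g = np.sqrt(1.0 + fp**2)
    t = geometry.half_thickness
    px = x - s * t * fp / g
    pz = midplane_height(geometry, x) + s * t / g
    return np.stack(np.broadcast_arrays(px, y, pz), axis=-1)


def leaflet_mean_curvature(geometry: BuckleGeometry, x, leaflet: str) -> np.ndarray:
    """Signed mean curvature of a leaflet surface at midplane parameter x.

    For a parallel surface at offset ``s t`` the non-zero principal curvature
    is ``k/(1 - s t k)``; the mean curvature is half that.  The sign is
    flipped so that geometry convex toward the leaflet's aqueous side is
    positive (upper leaflet: crest positive; lower leaflet: trough positive).
    """
    s = _leaflet_sign(leaflet)
    k = midplane_curvature(geometry, x)
    return -s * k / (2.0 * (1.0 - s * geometry.half_thickness * k))


def signed_membrane_curvature(geometry: BuckleGeometry, x, leaflet: str) -> np.ndarray:
    """Signed mean curvature of the membrane midplane, leaflet convention.

    This is the membrane curvature a peptide on the given leaflet samples:
    ``-s k(x)/2`` with s = +1 (upper) / -1 (lower), so a crest is positive
    for the upper-leaflet peptide and negative for the lower one.  Unlike
    the leaflet-surface curvature it has a symmetric accessible range.
    """
    s = _leaflet_sign(leaflet)
    return -s * midplane_curvature(geometry, x) / 2.0


def leaflet_area_element(geometry: BuckleGeometry, x, leaflet: str) -> np.ndarray:
    """Area element dA/(dx dy) of the leaflet surface in midplane parameters."""
    s = _leaflet_sign(leaflet)
    fp = midplane_slope(geometry, x)
    g = np.sqrt(1.0 + fp**2)
    k = midplane_curvature(geometry, x)
    return (1.0 - s * geometry.half_thickness * k) * g


def leaflet_inward_normal(geometry: BuckleGeometry, x, leaflet: str) -> np.ndarray:
    """Unit normal pointing from the leaflet surface toward the membrane core."""
    s = _leaflet_sign(leaflet)
    x = np.asarray(x, dtype=float)
    fp = midplane_slope(geometry, x)
    g = np.sqrt(1.0 + fp**2)
    nx = s * fp / g
    nz = -s / g
    return np.stack(np.broadcast_arrays(nx, np.zeros_like(nx), nz), axis=-1)


def leaflet_lateral_position(geometry: BuckleGeometry, x, leaflet: str) -> np.ndarray:
    """Lateral (x) coordinate of the leaflet surface point over parameter x."""
    s = _leaflet_sign(leaflet)
    fp = midplane_slope(geometry, np.asarray(x, dtype=float))
    g = np.sqrt(1.0 + fp**2)
    return np.asarray(x, dtype=float) - s * geometry.half_thickness * fp / g
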