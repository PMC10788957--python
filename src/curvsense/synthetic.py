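"""Synthetic buckled-membrane frames with curvature-sensing peptides.

Every MD-free verification in this package runs on trajectories produced
here: phosphate-like beads laid on the two analytic leaflet surfaces of a
:class:`~curvsense.geometry.BuckleGeometry` (jittered grid + Gaussian noise
along the local normal), and one or more peptide centres of mass placed by
an explicit Boltzmann curvature-preference model,

    p(x) dx  proportional to  exp(-kappa (H(x) - H0)^2) dA(x),

where ``H`` is the signed membrane (midplane) mean curvature under the
peptide's leaflet sign convention and ``dA`` the local area element of the
peptide's leaflet surface.  With ``kappa = 0`` the peptide samples the
leaflet area measure exactly — the null a non-sensing particle obeys — so
its raw curvature histogram is biased toward positive curvature (crests
offer the upper leaflet more area than troughs, and vice versa), and
reweighting by the accessible-curvature distribution must return a uniform
histogram.  The peptide is then displaced ``depth`` nm along the
inward surface normal and blurred by isotropic Gaussian noise.

Frames are independent draws (no diffusion dynamics) and fully reproducible
from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geom
from .errors import InsufficientSamplingError
from .geometry import BuckleGeometry
from .surface import n_basis_functions

__all__ = [
    "PeptideModel",
    "PeptideRecord",
    "MembraneFrame",
    "generate_frame",
    "place_peptide",
    "generate_trajectory",
    "analytic_accessible_histogram",
]

#: default Fourier truncation used downstream; generation checks bead counts
#: against it so frames are always fittable
DEFAULT_FIT_MODES = (6, 2)


@dataclass(frozen=True)
class PeptideModel:
    """Generative parameters of a synthetic curvature-sensing peptide.

    Parameters
    ----------
    leaflet : str
        'upper' or 'lower'.
    preferred_curvature : float
        H0, the membrane curvature the peptide favours (1/nm, leaflet sign
        convention).
    stiffness : float
        kappa (nm^2), scale of the Boltzmann exponent; 0 = no preference.
    depth : float
        Insertion depth along the inward leaflet normal from the phosphate
        surface (nm, positive = deeper).
    positional_noise : float
        Isotropic Gaussian blur of the final position (nm).
    """

    leaflet: str
    preferred_curvature: float = 0.0
    stiffness: float = 0.0
    depth: float = 0.0
    positional_noise: float = 0.1

    def __post_init__(self):
        if self.leaflet not in ("upper", "lower"):
            raise ValueError(f"leaflet must be 'upper' or 'lower', got {self.leaflet!r}")
        if self.stiffness < 0:
            raise ValueError("stiffness must be non-negative")
        if self.positional_noise < 0:
            raise ValueError("positional_noise must be non-negative")


@dataclass
class PeptideRecord:
    label: str
    leaflet: str | None  # None when read from a file without leaflet metadata
    position: np.ndarray  # shape (3,), nm


@dataclass
class MembraneFrame:
    """One time point: leaflet bead coordinates, peptide COMs, periodic box.

    x and y are periodic and wrapped into [0, box); z is the membrane normal
    and kept unwrapped (the midplane sits at z = 0, so lower-leaflet
    coordinates are negative).
    """

    upper_beads: np.ndarray  # (n_u, 3)
    lower_beads: np.ndarray  # (n_l, 3)
    peptides: list[PeptideRecord] = field(default_factory=list)
    box: tuple[float, float, float] = (20.0, 10.0, 12.0)

    def beads(self, leaflet: str) -> np.ndarray:
        if leaflet == "upper":
            return self.upper_beads
        if leaflet == "lower":
            return self.lower_beads
        raise ValueError(f"unknown leaflet {leaflet!r}")


def _wrap_xy(points: np.ndarray, box) -> np.ndarray:
    points[..., 0] %= box[0]
    points[..., 1] %= box[1]
    return points


def _grid_shape(geometry: BuckleGeometry) -> tuple[int, int]:
    n_target = geometry.bead_density * geometry.box_x * geometry.box_y
    nx = max(1, round(np.sqrt(n_target * geometry.box_x / geometry.box_y)))
    ny = max(1, round(n_target / nx))
    return nx, ny


def generate_frame(
    geometry: BuckleGeometry,
    noise_sigma: float = 0.1,
    seed=None,
    *,
    rng: np.random.Generator | None = None,
    fit_modes: tuple[int, int] = DEFAULT_FIT_MODES,
) -> MembraneFrame:
    """Draw one frame of leaflet beads (no peptides).

    Beads sit on a jittered grid in the midplane parameter plane, are mapped
    to the leaflet parallel surfaces and displaced by Gaussian noise of sd
    ``noise_sigma`` along the local surface normal.  Deterministic given
    ``seed`` (or an explicit ``rng``).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed) if rng is None else rng
    nx, ny = _grid_shape(geometry)
    n = nx * ny
    if n < 4 * n_basis_functions(fit_modes):
        raise InsufficientSamplingError(
            f"bead_density {geometry.bead_density} yields {n} beads per leaflet; "
            f"at least {4 * n_basis_functions(fit_modes)} are required for a "
            f"modes={fit_modes} fit"
        )
    leaflet_points = {}
    for leaflet in ("upper", "lower"):
        jitter = rng.random((nx, ny, 2))
        u = (np.arange(nx)[:, None] + jitter[..., 0]) * geometry.box_x / nx
        v = (np.arange(ny)[None, :] + jitter[..., 1]) * geometry.box_y / ny
        u, v = u.ravel(), np.broadcast_to(v, (nx, ny)).ravel()
        pts = geom.leaflet_surface_point(geometry, u, v, leaflet)
        if noise_sigma > 0:
            eta = rng.normal(0.0, noise_sigma, size=n)
            pts = pts - eta[:, None] * geom.leaflet_inward_normal(geometry, u, leaflet)
        leaflet_points[leaflet] = _wrap_xy(pts, geometry.box)
    return MembraneFrame(
        upper_beads=leaflet_points["upper"],
        lower_beads=leaflet_points["lower"],
        peptides=[],
        box=geometry.box,
    )


def _placement_density(geometry: BuckleGeometry, model: PeptideModel, n_grid: int):
    """Unnormalized placement density on a parameter-x grid (n_grid cells)."""
    x = np.linspace(0.0, geometry.box_x, n_grid + 1)
    h = geom.signed_membrane_curvature(geometry, x, model.leaflet)
    area = geom.leaflet_area_element(geometry, x, model.leaflet)
    expo = -model.stiffness * (h - model.preferred_curvature) ** 2
    expo -= expo.max()  # stabilize the sharp-Boltzmann limit
    return x, np.exp(expo) * area


class _PlacementSampler:
    """Cached inverse-CDF sampler for one (geometry, peptide model) pair."""

    def __init__(self, geometry: BuckleGeometry, model: PeptideModel, n_grid: int):
        self.geometry = geometry
        self.model = model
        self.x_grid, w = _placement_density(geometry, model, n_grid)
        cell_mass = 0.5 * (w[:-1] + w[1:]) * np.diff(self.x_grid)
        self.cell_mass = cell_mass
        self.cdf = np.concatenate([[0.0], np.cumsum(cell_mass)])

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        geometry, model = self.geometry, self.model
        u = rng.random() * self.cdf[-1]
        i = int(np.searchsorted(self.cdf, u, side="right") - 1)
        i = min(max(i, 0), len(self.cell_mass) - 1)
        frac = (u - self.cdf[i]) / self.cell_mass[i] if self.cell_mass[i] > 0 else 0.5
        x = self.x_grid[i] + frac * (self.x_grid[i + 1] - self.x_grid[i])
        y = rng.random() * geometry.box_y
        point = geom.leaflet_surface_point(geometry, x, y, model.leaflet)
        point = point + model.depth * geom.leaflet_inward_normal(
            geometry, x, model.leaflet
        )
        if model.positional_noise > 0:
            point = point + rng.normal(0.0, model.positional_noise, size=3)
        return _wrap_xy(point, geometry.box)


def place_peptide(
    geometry: BuckleGeometry,
    model: PeptideModel,
    seed=None,
    *,
    rng: np.random.Generator | None = None,
    n_grid: int = 1000,
) -> np.ndarray:
    """Draw one peptide COM from the Boltzmann curvature-preference density.

    The x marginal is sampled by inverse CDF on a grid of ``n_grid`` cells
    (default resolution 1e-3 of the box, avoiding Metropolis
    autocorrelation); y is uniform.  The surface point is displaced
    ``model.depth`` nm along the inward normal and blurred isotropically by
    ``model.positional_noise``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    return _PlacementSampler(geometry, model, n_grid).draw(rng)


def generate_trajectory(
    geometry: BuckleGeometry,
    models: list[PeptideModel],
    n_frames: int,
    noise_sigma: float = 0.1,
    seed=None,
    *,
    labels: list[str] | None = None,
    fit_modes: tuple[int, int] = DEFAULT_FIT_MODES,
) -> list[MembraneFrame]:
    """Independent frames with beads and peptides redrawn each frame.

    Reproducible from (parameters, seed): each frame spawns its own
    SeedSequence children, one stream for beads plus one per peptide.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if labels is None:
        labels = [f"PEP{i + 1}" for i in range(len(models))]
    if len(labels) != len(models):
        raise ValueError("labels and models must have equal length")
    ss = np.random.SeedSequence(seed)
    samplers = [_PlacementSampler(geometry, m, 1000) for m in models]
    frames = []
    for children in (c.spawn(1 + len(models)) for c in ss.spawn(n_frames)):
        frame = generate_frame(
            geometry,
            noise_sigma,
            rng=np.random.default_rng(children[0]),
            fit_modes=fit_modes,
        )
        for sampler, model, label, child in zip(samplers, models, labels, children[1:]):
            pos = sampler.draw(np.random.default_rng(child))
            frame.peptides.append(PeptideRecord(label, model.leaflet, pos))
        frames.append(frame)
    return frames


def analytic_accessible_histogram(
    geometry: BuckleGeometry,
    leaflet: str,
    bin_edges: np.ndarray,
    n_grid: int = 20000,
    *,
    field: str = "membrane",
) -> np.ndarray:
    """Area-weighted curvature histogram of the exact synthetic geometry.

    ``field='membrane'`` histograms the signed midplane curvature a peptide
    on the leaflet samples (the pipeline's accessible distribution);
    ``field='leaflet'`` histograms the leaflet parallel-surface's own mean
    curvature.  In both cases the mass is the leaflet surface area.  Serves
    as the geometry-based oracle for the fitted-surface path.  Returns bin
    masses normalized to 1.
    """
    x = np.linspace(0.0, geometry.box_x, n_grid, endpoint=False)
    if field == "membrane":
        h = geom.signed_membrane_curvature(geometry, x, leaflet)
    elif field == "leaflet":
        h = geom.leaflet_mean_curvature(geometry, x, leaflet)
    else:
        raise ValueError("field must be 'membrane' or 'leaflet'")
    area = geom.leaflet_area_element(geometry, x, leaflet)
    masses, _ = np.histogram(h, bins=bin_edges, weights=area)
    total = masses.sum()
    if total <= 0:
        raise ValueError("bin_edges do not cover the accessible curvature range")
    return masses / total
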