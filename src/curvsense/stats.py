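"""Curvature distributions: accessible, sampled, reweighted, and summaries.

The accessible-curvature distribution is the area-weighted histogram of the
signed mean curvature present on a leaflet surface — the distribution a
non-sensing particle would sample.  Peptide-sampled histograms are divided
bin-wise by it ("reweighting") to remove the geometric area bias of the
buckle, whose crest regions occupy more leaflet area than its troughs.  A
peptide with no curvature preference therefore reweights to a uniform
histogram, and the mode/mean of the reweighted histogram estimate the
peptide's preferred curvature.

Bins are uniform cells of a global lattice whose centers sit on integer
multiples of the bin width, so distributions from different runs share edges
and can be pooled or averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import BinMismatchError, EmptyDistributionError, MaskedMassWarning
from .surface import FittedSurface

__all__ = [
    "CurvatureDistribution",
    "make_bins",
    "accessible_distribution",
    "sampled_distribution",
    "reweight",
    "weighted_mean",
    "weighted_median",
    "replica_average",
    "uniformity_zscores",
    "pool_sampled",
    "average_distributions",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_SUPPORT_FLOOR",
]

#: Default histogram bin width (1/nm).  Chosen to resolve the Boltzmann
#: preference width (2*kappa)^(-1/2) ~ 0.1 1/nm of a kappa ~ 50 nm^2 sensor
#: while keeping per-bin multinomial noise of a few-thousand-frame run below
#: the adjacent-bin contrast; see docs/methods.md.
DEFAULT_BIN_WIDTH = 0.04

#: Bins holding less than this fraction of total accessible mass are masked
#: out of the reweighting support.
DEFAULT_SUPPORT_FLOOR = 1e-4


@dataclass
class CurvatureDistribution:
    """Binned curvature histogram with normalization metadata.

    masses are normalized to 1 over the unmasked (in-support) bins; masked
    bins carry zero mass.  ``n_samples`` is set for count-based (sampled)
    histograms so multinomial uncertainties can be reconstructed.
    """

    bin_edges: np.ndarray
    masses: np.ndarray
    kind: str  # 'sampled' | 'accessible' | 'reweighted'
    support_mask: np.ndarray = None  # True = bin in support
    n_samples: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.support_mask is None:
            self.support_mask = np.ones(len(self.masses), dtype=bool)
        self.support_mask = np.asarray(self.support_mask, dtype=bool)
        if len(self.bin_edges) != len(self.masses) + 1:
            raise ValueError("bin_edges must be one longer than masses")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must have uniform width")
        if np.any(self.masses < 0):
            raise ValueError("masses must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def normalized(self) -> "CurvatureDistribution":
        total = self.masses[self.support_mask].sum()
        if total <= 0:
            raise EmptyDistributionError("no mass in supported bins")
        m = np.where(self.support_mask, self.masses / total, 0.0)
        return CurvatureDistribution(
            self.bin_edges, m, self.kind, self.support_mask, self.n_samples,
            dict(self.metadata),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "mass": self.masses,
                "masked": ~self.support_mask,
            }
        )


def make_bins(lo: float, hi: float, width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Uniform bin edges covering [lo, hi], padded by one bin on each side.

    Edges lie on the global lattice with bin centers at integer multiples of
    ``width``, so bins from different calls are cells of one grid.
    """
    if hi < lo:
        lo, hi = hi, lo
    m_lo = int(np.floor(lo / width + 0.5)) - 1
    m_hi = int(np.floor(hi / width + 0.5)) + 1
    return (np.arange(m_lo, m_hi + 2) - 0.5) * width


def _grid_curvature_weights(
    surface: FittedSurface,
    grid: tuple[int, int],
    weight_surface: FittedSurface | None = None,
):
    """Curvature values and area weights on a regular lateral grid.

    Values are the signed mean curvature of ``surface``; weights are the
    area element of ``weight_surface`` (default: the same surface).
    """
    nx, ny = grid
    x = (np.arange(nx) + 0.5) * surface.box[0] / nx
    y = (np.arange(ny) + 0.5) * surface.box[1] / ny
    xx, yy = np.meshgrid(x, y, indexing="ij")
    h = surface.mean_curvature(xx, yy).ravel()
    ws = weight_surface if weight_surface is not None else surface
    hx, hy = ws.gradient(xx, yy)
    area = np.sqrt(1.0 + hx**2 + hy**2).ravel()
    return h, area


def accessible_distribution(
    surfaces,
    bin_edges=None,
    *,
    weight_surfaces=None,
    grid: tuple[int, int] = (128, 128),
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> CurvatureDistribution:
    """Area-weighted histogram of curvature over one or more fitted surfaces.

    The signed mean curvature is evaluated on a regular lateral grid (at
    least 64 points per box length is recommended); each grid point carries
    mass proportional to an area element sqrt(1 + hx^2 + hy^2) dx dy.
    Passing several surfaces (e.g. per-frame fits of a noisy trajectory)
    averages their histograms.

    ``weight_surfaces`` lets the mass come from a different surface than
    the curvature values: the analysis pipeline histograms the membrane
    (midplane) curvature weighted by the area of the peptide's leaflet
    surface, which is where a laterally diffusing peptide actually resides.
    By default values and weights come from the same surface.

    A flat surface validly concentrates all mass in the bin containing 0.
    """
    if isinstance(surfaces, FittedSurface):
        surfaces = [surfaces]
    if not surfaces:
        raise ValueError("need at least one surface")
    if weight_surfaces is None:
        weight_surfaces = [None] * len(surfaces)
    elif isinstance(weight_surfaces, FittedSurface):
        weight_surfaces = [weight_surfaces]
    if len(weight_surfaces) != len(surfaces):
        raise ValueError("weight_surfaces must match surfaces in length")
    evals = [
        _grid_curvature_weights(s, grid, w) for s, w in zip(surfaces, weight_surfaces)
    ]
    if bin_edges is None:
        lo = min(h.min() for h, _ in evals)
        hi = max(h.max() for h, _ in evals)
        bin_edges = make_bins(lo, hi, bin_width)
    bin_edges = np.asarray(bin_edges, dtype=float)
    masses = np.zeros(len(bin_edges) - 1)
    for h, area in evals:
        counts, _ = np.histogram(h, bins=bin_edges, weights=area)
        masses += counts / area.sum()
    masses /= len(evals)
    dist = CurvatureDistribution(bin_edges, masses, "accessible")
    return dist.normalized()


def sampled_distribution(values, bin_edges, label: str | None = None) -> CurvatureDistribution:
    """Histogram of peptide-sampled curvature values, normalized to 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyDistributionError("no sampled curvature values")
    counts, _ = np.histogram(values, bins=bin_edges)
    dist = CurvatureDistribution(
        np.asarray(bin_edges, dtype=float),
        counts / values.size,
        "sampled",
        n_samples=int(values.size),
        metadata={"label": label} if label else {},
    )
    return dist


def reweight(
    sampled: CurvatureDistribution,
    accessible: CurvatureDistribution,
    floor: float = DEFAULT_SUPPORT_FLOOR,
    *,
    leak_tolerance: float = 0.01,
) -> CurvatureDistribution:
    """Divide a sampled histogram bin-wise by the accessible histogram.

    Bins whose accessible mass is below ``floor`` (fraction of total) are
    masked and excluded from the result's support; sampled mass falling in
    masked bins beyond ``leak_tolerance`` triggers a MaskedMassWarning
    reporting the leaked fraction, and is never silently dropped without it.
    """
    if len(sampled.bin_edges) != len(accessible.bin_edges) or not np.allclose(
        sampled.bin_edges, accessible.bin_edges
    ):
        raise BinMismatchError("sampled and accessible distributions use different bins")
    acc = accessible.normalized()
    mask = acc.masses >= floor
    leaked = float(sampled.masses[~mask].sum() / max(sampled.masses.sum(), 1e-300))
    if leaked > leak_tolerance:
        warnings.warn(
            f"{leaked:.1%} of sampled mass lies outside the accessible support "
            f"(floor={floor:g}) and was masked",
            MaskedMassWarning,
            stacklevel=2,
        )
    ratio = np.zeros_like(sampled.masses)
    ratio[mask] = sampled.masses[mask] / acc.masses[mask]
    dist = CurvatureDistribution(
        sampled.bin_edges,
        ratio,
        "reweighted",
        support_mask=mask,
        n_samples=sampled.n_samples,
        metadata={**sampled.metadata, "leaked_mass_fraction": leaked},
    )
    return dist.normalized()


def weighted_mean(dist: CurvatureDistribution) -> float:
    """Mean curvature of a normalized distribution: sum(center * mass)."""
    d = dist.normalized()
    return float(np.sum(d.centers * d.masses))


def weighted_median(dist: CurvatureDistribution) -> float:
    """Median with linear interpolation inside the crossing bin."""
    d = dist.normalized()
    cum = np.cumsum(d.masses)
    i = int(np.searchsorted(cum, 0.5))
    prev = cum[i - 1] if i > 0 else 0.0
    if d.masses[i] <= 0:  # 0.5 hit exactly on a bin boundary
        return float(d.bin_edges[i])
    frac = (0.5 - prev) / d.masses[i]
    return float(d.bin_edges[i] + frac * d.bin_width)


def replica_average(per_replica_means) -> tuple[float, float]:
    """Arithmetic mean and standard error over independent replicas.

    With a single replica the mean is returned and the sem is NaN
    (undefined).  An empty list is an error.
    """
    values = np.asarray(list(per_replica_means), dtype=float)
    if values.size == 0:
        raise EmptyDistributionError("no replicas given")
    mean = float(values.mean())
    if values.size == 1:
        return mean, float("nan")
    return mean, float(values.std(ddof=1) / np.sqrt(values.size))


def uniformity_zscores(
    sampled: CurvatureDistribution, accessible: CurvatureDistribution
) -> np.ndarray:
    """Per-bin z-scores of a sampled histogram against the accessible null.

    Under the no-preference null the sampled counts are multinomial with
    probabilities equal to the accessible masses, which is equivalent to the
    reweighted histogram being uniform over the support; z-scores are
    computed on the counts, where the multinomial standard error is exact.
    Returned only for bins in the accessible support.
    """
    if sampled.n_samples is None:
        raise ValueError("sampled distribution must carry n_samples")
    if not np.allclose(sampled.bin_edges, accessible.bin_edges):
        raise BinMismatchError("distributions use different bins")
    acc = accessible.normalized()
    mask = acc.masses > 0
    n = sampled.n_samples
    counts = sampled.masses * n
    expected = n * acc.masses[mask]
    se = np.sqrt(n * acc.masses[mask] * (1.0 - acc.masses[mask]))
    return (counts[mask] - expected) / np.where(se > 0, se, np.inf)


def _common_lattice(dists):
    width = dists[0].bin_width
    for d in dists:
        if not np.isclose(d.bin_width, width):
            raise BinMismatchError("distributions use different bin widths")
        offset = d.bin_edges[0] / width + 0.5
        if not np.isclose(offset, round(offset)):
            raise BinMismatchError("distribution bins are not on the common lattice")
    lo = min(d.bin_edges[0] for d in dists)
    hi = max(d.bin_edges[-1] for d in dists)
    m_lo = round(lo / width - 0.5)
    m_hi = round(hi / width - 0.5)
    edges = (np.arange(m_lo, m_hi + 1) + 0.5) * width
    return edges, width, m_lo


def _embed(dist, n_bins, width, m_lo):
    out = np.zeros(n_bins)
    mask = np.zeros(n_bins, dtype=bool)
    start = round(dist.bin_edges[0] / width - 0.5) - m_lo
    out[start : start + len(dist.masses)] = dist.masses
    mask[start : start + len(dist.masses)] = dist.support_mask
    return out, mask


def pool_sampled(dists) -> CurvatureDistribution:
    """Pool count-based sampled histograms (shared lattice) into one."""
    dists = list(dists)
    if any(d.n_samples is None for d in dists):
        raise ValueError("pooling requires count-based sampled distributions")
    edges, width, m_lo = _common_lattice(dists)
    counts = np.zeros(len(edges) - 1)
    for d in dists:
        m, _ = _embed(d, len(edges) - 1, width, m_lo)
        counts += m * d.n_samples
    n = sum(d.n_samples for d in dists)
    return CurvatureDistribution(edges, counts / n, "sampled", n_samples=n)


def average_distributions(dists) -> CurvatureDistribution:
    """Average normalized distributions of one kind on the shared lattice.

    Masked bins contribute zero; the result's support is the union of the
    inputs' supports and the averaged masses are renormalized.
    """
    dists = [d.normalized() for d in dists]
    edges, width, m_lo = _common_lattice(dists)
    masses = np.zeros(len(edges) - 1)
    mask = np.zeros(len(edges) - 1, dtype=bool)
    for d in dists:
        m, msk = _embed(d, len(edges) - 1, width, m_lo)
        masses += m
        mask |= msk
    masses /= len(dists)
    return CurvatureDistribution(edges, masses, dists[0].kind, support_mask=mask).normalized()
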