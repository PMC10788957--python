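"""Model/Results interface tying the full analysis together.

:class:`CurvatureSensingModel` holds a trajectory of membrane frames plus
the analysis configuration (fit modes, histogram binning, support floor);
:meth:`CurvatureSensingModel.fit` runs the pipeline — per-frame periodic
surface fits, peptide-sampled curvature and insertion depth,
accessible-curvature distribution, reweighting — and returns a
:class:`CurvatureSensingResults` carrying per-peptide distributions and
summary statistics with a statsmodels-style ``summary()`` table.

Replica studies (the standard protocol averages three independent
replicas) are handled by :func:`fit_replicas` / :func:`combine_replicas`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as cstats
from .gro import read_trajectory
from .sampling import sample_curvature
from .stats import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_SUPPORT_FLOOR,
    CurvatureDistribution,
    reweight,
    replica_average,
    sampled_distribution,
    weighted_mean,
    weighted_median,
)
from .surface import SIGN_CONVENTION
from .synthetic import BuckleGeometry, generate_trajectory

__all__ = [
    "CurvatureSensingModel",
    "CurvatureSensingResults",
    "PeptideSummary",
    "fit_replicas",
    "combine_replicas",
]


@dataclass
class PeptideSummary:
    """Per-peptide fitted quantities."""

    label: str
    leaflet: str
    n_frames: int
    raw_mean: float  # mean of sampled curvature before reweighting (1/nm)
    weighted_mean: float  # mean of the reweighted distribution (1/nm)
    weighted_median: float  # median of the reweighted distribution (1/nm)
    depth_mean: float  # nm
    depth_sem: float  # nm
    mean_hydrophobicity: float | None = None  # kcal/mol, if a sequence was given

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


class CurvatureSensingModel:
    """Curvature-sensing analysis of peptides on a buckled membrane.

    Parameters
    ----------
    frames : list of MembraneFrame
        Trajectory to analyze (coordinates in nm).
    modes : (int, int)
        Fourier truncation of the leaflet surface fits.
    bin_width : float
        Curvature histogram bin width (1/nm); edges sit on a global lattice
        with centers at integer multiples of the width.
    support_floor : float
        Fraction of accessible mass below which a bin is masked.
    n_accessible_frames : int or None
        Number of evenly spaced frames whose fitted surfaces are averaged
        into the accessible distribution; None (default) averages every
        frame, so the accessible histogram carries the same per-frame fit
        noise as the sampled one.  One frame suffices for a static
        noiseless geometry.
    accessible_grid : (int, int)
        Lateral quadrature points per frame for the accessible histogram;
        each frame's grid is stratified-jittered, so frame averaging acts
        as unbiased Monte Carlo quadrature.
    ridge : float
        Optional ridge penalty for sparse bead counts (0 = OLS).
    sequences : dict, optional
        label -> one-letter sequence; adds mean hydrophobicity to summaries.
    """

    def __init__(
        self,
        frames,
        *,
        modes=(6, 2),
        bin_width: float = DEFAULT_BIN_WIDTH,
        bin_edges=None,
        support_floor: float = DEFAULT_SUPPORT_FLOOR,
        n_accessible_frames: int | None = None,
        accessible_grid: tuple[int, int] = (64, 4),
        ridge: float = 0.0,
        check_leaflet: bool = True,
        leaflet_offset: float | None = None,
        sequences: dict | None = None,
        metadata: dict | None = None,
    ):
        if not frames:
            raise ValueError("need at least one frame")
        self.frames = list(frames)
        self.modes = (int(modes[0]), int(modes[1]))
        self.bin_width = float(bin_width)
        self.bin_edges = None if bin_edges is None else np.asarray(bin_edges, float)
        self.support_floor = float(support_floor)
        self.n_accessible_frames = (
            None if n_accessible_frames is None else int(n_accessible_frames)
        )
        self.accessible_grid = accessible_grid
        self.ridge = float(ridge)
        self.check_leaflet = bool(check_leaflet)
        self.leaflet_offset = None if leaflet_offset is None else float(leaflet_offset)
        self.sequences = dict(sequences or {})
        self.metadata = dict(metadata or {})

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_synthetic(
        cls,
        geometry: BuckleGeometry | None = None,
        models=None,
        n_frames: int = 1000,
        noise_sigma: float = 0.1,
        seed=None,
        labels=None,
        **kwargs,
    ) -> "CurvatureSensingModel":
        """Generate a synthetic trajectory and wrap it in a model."""
        from .synthetic import PeptideModel

        geometry = geometry or BuckleGeometry()
        if models is None:
            models = [PeptideModel("upper"), PeptideModel("lower")]
        frames = generate_trajectory(
            geometry, models, n_frames, noise_sigma, seed, labels=labels
        )
        kwargs.setdefault("leaflet_offset", geometry.half_thickness)
        meta = {
            "source": "synthetic",
            "geometry": geometry.__dict__ | {},
            "peptide_models": [m.__dict__ | {} for m in models],
            "n_frames": n_frames,
            "noise_sigma": noise_sigma,
            "seed": seed,
        }
        return cls(frames, metadata=meta, **kwargs)

    @classmethod
    def from_trajectory(
        cls,
        topology,
        trajectory=None,
        *,
        upper_sel="resname UMB",
        lower_sel="resname LMB",
        peptide_sel="resname PEP",
        **kwargs,
    ) -> "CurvatureSensingModel":
        """Load frames from GRO (single/concatenated) or GRO + XTC."""
        frames = read_trajectory(
            topology,
            trajectory,
            upper_sel=upper_sel,
            lower_sel=lower_sel,
            peptide_sel=peptide_sel,
        )
        meta = {"source": str(topology), "trajectory": str(trajectory) if trajectory else None}
        return cls(frames, metadata=meta, **kwargs)

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "CurvatureSensingResults":
        if self.n_accessible_frames is None:
            keep = np.arange(len(self.frames))
        else:
            keep = np.unique(
                np.linspace(
                    0,
                    len(self.frames) - 1,
                    min(self.n_accessible_frames, len(self.frames)),
                ).astype(int)
            )
        samples, flags, surfaces = sample_curvature(
            self.frames,
            self.modes,
            ridge=self.ridge,
            check_leaflet=self.check_leaflet,
            keep_surfaces_for=keep,
            leaflet_offset=self.leaflet_offset,
        )
        if samples.empty:
            raise ValueError("no peptide samples could be collected")

        # accessible curvature per leaflet: membrane (midplane) curvature
        # values from the leaflet fit (parallel-surface correction), mass
        # weighted by that leaflet surface's own area element, averaged over
        # the kept frames — the same field and measure the peptides sample
        from .sampling import leaflet_offset_estimate, membrane_curvature

        nx, ny = self.accessible_grid
        box = self.frames[0].box
        # fixed jitter stream: per-frame stratified quadrature points; a
        # constant seed keeps fit() deterministic for a given trajectory
        qrng = np.random.default_rng(1905)
        evals = {"upper": [], "lower": []}
        for i in keep:
            offset = (
                self.leaflet_offset
                if self.leaflet_offset is not None
                else leaflet_offset_estimate(surfaces[i])
            )
            gx = (np.arange(nx) + qrng.random(nx)) * box[0] / nx
            gy = (np.arange(ny) + qrng.random(ny)) * box[1] / ny
            xx, yy = np.meshgrid(gx, gy, indexing="ij")
            for lf in ("upper", "lower"):
                surf = surfaces[i][lf]
                h = membrane_curvature(surfaces[i], xx, yy, lf, offset).ravel()
                sx, sy = surf.gradient(xx, yy)
                area = np.sqrt(1.0 + sx**2 + sy**2).ravel()
                evals[lf].append((h, area))
        edges = self.bin_edges
        if edges is None:
            lo = min(h.min() for ev in evals.values() for h, _ in ev)
            hi = max(h.max() for ev in evals.values() for h, _ in ev)
            lo = min(lo, samples.curvature_per_nm.min())
            hi = max(hi, samples.curvature_per_nm.max())
            edges = cstats.make_bins(lo, hi, self.bin_width)

        accessible = {}
        for lf, ev in evals.items():
            masses = np.zeros(len(edges) - 1)
            for h, area in ev:
                counts, _ = np.histogram(h, bins=edges, weights=area)
                masses += counts / area.sum()
            accessible[lf] = cstats.CurvatureDistribution(
                edges, masses / len(ev), "accessible"
            ).normalized()

        peptides = {}
        distributions = {}
        for label, group in samples.groupby("peptide", sort=False):
            leaflet = group.leaflet.iloc[0]
            sampled = sampled_distribution(
                group.curvature_per_nm.to_numpy(), edges, label=label
            )
            rw = reweight(sampled, accessible[leaflet], self.support_floor)
            seq = self.sequences.get(label)
            hydro = None
            if seq is not None:
                from .hydropathy import mean_hydrophobicity

                hydro = mean_hydrophobicity(seq)
            depth = group.depth_nm.to_numpy()
            peptides[label] = PeptideSummary(
                label=label,
                leaflet=leaflet,
                n_frames=len(group),
                raw_mean=float(group.curvature_per_nm.mean()),
                weighted_mean=weighted_mean(rw),
                weighted_median=weighted_median(rw),
                depth_mean=float(depth.mean()),
                depth_sem=float(depth.std(ddof=1) / np.sqrt(len(depth)))
                if len(depth) > 1
                else float("nan"),
                mean_hydrophobicity=hydro,
            )
            distributions[label] = {"sampled": sampled, "reweighted": rw}

        config = {
            "modes": list(self.modes),
            "bin_width": float(edges[1] - edges[0]),
            "support_floor": self.support_floor,
            "n_accessible_frames": int(len(keep)),
            "ridge": self.ridge,
            "sign_convention": SIGN_CONVENTION,
            "depth_convention": "signed distance along the local surface normal; "
            "positive = toward the membrane interior",
            "units": {"length": "nm", "curvature": "1/nm"},
        }
        return CurvatureSensingResults(
            model=self,
            samples=samples,
            flags=flags,
            bin_edges=edges,
            accessible=accessible,
            distributions=distributions,
            peptides=peptides,
            config=config,
        )


@dataclass
class CurvatureSensingResults:
    """Fitted quantities of one trajectory analysis."""

    model: CurvatureSensingModel
    samples: pd.DataFrame
    flags: list
    bin_edges: np.ndarray
    accessible: dict  # leaflet -> CurvatureDistribution
    distributions: dict  # peptide label -> {'sampled': ..., 'reweighted': ...}
    peptides: dict  # peptide label -> PeptideSummary
    config: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.as_dict() for p in self.peptides.values()]).set_index(
            "label"
        )

    def summary(self) -> str:
        df = self.summary_frame()
        lines = [
            "Curvature-sensing analysis summary",
            "=" * 72,
            f"frames: {self.samples.frame.nunique()}   "
            f"fit modes: {tuple(self.config['modes'])}   "
            f"bin width: {self.config['bin_width']:g} 1/nm",
            f"sign convention: positive H = convex toward the peptide's aqueous side",
            "-" * 72,
            df.to_string(
                float_format=lambda v: f"{v: .4f}",
                columns=[
                    c
                    for c in [
                        "leaflet",
                        "n_frames",
                        "raw_mean",
                        "weighted_mean",
                        "weighted_median",
                        "depth_mean",
                        "depth_sem",
                        "mean_hydrophobicity",
                    ]
                    if c in df.columns
                ],
            ),
            "-" * 72,
            f"flagged (excluded) peptide-frames: {len(self.flags)}",
        ]
        return "\n".join(lines)

    def reweighted(self, label: str) -> CurvatureDistribution:
        return self.distributions[label]["reweighted"]

    def sampled(self, label: str) -> CurvatureDistribution:
        return self.distributions[label]["sampled"]

    # -- persistence -------------------------------------------------------
    def summary_dict(self) -> dict:
        return {
            "config": self.config,
            "peptides": {k: _jsonable(v.as_dict()) for k, v in self.peptides.items()},
            "n_flagged": len(self.flags),
        }

    def save(self, outdir) -> None:
        """Write tidy CSVs and a summary JSON into ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "samples.csv", index=False)
        for lf, dist in self.accessible.items():
            dist.to_frame().to_csv(out / f"accessible_{lf}.csv", index=False)
        for label, dd in self.distributions.items():
            for kind, dist in dd.items():
                dist.to_frame().to_csv(out / f"{label}_{kind}.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=1, sort_keys=True)

    def plot_distributions(self, ax=None):
        """Step plot of reweighted distributions per peptide."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, dd in self.distributions.items():
            d = dd["reweighted"]
            ax.stairs(d.masses, d.bin_edges, label=f"{label} reweighted")
        for lf, d in self.accessible.items():
            ax.stairs(d.masses, d.bin_edges, linestyle="--", label=f"accessible {lf}")
        ax.set_xlabel("mean curvature H (1/nm)")
        ax.set_ylabel("probability mass")
        ax.legend(fontsize=8)
        return ax


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        if isinstance(v, float) and np.isnan(v):
            v = None
        out[k] = v
    return out


def fit_replicas(
    make_model, n_replicas: int = 3, base_seed=None
) -> list[CurvatureSensingResults]:
    """Fit ``n_replicas`` independent replicas.

    ``make_model(seed)`` must return a CurvatureSensingModel; replica seeds
    are integers spawned from ``base_seed``.
    """
    return [make_model(s).fit() for s in _spawn_ints(base_seed, n_replicas)]


def _spawn_ints(base_seed, n) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def combine_replicas(results: list, labels=None) -> pd.DataFrame:
    """Replica-averaged weighted means (and depths) with standard errors.

    Mirrors the published protocol of averaging three independent replicas;
    rows are peptide labels with replica values, mean, and sem.
    """
    if not results:
        raise ValueError("no replica results")
    if labels is None:
        labels = list(results[0].peptides)
    rows = []
    for label in labels:
        wm = [r.peptides[label].weighted_mean for r in results]
        dm = [r.peptides[label].depth_mean for r in results]
        mean, sem = replica_average(wm)
        dmean, dsem = replica_average(dm)
        rows.append(
            {
                "label": label,
                "leaflet": results[0].peptides[label].leaflet,
                "n_replicas": len(results),
                "replica_weighted_means": wm,
                "weighted_mean": mean,
                "weighted_mean_sem": sem,
                "depth_mean": dmean,
                "depth_sem": dsem,
            }
        )
    return pd.DataFrame(rows).set_index("label")
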