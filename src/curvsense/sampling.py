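"""Per-frame peptide observables: sampled membrane curvature and depth.

For every trajectory frame each leaflet's phosphate beads are fitted with a
periodic surface.  The curvature a peptide samples is the signed mean
curvature of the membrane midplane at the peptide's lateral position, under
the peptide's leaflet sign convention (positive = convex toward its aqueous
side).  It is obtained from the peptide's own leaflet fit by inverting the
parallel-surface relation: a phosphate surface at normal offset t from a
midplane of curvature k has curvature k/(1 - s t k), so

    k_mid = k_leaflet / (1 + s t k_leaflet),   s = +1 upper / -1 lower,

exact for a cylindrically curved (1D-buckled) membrane.  Using the
membrane curvature rather than the leaflet surface's own curvature keeps
the accessible range symmetric between crests and troughs, so the only
crest/trough imbalance a non-sensing peptide feels is the leaflet area
excess over regions curving away from it — exactly the bias the
accessible-curvature reweighting removes.  The offset t is estimated from
the two fits' mean heights unless supplied.

The insertion depth is the signed distance from the peptide centre of mass
to the fitted phosphate surface of its own leaflet along the local surface
normal (positive toward the membrane core); the normal-distance definition,
rather than a vertical one, is rotation-consistent on curved regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AmbiguousLeafletError, CurvSenseError
from .surface import FittedSurface, fit_surface
from .synthetic import MembraneFrame

__all__ = [
    "fit_frame_surfaces",
    "membrane_surface",
    "membrane_curvature",
    "leaflet_offset_estimate",
    "nearest_surface_point",
    "insertion_depth",
    "assign_leaflet",
    "sample_curvature",
]


def fit_frame_surfaces(
    frame: MembraneFrame, modes=(6, 2), ridge: float = 0.0
) -> dict[str, FittedSurface]:
    """Fit both leaflet surfaces and the midplane of one frame.

    The 'midplane' entry averages the two leaflet fits' coefficients (no
    separate midplane beads exist); its residual is recorded as NaN.
    """
    surfaces = {
        leaflet: fit_surface(
            frame.beads(leaflet), frame.box, modes, ridge=ridge, leaflet=leaflet
        )
        for leaflet in ("upper", "lower")
    }
    surfaces["midplane"] = FittedSurface(
        coefficients=0.5 * (surfaces["upper"].coefficients + surfaces["lower"].coefficients),
        box=surfaces["upper"].box,
        modes=surfaces["upper"].modes,
        rms_residual=float("nan"),
        leaflet="midplane",
    )
    return surfaces


def membrane_surface(surfaces: dict[str, FittedSurface], leaflet: str) -> FittedSurface:
    """The fitted midplane relabelled with a peptide's leaflet sign.

    ``membrane_surface(surfaces, 'lower').mean_curvature(x, y)`` is the
    membrane curvature a lower-leaflet peptide at (x, y) samples.  Note the
    vertically averaged midplane underestimates curvature radii at large
    offset-times-curvature; :func:`membrane_curvature` (the pipeline path)
    avoids that by correcting a single leaflet fit instead.
    """
    mid = surfaces["midplane"]
    if leaflet == "midplane":
        return mid
    return FittedSurface(mid.coefficients, mid.box, mid.modes, mid.rms_residual, leaflet)


def leaflet_offset_estimate(
    surfaces: dict[str, FittedSurface], n_grid: int = 64
) -> float:
    """Midplane-to-phosphate offset from the two leaflet fits (nm).

    The vertical chord between two parallel surfaces at one lateral
    position is about 2 t g, with g the local metric factor of the
    midplane, so t is the box average of (h_upper - h_lower) / (2 g).
    """
    up, lo = surfaces["upper"], surfaces["lower"]
    x = (np.arange(n_grid) + 0.5) * up.box[0] / n_grid
    y = (np.arange(max(n_grid // 4, 4)) + 0.5) * up.box[1] / max(n_grid // 4, 4)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    sep = up.evaluate(xx, yy) - lo.evaluate(xx, yy)
    ux, uy = up.gradient(xx, yy)
    lx, ly = lo.gradient(xx, yy)
    mx, my = 0.5 * (ux + lx), 0.5 * (uy + ly)
    g = np.sqrt(1.0 + mx**2 + my**2)
    return float(np.mean(sep / (2.0 * g)))


def membrane_curvature(
    surfaces: dict[str, FittedSurface], x, y, leaflet: str, leaflet_offset: float
) -> np.ndarray:
    """Signed membrane (midplane) curvature at a lateral position.

    Each leaflet fit yields a midplane-curvature estimate by inverting the
    parallel-surface relation k_mid = k_leaflet / (1 + s t k_leaflet)
    (cylindrical-curvature assumption, s = +1 upper / -1 lower, t the
    midplane-to-phosphate offset).  The inversion amplifies fit noise by
    1/(1 + s t k)^2 wherever the leaflet is the outer, flatter surface, so
    the two estimates are combined with inverse-variance weights
    (1 + s t k)^4 — at every position at least one leaflet is the inner
    surface and well conditioned.  The result is signed by ``leaflet``:
    positive = convex toward that leaflet's aqueous side.
    """
    sign = 1.0 if leaflet == "upper" else -1.0
    other = "lower" if leaflet == "upper" else "upper"
    own = surfaces[leaflet]
    t = leaflet_offset

    # own-leaflet estimate, evaluated where the peptide actually is
    k_own = 2.0 * own.geometric_mean_curvature(x, y)
    den_own = np.maximum(1.0 + sign * t * k_own, 0.2)

    # the opposite leaflet's point over the same midplane foot is laterally
    # shifted by 2 t grad/g (parallel surfaces share tangent directions),
    # so the second estimate is taken there, not at (x, y)
    mx, my = own.gradient(x, y)
    g = np.sqrt(1.0 + mx**2 + my**2)
    x2 = x + sign * 2.0 * t * mx / g
    y2 = y + sign * 2.0 * t * my / g
    k_oth = 2.0 * surfaces[other].geometric_mean_curvature(x2, y2)
    den_oth = np.maximum(1.0 - sign * t * k_oth, 0.2)

    w_own, w_oth = den_own**4, den_oth**4
    kappa_mid = (w_own * (k_own / den_own) + w_oth * (k_oth / den_oth)) / (w_own + w_oth)
    return -sign * kappa_mid / 2.0


def nearest_surface_point(
    surface: FittedSurface, point, *, tol: float = 1e-6, max_iter: int = 60
) -> np.ndarray:
    """Foot of the perpendicular from ``point`` onto the fitted surface.

    Damped Newton minimization of the squared distance
    D^2(u, v) = (u-px)^2 + (v-py)^2 + (h(u,v)-pz)^2 seeded at the peptide's
    lateral position; because the basis is periodic no wrapping is needed.
    """
    px, py, pz = (float(c) for c in np.asarray(point, dtype=float))
    u, v = px, py

    def objective(u, v):
        dz = surface.evaluate(u, v) - pz
        return (u - px) ** 2 + (v - py) ** 2 + dz * dz

    def grad_hess(u, v):
        h, hx, hy, hxx, hxy, hyy = surface.derivatives(u, v)
        dz = h - pz
        g = 2.0 * np.array([(u - px) + dz * hx, (v - py) + dz * hy])
        H = 2.0 * np.array(
            [
                [1.0 + hx * hx + dz * hxx, hx * hy + dz * hxy],
                [hx * hy + dz * hxy, 1.0 + hy * hy + dz * hyy],
            ]
        )
        return g, H

    # Levenberg-Marquardt: accept a step only if the squared distance drops
    f = objective(u, v)
    lam = 1e-4
    for _ in range(max_iter):
        g, H = grad_hess(u, v)
        if np.linalg.norm(g) < tol:
            break
        improved = False
        for _ in range(40):
            try:
                step = np.linalg.solve(H + lam * np.eye(2), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            f_new = objective(u + step[0], v + step[1])
            if np.isfinite(f_new) and f_new <= f:
                u, v, f = u + step[0], v + step[1], f_new
                lam = max(lam * 0.3, 1e-12)
                improved = True
                break
            lam *= 10.0
        if not improved:  # numerical floor reached
            break
    g, _ = grad_hess(u, v)
    if np.linalg.norm(g) > max(tol, 1e-4):
        raise CurvSenseError("nearest-surface-point search did not converge")
    return np.array([u, v, float(surface.evaluate(u, v))])


def _signed_normal_distance(surface: FittedSurface, point) -> float:
    """Distance along the surface normal; positive toward the membrane core."""
    foot = nearest_surface_point(surface, point)
    hx, hy = surface.gradient(foot[0], foot[1])
    g = np.sqrt(1.0 + hx * hx + hy * hy)
    if surface.leaflet == "lower":
        inward = np.array([-hx / g, -hy / g, 1.0 / g])
    else:
        inward = np.array([hx / g, hy / g, -1.0 / g])
    return float(np.dot(np.asarray(point, dtype=float) - foot, inward))


def insertion_depth(surface: FittedSurface, peptide_point) -> float:
    """Signed insertion depth of a peptide COM relative to its leaflet surface.

    Positive values mean displacement from the fitted phosphate surface
    toward the membrane interior (deeper insertion); negative toward water.
    """
    return _signed_normal_distance(surface, peptide_point)


def assign_leaflet(
    surfaces: dict[str, FittedSurface], peptide_point, *, tol: float = 1e-6
) -> str:
    """Leaflet whose fitted surface is nearer in absolute normal distance."""
    d_upper = abs(_signed_normal_distance(surfaces["upper"], peptide_point))
    d_lower = abs(_signed_normal_distance(surfaces["lower"], peptide_point))
    if abs(d_upper - d_lower) < tol:
        raise AmbiguousLeafletError(
            f"peptide equidistant from both leaflets ({d_upper:.6f} nm)"
        )
    return "upper" if d_upper < d_lower else "lower"


def _fast_assign(surfaces, point) -> str:
    """assign_leaflet with a cheap vertical-distance shortcut.

    The normal distance d to a graph surface obeys |dz|/g_max <= d <= |dz|
    with dz the vertical offset and g_max the maximal metric factor; when
    those intervals do not overlap the full normal-projection search is
    unnecessary.
    """
    point = np.asarray(point, dtype=float)
    dz_u = abs(float(point[2] - surfaces["upper"].evaluate(point[0], point[1])))
    dz_l = abs(float(point[2] - surfaces["lower"].evaluate(point[0], point[1])))
    g_max = 2.0  # generous bound: slopes above sqrt(3) do not occur for gentle buckles
    if dz_u * g_max < dz_l:
        return "upper"
    if dz_l * g_max < dz_u:
        return "lower"
    return assign_leaflet(surfaces, point)


def sample_curvature(
    frames,
    modes=(6, 2),
    *,
    ridge: float = 0.0,
    check_leaflet: bool = True,
    keep_surfaces_for=(),
    leaflet_offset: float | None = None,
):
    """Evaluate peptide-sampled curvature and depth over a trajectory.

    Per frame: fit both leaflet surfaces, then record for each peptide the
    signed membrane curvature at the peptide's (x, y) — from its leaflet's
    fit via the parallel-surface correction, with the leaflet offset
    estimated from the fits unless given — and its insertion depth relative
    to its leaflet surface.  Peptides whose nearest surface disagrees with
    their recorded leaflet (midplane crossers) are excluded from that frame
    and reported in ``flags`` rather than silently re-assigned.

    Returns
    -------
    samples : pandas.DataFrame
        Columns frame, peptide, leaflet, curvature_per_nm, depth_nm.
    flags : list of (frame_index, label, reason)
    surfaces : dict frame_index -> {leaflet: FittedSurface}
        Only for the indices in ``keep_surfaces_for``.
    """
    keep = set(keep_surfaces_for)
    records = []
    flags = []
    kept_surfaces = {}
    for i, frame in enumerate(frames):
        try:
            surfaces = fit_frame_surfaces(frame, modes, ridge)
        except CurvSenseError as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
        if i in keep:
            kept_surfaces[i] = surfaces
        offset = (
            leaflet_offset if leaflet_offset is not None else leaflet_offset_estimate(surfaces)
        )
        for pep in frame.peptides:
            leaflet = pep.leaflet
            if leaflet is None:
                leaflet = _fast_assign(surfaces, pep.position)
            elif check_leaflet:
                assigned = _fast_assign(surfaces, pep.position)
                if assigned != leaflet:
                    flags.append((i, pep.label, f"nearest surface is {assigned}"))
                    continue
            records.append(
                (
                    i,
                    pep.label,
                    leaflet,
                    float(
                        membrane_curvature(
                            surfaces, pep.position[0], pep.position[1], leaflet, offset
                        )
                    ),
                    insertion_depth(surfaces[leaflet], pep.position),
                )
            )
    samples = pd.DataFrame(
        records, columns=["frame", "peptide", "leaflet", "curvature_per_nm", "depth_nm"]
    )
    return samples, flags, kept_surfaces
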