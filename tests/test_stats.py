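"""Curvature distributions: binning, reweighting, summaries, replicas."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import curvsense as cs
from curvsense.errors import BinMismatchError, EmptyDistributionError, MaskedMassWarning
from curvsense.stats import (
    CurvatureDistribution,
    average_distributions,
    make_bins,
    pool_sampled,
    uniformity_zscores,
)
from curvsense.surface import fit_surface


def dist(masses, width=0.04, kind="sampled", start_center=0.0, **kw):
    masses = np.asarray(masses, dtype=float)
    m0 = round(start_center / width)
    edges = (np.arange(m0, m0 + len(masses) + 1) - 0.5) * width
    return CurvatureDistribution(edges, masses, kind, **kw)


# -- binning ---------------------------------------------------------------
@given(
    lo=st.floats(-0.5, 0.5),
    hi=st.floats(-0.5, 0.5),
    width=st.sampled_from([0.02, 0.04, 0.05]),
)
def test_make_bins_lattice_and_coverage(lo, hi, width):
    edges = make_bins(lo, hi, width)
    assert edges[0] <= min(lo, hi) and edges[-1] >= max(lo, hi)
    np.testing.assert_allclose(np.diff(edges), width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    np.testing.assert_allclose(centers / width, np.round(centers / width), atol=1e-9)


# -- accessible ------------------------------------------------------------
def test_flat_surface_all_mass_in_zero_bin(sine_beads):
    pts = sine_beads.copy()
    pts[:, 2] = 2.0
    s = fit_surface(pts, (20, 10), (4, 1), leaflet="upper")
    d = cs.accessible_distribution(s, make_bins(-0.1, 0.1, 0.04))
    centers = d.centers
    assert d.masses[np.abs(centers) < 0.02] == pytest.approx(1.0)


def test_accessible_mass_positive_for_parallel_surface(upper_parallel_surface):
    """Fitted-surface path agrees with the analytic area-integration oracle.

    The curvature extrema carry integrable density spikes, so a small
    truncation shift of the extreme curvature can move spike mass across
    one bin edge; the earth-mover distance is the shift-robust comparison.
    """
    from curvsense.synthetic import analytic_accessible_histogram

    edges = make_bins(-0.25, 0.15, 0.02)
    d = cs.accessible_distribution(upper_parallel_surface, edges, grid=(1024, 8))
    assert d.masses[d.centers > 0].sum() > 0.5
    oracle = analytic_accessible_histogram(
        cs.BuckleGeometry(), "upper", edges, field="leaflet"
    )
    emd = np.abs(np.cumsum(d.masses - oracle)).sum() * d.bin_width
    assert emd < 2e-3  # 1/nm; about one bin width times the spike mass


def test_accessible_grid_convergence(upper_parallel_surface):
    edges = make_bins(-0.25, 0.15, 0.02)
    d1 = cs.accessible_distribution(upper_parallel_surface, edges, grid=(2048, 8))
    d2 = cs.accessible_distribution(upper_parallel_surface, edges, grid=(4096, 8))
    assert np.abs(d1.masses - d2.masses).max() < 1e-3


# -- reweighting -----------------------------------------------------------
def test_reweight_identity_gives_uniform():
    acc = dist([0.5, 0.3, 0.2], kind="accessible")
    sam = dist([0.5, 0.3, 0.2], kind="sampled", n_samples=1000)
    rw = cs.reweight(sam, acc)
    np.testing.assert_allclose(rw.masses, 1 / 3)
    assert rw.kind == "reweighted"


def test_reweight_point_mass_stays_point_mass():
    acc = dist([0.5, 0.3, 0.2], kind="accessible")
    sam = dist([0.0, 1.0, 0.0], kind="sampled", n_samples=100)
    rw = cs.reweight(sam, acc)
    np.testing.assert_allclose(rw.masses, [0, 1, 0])


def test_reweight_uniform_sampled_hand_computed():
    # sampled uniform over accessible (0.5, 0.3, 0.2):
    # reweighted = (2, 3.333, 5) / 10.333
    acc = dist([0.5, 0.3, 0.2], kind="accessible")
    sam = dist([1 / 3, 1 / 3, 1 / 3], kind="sampled", n_samples=300)
    rw = cs.reweight(sam, acc)
    np.testing.assert_allclose(
        rw.masses, np.array([2.0, 10 / 3, 5.0]) / (2.0 + 10 / 3 + 5.0), rtol=1e-12
    )


def test_reweight_masks_below_floor_and_warns_on_leak():
    acc = dist([0.6, 0.4, 0.0], kind="accessible")
    sam = dist([0.5, 0.4, 0.1], kind="sampled", n_samples=1000)
    with pytest.warns(MaskedMassWarning, match="10.0%"):
        rw = cs.reweight(sam, acc, floor=1e-4)
    assert not rw.support_mask[2]
    assert rw.masses[2] == 0.0
    assert rw.metadata["leaked_mass_fraction"] == pytest.approx(0.1)


def test_reweight_bin_mismatch_rejected():
    acc = dist([0.5, 0.5], kind="accessible")
    sam = dist([0.5, 0.5], width=0.02, kind="sampled", n_samples=10)
    with pytest.raises(BinMismatchError):
        cs.reweight(sam, acc)


@given(
    masses=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=12),
    sampled=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=12),
)
def test_reweight_preserves_normalization(masses, sampled):
    n = min(len(masses), len(sampled))
    acc = dist(np.array(masses[:n]) / np.sum(masses[:n]), kind="accessible")
    s = np.array(sampled[:n])
    if s.sum() == 0:
        s[0] = 1.0
    sam = dist(s / s.sum(), kind="sampled", n_samples=100)
    rw = cs.reweight(sam, acc)
    assert rw.masses.sum() == pytest.approx(1.0)
    assert np.all(rw.masses[~rw.support_mask] == 0)


# -- summaries -------------------------------------------------------------
def test_weighted_mean_and_median_point_mass():
    # single occupied bin centered at 0.1
    d = dist([0.0, 1.0, 0.0], width=0.05, start_center=0.05)
    assert cs.weighted_mean(d) == pytest.approx(0.1)
    assert cs.weighted_median(d) == pytest.approx(0.1)


def test_weighted_mean_symmetric_distribution_is_zero():
    d = dist([0.2, 0.1, 0.4, 0.1, 0.2], start_center=-0.08)
    assert cs.weighted_mean(d) == pytest.approx(0.0, abs=1e-12)


def test_weighted_summary_hand_computed():
    # masses (0.25, 0.5, 0.25) at centers (-1, 0, 1)
    edges = np.array([-1.5, -0.5, 0.5, 1.5])
    d = CurvatureDistribution(edges, [0.25, 0.5, 0.25], "reweighted")
    assert cs.weighted_mean(d) == pytest.approx(0.0)
    assert cs.weighted_median(d) == pytest.approx(0.0)


def test_empty_distribution_rejected():
    d = dist([0.0, 0.0, 0.0])
    with pytest.raises(EmptyDistributionError):
        cs.weighted_mean(d)


def test_replica_average():
    mean, sem = cs.replica_average([-0.1, -0.1, -0.1])
    assert (mean, sem) == (pytest.approx(-0.1), pytest.approx(0.0))
    mean, sem = cs.replica_average([0.0, 0.1, 0.2])
    assert mean == pytest.approx(0.1)
    assert sem == pytest.approx(0.1 / np.sqrt(3), rel=1e-6)  # 0.0577
    mean, sem = cs.replica_average([0.3])
    assert mean == pytest.approx(0.3)
    assert np.isnan(sem)
    with pytest.raises(EmptyDistributionError):
        cs.replica_average([])


def test_uniformity_zscores_under_null():
    rng = np.random.default_rng(6)
    p = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
    counts = rng.multinomial(5000, p)
    acc = dist(p, kind="accessible")
    sam = dist(counts / counts.sum(), kind="sampled", n_samples=5000)
    z = uniformity_zscores(sam, acc)
    assert np.all(np.abs(z) < 4)


# -- lattice pooling -------------------------------------------------------
def test_pool_and_average_on_shared_lattice():
    a = dist([0.5, 0.5], kind="sampled", n_samples=100, start_center=0.0)
    b = dist([0.25, 0.75], kind="sampled", n_samples=300, start_center=0.04)
    pooled = pool_sampled([a, b])
    assert pooled.n_samples == 400
    # bins: centers 0.0, 0.04, 0.08 -> counts 50, 50+75, 225
    np.testing.assert_allclose(pooled.masses, [50 / 400, 125 / 400, 225 / 400])
    avg = average_distributions([a, b])
    assert avg.masses.sum() == pytest.approx(1.0)


def test_pool_rejects_incompatible_lattice():
    a = dist([1.0], width=0.04, kind="sampled", n_samples=10)
    b = dist([1.0], width=0.02, kind="sampled", n_samples=10)
    with pytest.raises(BinMismatchError):
        pool_sampled([a, b])
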