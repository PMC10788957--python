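"""Synthetic buckled-membrane generator: beads, peptides, trajectories."""

import numpy as np
import pytest
from scipy import stats as sps

import curvsense as cs
from curvsense import geometry as g
from curvsense.errors import InsufficientSamplingError
from curvsense.synthetic import _PlacementSampler, analytic_accessible_histogram


def frames_equal(a, b):
    return (
        np.array_equal(a.upper_beads, b.upper_beads)
        and np.array_equal(a.lower_beads, b.lower_beads)
        and all(
            np.array_equal(p.position, q.position) and p.label == q.label
            for p, q in zip(a.peptides, b.peptides)
        )
    )


def test_same_seed_bitwise_identical(geometry):
    models = [cs.PeptideModel("upper"), cs.PeptideModel("lower")]
    t1 = cs.generate_trajectory(geometry, models, 5, 0.1, seed=11)
    t2 = cs.generate_trajectory(geometry, models, 5, 0.1, seed=11)
    assert all(frames_equal(a, b) for a, b in zip(t1, t2))


def test_disjoint_seeds_differ(geometry):
    f1 = cs.generate_frame(geometry, 0.1, seed=1)
    f2 = cs.generate_frame(geometry, 0.1, seed=2)
    assert not np.array_equal(f1.upper_beads, f2.upper_beads)


def test_flat_noiseless_beads_sit_at_half_thickness(flat_geometry):
    frame = cs.generate_frame(flat_geometry, 0.0, seed=0)
    np.testing.assert_array_equal(frame.upper_beads[:, 2], 2.0)
    np.testing.assert_array_equal(frame.lower_beads[:, 2], -2.0)


def test_noise_sd_recovered(flat_geometry):
    # chi-distribution bounds on the sd estimate from ~10^4 displacements
    big = cs.BuckleGeometry(amplitude=0.0, box_x=100.0, box_y=70.0, bead_density=1.5)
    frame = cs.generate_frame(big, 0.1, seed=3)
    disp = frame.upper_beads[:, 2] - 2.0
    assert len(disp) >= 10_000
    assert 0.095 <= disp.std() <= 0.105


def test_insufficient_density_rejected():
    geo = cs.BuckleGeometry(bead_density=0.2)
    with pytest.raises(InsufficientSamplingError):
        cs.generate_frame(geo, 0.1, seed=0)


def test_zero_stiffness_flat_gives_uniform_x(flat_geometry):
    model = cs.PeptideModel("upper", stiffness=0.0, depth=0.0, positional_noise=0.0)
    rng = np.random.default_rng(7)
    sampler = _PlacementSampler(flat_geometry, model, 1000)
    xs = np.array([sampler.draw(rng)[0] for _ in range(10_000)])
    # KS statistic below the 1% critical value 1.63/sqrt(n)
    stat = sps.kstest(xs / flat_geometry.box_x, "uniform").statistic
    assert stat < 1.63 / np.sqrt(len(xs))


def test_sharp_boltzmann_limit_concentrates(geometry):
    # H0 at the extreme negative membrane curvature of the upper leaflet:
    # the trough, x = 15 for A sin(q x)
    h_min = float(np.min(g.signed_membrane_curvature(geometry, np.linspace(0, 20, 2001), "upper")))
    model = cs.PeptideModel("upper", h_min, stiffness=1e6, depth=0.0, positional_noise=0.0)
    rng = np.random.default_rng(8)
    sampler = _PlacementSampler(geometry, model, 1000)
    pts = np.array([sampler.draw(rng) for _ in range(500)])
    ang = 2 * np.pi * pts[:, 0] / geometry.box_x
    # circular sd of the wrapped x coordinate
    R = abs(np.mean(np.exp(1j * ang)))
    circ_sd = np.sqrt(-2 * np.log(R)) * geometry.box_x / (2 * np.pi)
    assert circ_sd < 0.05 * geometry.box_x
    # concentrated at the trough
    assert abs(np.median(pts[:, 0]) - 15.0) < 0.5


def test_null_peptide_samples_accessible_curvature(geometry):
    """kappa = 0 placements histogram like the accessible distribution.

    Placements (depth 0, no blur) are mapped back to their midplane
    parameter by inverting the lateral map, so the sampled membrane
    curvature can be compared bin-wise (3 sigma multinomial) with the
    analytic area-weighted accessible histogram.
    """
    model = cs.PeptideModel("upper", stiffness=0.0, depth=0.0, positional_noise=0.0)
    rng = np.random.default_rng(9)
    sampler = _PlacementSampler(geometry, model, 2000)
    lateral = np.array([sampler.draw(rng)[0] for _ in range(10_000)])

    # principal-branch inverse of the (wrapped) leaflet lateral map
    xg = np.linspace(0, 20, 40001)
    Xg = g.leaflet_lateral_position(geometry, xg, "upper")

    def curvature_of_wrapped_lateral(L):
        param = np.interp(L, Xg, xg)  # clips to the principal branch
        return g.signed_membrane_curvature(geometry, param, "upper")

    h = curvature_of_wrapped_lateral(lateral)
    edges = cs.make_bins(-0.12, 0.12, 0.02)

    # oracle: fine-grid quadrature of the same deterministic assignment
    xq = np.linspace(0, 20, 200001)
    weights = g.leaflet_area_element(geometry, xq, "upper")
    hq = curvature_of_wrapped_lateral(g.leaflet_lateral_position(geometry, xq, "upper") % 20.0)
    expected, _ = np.histogram(hq, bins=edges, weights=weights)
    expected = expected / expected.sum()

    counts, _ = np.histogram(h, bins=edges)
    n = counts.sum()
    se = np.sqrt(n * expected * (1 - expected))
    z = np.abs(counts - n * expected) / np.where(se > 0, se, np.inf)
    assert np.all(z[expected > 1e-4] <= 3.5)
    # and the bulk of the distribution matches the clean analytic accessible
    clean = analytic_accessible_histogram(geometry, "upper", edges)
    assert np.abs(expected - clean).sum() < 0.15


def test_trajectory_contract(geometry):
    models = [cs.PeptideModel("upper"), cs.PeptideModel("lower")]
    frames = cs.generate_trajectory(geometry, models, 50, 0.1, seed=12)
    assert len(frames) == 50
    assert all(len(f.peptides) == 2 for f in frames)
    labels = {p.label for f in frames for p in f.peptides}
    assert labels == {"PEP1", "PEP2"}
    # frames are independent draws
    assert not np.array_equal(frames[0].upper_beads, frames[1].upper_beads)


def test_single_frame_matches_manual_subseeds(geometry):
    models = [cs.PeptideModel("upper")]
    frames = cs.generate_trajectory(geometry, models, 1, 0.1, seed=13)
    children = np.random.SeedSequence(13).spawn(1)[0].spawn(2)
    manual = cs.generate_frame(geometry, 0.1, rng=np.random.default_rng(children[0]))
    pos = cs.place_peptide(geometry, models[0], rng=np.random.default_rng(children[1]))
    assert np.array_equal(frames[0].upper_beads, manual.upper_beads)
    assert np.array_equal(frames[0].peptides[0].position, pos)


def test_coordinates_wrapped_in_lateral_box(geometry):
    frames = cs.generate_trajectory(
        geometry, [cs.PeptideModel("upper", depth=0.5)], 5, 0.2, seed=14
    )
    for f in frames:
        for arr in (f.upper_beads, f.lower_beads):
            assert np.all((arr[:, 0] >= 0) & (arr[:, 0] < geometry.box_x))
            assert np.all((arr[:, 1] >= 0) & (arr[:, 1] < geometry.box_y))
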