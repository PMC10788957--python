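"""Peptide observables: leaflet assignment, depth, sampled curvature."""

import numpy as np
import pytest

import curvsense as cs
from curvsense import geometry as g
from curvsense.errors import AmbiguousLeafletError
from curvsense.sampling import (
    assign_leaflet,
    fit_frame_surfaces,
    insertion_depth,
    leaflet_offset_estimate,
    membrane_curvature,
    nearest_surface_point,
)
from curvsense.surface import FittedSurface


def flat_surface(z, leaflet):
    coeff = np.zeros((9, 3))
    coeff[0, 0] = z
    return FittedSurface(coeff, (20.0, 10.0), (4, 1), 0.0, leaflet)


@pytest.fixture(scope="module")
def flat_pair():
    return {"upper": flat_surface(2.0, "upper"), "lower": flat_surface(-2.0, "lower")}


def test_assign_leaflet_flat(flat_pair):
    assert assign_leaflet(flat_pair, [3.0, 4.0, 1.5]) == "upper"
    assert assign_leaflet(flat_pair, [3.0, 4.0, -1.5]) == "lower"


def test_assign_leaflet_tie_is_ambiguous(flat_pair):
    with pytest.raises(AmbiguousLeafletError):
        assign_leaflet(flat_pair, [3.0, 4.0, 0.0])


def test_insertion_depth_flat(flat_pair):
    # below the upper surface = toward the membrane interior = positive
    assert insertion_depth(flat_pair["upper"], [1.0, 1.0, 1.0]) == pytest.approx(1.0)
    assert insertion_depth(flat_pair["upper"], [1.0, 1.0, 2.5]) == pytest.approx(-0.5)
    assert insertion_depth(flat_pair["lower"], [1.0, 1.0, -1.0]) == pytest.approx(1.0)


def test_nearest_point_on_curved_surface(geometry, upper_parallel_surface):
    # displace a known surface point along the inward normal; the foot of
    # the normal projection must return (approximately) the surface point
    x = 3.3
    p_surf = g.leaflet_surface_point(geometry, x, 5.0, "upper")
    inward = g.leaflet_inward_normal(geometry, x, "upper")
    probe = p_surf + 0.7 * inward
    foot = nearest_surface_point(upper_parallel_surface, probe)
    np.testing.assert_allclose(foot, p_surf, atol=5e-3)
    assert insertion_depth(upper_parallel_surface, probe) == pytest.approx(0.7, abs=5e-3)


def test_depth_sign_convention_on_curved_surface(geometry, upper_parallel_surface):
    p_surf = g.leaflet_surface_point(geometry, 8.0, 2.0, "upper")
    outward = -g.leaflet_inward_normal(geometry, 8.0, "upper")
    probe = p_surf + 0.4 * outward
    assert insertion_depth(upper_parallel_surface, probe) == pytest.approx(-0.4, abs=5e-3)


def test_membrane_curvature_matches_analytic(geometry):
    frame = cs.generate_frame(geometry, 0.0, seed=0)
    surfaces = fit_frame_surfaces(frame, (4, 1))
    xs = np.linspace(0, 20, 81)
    lat = g.leaflet_lateral_position(geometry, xs, "upper")
    est = membrane_curvature(surfaces, lat, 5.0, "upper", geometry.half_thickness)
    truth = g.signed_membrane_curvature(geometry, xs, "upper")
    assert np.abs(est - truth).max() < 6e-3


def test_leaflet_offset_estimated_from_fits(geometry):
    frame = cs.generate_frame(geometry, 0.0, seed=1)
    surfaces = fit_frame_surfaces(frame, (4, 1))
    assert leaflet_offset_estimate(surfaces) == pytest.approx(
        geometry.half_thickness, abs=0.02
    )


def test_pinned_peptide_curvature_is_frame_invariant(geometry):
    """Static noiseless buckle, peptide pinned at the crest: every frame
    reports the closed-form crest membrane curvature."""
    from curvsense.synthetic import MembraneFrame, PeptideRecord

    crest = g.leaflet_surface_point(geometry, 5.0, 5.0, "upper")
    base = cs.generate_frame(geometry, 0.0, seed=2)
    frames = [
        MembraneFrame(
            base.upper_beads, base.lower_beads,
            [PeptideRecord("PIN", "upper", crest.copy())], base.box,
        )
        for _ in range(4)
    ]
    samples, flags, _ = cs.sample_curvature(frames, (4, 1), leaflet_offset=2.0)
    assert not flags
    expected = geometry.amplitude * geometry.wavenumber**2 / 2  # +A q^2 / 2
    assert samples.curvature_per_nm.std() == pytest.approx(0.0, abs=1e-12)
    assert samples.curvature_per_nm.iloc[0] == pytest.approx(expected, abs=0.01)


def test_flat_frames_zero_curvature(flat_geometry):
    frames = cs.generate_trajectory(
        flat_geometry, [cs.PeptideModel("upper"), cs.PeptideModel("lower")], 5, 0.0, seed=3
    )
    samples, _, _ = cs.sample_curvature(frames, (4, 1))
    np.testing.assert_allclose(samples.curvature_per_nm, 0.0, atol=1e-6)


def test_depth_recovery_short_run(geometry):
    models = [
        cs.PeptideModel("upper", depth=0.8, positional_noise=0.1),
        cs.PeptideModel("lower", depth=0.8, positional_noise=0.1),
    ]
    frames = cs.generate_trajectory(geometry, models, 300, 0.1, seed=4)
    samples, _, _ = cs.sample_curvature(frames, (4, 1))
    assert samples.depth_nm.mean() == pytest.approx(0.8, abs=0.02)


def test_midplane_crosser_flagged_not_reassigned(geometry):
    from curvsense.synthetic import MembraneFrame, PeptideRecord

    base = cs.generate_frame(geometry, 0.0, seed=5)
    # labelled upper but sitting on the lower leaflet surface
    stray = g.leaflet_surface_point(geometry, 4.0, 5.0, "lower")
    frame = MembraneFrame(
        base.upper_beads, base.lower_beads,
        [PeptideRecord("STRAY", "upper", stray)], base.box,
    )
    samples, flags, _ = cs.sample_curvature([frame], (4, 1))
    assert samples.empty
    assert flags == [(0, "STRAY", "nearest surface is lower")]


def test_unlabelled_peptides_assigned_by_nearest_surface(geometry):
    from curvsense.synthetic import MembraneFrame, PeptideRecord

    base = cs.generate_frame(geometry, 0.0, seed=6)
    pos = g.leaflet_surface_point(geometry, 12.0, 3.0, "lower")
    frame = MembraneFrame(
        base.upper_beads, base.lower_beads,
        [PeptideRecord("PEP1", None, pos)], base.box,
    )
    samples, flags, _ = cs.sample_curvature([frame], (4, 1))
    assert samples.leaflet.tolist() == ["lower"]
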