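import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import filamentforge as ff
from filamentforge.screw import GeometryError

Z = np.array([0.0, 0.0, 1.0])


def cloud(n=9, seed=0, scale=6.0):
    return np.random.default_rng(seed).normal(size=(n, 3)) * scale


def test_identity_pair_gives_zero_screw():
    pts = cloud()
    t = ff.fit_screw(pts, pts)
    assert t.angle_per_step == pytest.approx(0.0, abs=1e-9)
    assert t.translation_per_step == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("angle,translation,axis_dir,axis_point", [
    (60.0, 15.3, Z, np.zeros(3)),
    (60.0, 15.3, Z, np.array([3.0, -2.0, 5.0])),
    (-47.5, 4.2, np.array([1.0, 2.0, 2.0]) / 3.0, np.array([1.0, 1.0, 0.0])),
    (170.0, 0.8, np.array([0.0, 1.0, 0.0]), np.array([-4.0, 0.0, 2.0])),
    (20.0, 5.1, Z, np.zeros(3)),
])
def test_forward_construct_then_fit_recovers_parameters(angle, translation,
                                                        axis_dir, axis_point):
    """Oracle equivalence: a screw applied to points is recovered exactly."""
    true = ff.ScrewTransform(axis_point, axis_dir, angle, translation)
    pts = cloud(12, seed=3)
    fit = ff.fit_screw(pts, true.transform_points(pts))
    # canonical orientation may flip axis+angle together
    sign = 1.0 if fit.axis_dir @ true.axis_dir > 0 else -1.0
    assert sign * fit.angle_per_step == pytest.approx(angle, abs=1e-6)
    assert sign * fit.translation_per_step == pytest.approx(translation, abs=1e-6)
    assert np.allclose(sign * fit.axis_dir, true.axis_dir, atol=1e-6)
    # the fitted motion reproduces the mapped points
    assert np.allclose(fit.transform_points(pts), true.transform_points(pts), atol=1e-6)


def test_fit_rejects_degenerate_inputs():
    with pytest.raises(GeometryError):
        ff.fit_screw(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), np.array([1.0, 1.0, 0.0]))
    with pytest.raises(GeometryError):
        ff.fit_screw(line, line + 1.0)


@given(n=st.integers(-6, 6), angle=st.floats(-170, 170), translation=st.floats(-20, 20))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_screw_composition_matches_scaled_single_step(n, angle, translation):
    """n steps of a screw equal one step with n*angle, n*translation."""
    t = ff.ScrewTransform(np.array([1.0, -2.0, 0.5]), np.array([2.0, 1.0, 3.0]),
                          angle, translation)
    pts = cloud(5, seed=1)
    stepwise = pts.copy()
    for _ in range(abs(n)):
        stepwise = t.transform_points(stepwise, 1 if n >= 0 else -1)
    assert np.allclose(stepwise, t.transform_points(pts, n), atol=1e-8)


def test_apply_screw_is_rigid_and_invertible(filament_strand_18):
    t = ff.ScrewTransform(np.zeros(3), Z, 60.0, 15.3)
    s = filament_strand_18
    moved = ff.apply_screw(t, s, 3)
    d0 = np.linalg.norm(s.coords[:, None] - s.coords[None], axis=-1)
    d1 = np.linalg.norm(moved.coords[:, None] - moved.coords[None], axis=-1)
    assert np.allclose(d0, d1, atol=1e-9)                      # rigid motion
    assert np.allclose(ff.apply_screw(t, s, 0).coords, s.coords)
    back = ff.apply_screw(t, moved, -3)
    assert np.allclose(back.coords, s.coords, atol=1e-9)       # inverse


def test_six_filament_steps_close_one_turn():
    t = ff.ScrewTransform(np.zeros(3), Z, 60.0, 15.3)
    rot, offset = t.matrix(6)
    assert np.allclose(rot, np.eye(3), atol=1e-12)             # net 360°
    assert np.allclose(offset, [0, 0, 6 * 15.3])


def test_replicate_single_copy_is_identity(filament_strand_18):
    t = ff.ScrewTransform(np.zeros(3), Z, 60.0, 15.3)
    rep = ff.replicate_along_screw(filament_strand_18, t, 1)
    assert np.allclose(rep.coords, filament_strand_18.coords)
    with pytest.raises(ValueError):
        ff.replicate_along_screw(filament_strand_18, t, 0)


def test_replicated_trinucleotide_spans_one_turn():
    """Six screw copies of a 3-nt fragment: 18 residues, one helical turn."""
    tri = ff.build_filament_strand("TTT")
    t = ff.ScrewTransform(np.zeros(3), Z, 60.0, 15.3)
    rep = ff.replicate_along_screw(tri, t, 6)
    assert rep.residue_indices("A") == list(range(1, 19))
    p = rep.atom_positions("A", "P")
    assert p[:, 2].max() - p[:, 2].min() == pytest.approx(5 * 15.3 + 2 * 3.6, abs=1e-9)
    # copy k un-screwed reproduces copy 0 exactly
    for k in (1, 3, 5):
        copy_k = p[3 * k:3 * k + 3]
        assert np.allclose(t.transform_points(copy_k, -k), p[:3], atol=1e-9)
    # axial extent of the screw itself: 6 copies advance 6 steps
    assert t.transform_points(np.zeros((1, 3)), 6)[0, 2] == pytest.approx(6 * 15.3)


def test_replication_splits_concatenate():
    tri = ff.build_filament_strand("TTT")
    t = ff.ScrewTransform(np.zeros(3), Z, 60.0, 15.3)
    whole = ff.replicate_along_screw(tri, t, 5)
    first = ff.replicate_along_screw(tri, t, 2)
    rest = ff.apply_screw(t, ff.replicate_along_screw(tri, t, 3), 2)
    combined = np.vstack([first.coords, rest.coords])
    assert np.allclose(whole.coords, combined, atol=1e-9)


def test_infer_axis_recovers_build_frame(filament_strand_18):
    axis = ff.infer_axis(filament_strand_18, 3)
    assert np.allclose(np.abs(axis.direction), Z, atol=1e-6)
    assert np.linalg.norm(axis.point[:2]) == pytest.approx(0.0, abs=1e-6)


def test_infer_axis_is_equivariant_under_rotation(filament_strand_18, rng):
    from conftest import random_rigid
    rot, trans = random_rigid(rng)
    moved = filament_strand_18.with_coords(filament_strand_18.coords @ rot.T + trans)
    axis = ff.infer_axis(moved, 3)
    expected = rot @ Z
    assert min(np.linalg.norm(axis.direction - expected),
               np.linalg.norm(axis.direction + expected)) < 1e-6


def test_infer_axis_stable_under_noise(filament_strand_18):
    """Gaussian sigma=0.3 Å: recovered axis within 2° of +z, 20 seeds."""
    for seed in range(20):
        noisy = ff.perturb_structure(filament_strand_18, 0.3, seed)
        axis = ff.infer_axis(noisy, 3)
        angle = np.degrees(np.arccos(np.clip(abs(axis.direction @ Z), -1, 1)))
        assert angle < 2.0


def test_infer_axis_needs_two_periods():
    short = ff.build_filament_strand("TTT")
    with pytest.raises(GeometryError, match="residues"):
        ff.infer_axis(short, 3)
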