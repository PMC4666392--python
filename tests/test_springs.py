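import numpy as np
import pytest

import filamentforge as ff
from filamentforge import springs
from filamentforge.springs import ClosureError, SpringNetwork
from filamentforge.structure import Atom, Structure


def two_node_network(r0=2.0, k=0.5, stretch=0.0):
    atoms = [Atom("P", "P", np.zeros(3), 1, "DT", "A"),
             Atom("P", "P", np.array([r0 + stretch, 0.0, 0.0]), 2, "DT", "A")]
    s = Structure(atoms)
    return SpringNetwork(s, np.array([[0, 1]]), np.array([k]), np.array([r0]),
                         np.zeros(0, int), np.zeros(0), np.zeros((0, 3)),
                         np.zeros((0, 2), int), np.zeros(0), np.zeros(0))


def test_energy_zero_at_rest_length():
    assert two_node_network().energy() == 0.0


def test_stretched_bond_energy_closed_form():
    """E = k * dr^2 convention: 1 Å stretch at k = 0.5 gives 0.5 kcal/mol."""
    assert two_node_network(stretch=1.0).energy() == pytest.approx(0.5)


def test_analytic_gradient_matches_central_difference(default_model, rng):
    """<= 1e-4 relative agreement over 50 random configurations."""
    net = springs.build_network(default_model)
    base = default_model.coords.ravel()
    h = 1e-6
    for trial in range(50):
        x = base + rng.normal(0, 0.4, base.size)
        _, g = net.energy_and_gradient(x)
        probe = rng.integers(0, base.size, size=6)
        for i in probe:
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num = (net.energy_and_gradient(xp)[0] - net.energy_and_gradient(xm)[0]) / (2 * h)
            assert abs(g[i] - num) <= 1e-4 * max(1.0, abs(num))


def test_minimize_is_monotone_and_deterministic(default_model):
    pert = ff.perturb_structure(default_model, 0.8, 11)
    net = springs.build_network(default_model)
    r1, t1 = springs.minimize(net, start_coords=pert.coords)
    r2, t2 = springs.minimize(net, start_coords=pert.coords)
    assert np.diff(t1).max() <= 1e-9                 # non-increasing energy
    assert t1 == t2                                  # bitwise deterministic
    assert np.array_equal(r1.coords, r2.coords)


def test_trace_matches_recomputed_energy(default_model):
    pert = ff.perturb_structure(default_model, 0.5, 5)
    net = springs.build_network(default_model)
    relaxed, trace = springs.minimize(net, start_coords=pert.coords)
    assert trace[-1] == pytest.approx(net.energy(relaxed.coords), abs=1e-9)


def test_already_minimal_network_unchanged(default_model):
    net = springs.build_network(default_model)
    relaxed, trace = springs.minimize(net)
    assert trace[0] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(relaxed.coords, default_model.coords, atol=1e-9)


def test_single_stretched_bond_converges_to_rest_length():
    net = two_node_network(r0=2.0, k=0.5, stretch=1.3)
    relaxed, trace = springs.minimize(net, tol=1e-12)
    d = np.linalg.norm(relaxed.coords[1] - relaxed.coords[0])
    assert d == pytest.approx(2.0, abs=1e-6)
    assert trace[-1] < trace[0]


def test_non_finite_start_rejected(default_model):
    net = springs.build_network(default_model)
    bad = default_model.coords.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        springs.minimize(net, start_coords=bad)


def test_anchored_recovery_from_noise():
    """sigma = 1 Å perturbation of the ideal filament relaxes back onto the
    anchored phosphate positions (RMSD < 0.3 Å, fixed seed)."""
    ideal = ff.build_filament_strand("T" * 18)
    net = springs.build_network(ideal)
    pidx = np.array([i for i, a in enumerate(ideal.atoms) if a.name == "P"])
    net.anchor_idx = pidx
    net.anchor_k = np.full(len(pidx), 0.5)
    net.anchor_target = ideal.coords[pidx]
    pert = ff.perturb_structure(ideal, 1.0, 42)
    relaxed, _ = springs.minimize(net, start_coords=pert.coords)
    rmsd = np.sqrt(np.mean(np.sum((relaxed.coords[pidx] - ideal.coords[pidx]) ** 2, axis=1)))
    assert rmsd < 0.3


class TestCloseBackbone:
    def fragments(self, gap=0.0):
        """Six screw-replicated trinucleotides; optionally misplace the
        terminal O3' of every fragment by ``gap`` Å to open the junctions."""
        tri = ff.build_filament_strand("TTT")
        if gap:
            o3 = tri.atom("A", 3, "O3'")
            o3.position = o3.position + np.array([0.0, 0.0, gap])
        screw = ff.ScrewTransform(np.zeros(3), [0, 0, 1], 60.0, 15.3)
        return [ff.apply_screw(screw, tri, k) for k in range(6)], screw

    def test_continuous_fragments_are_a_no_op(self):
        frags, screw = self.fragments(0.0)
        closed = springs.close_backbone(frags, screw)
        stacked = np.vstack([f.coords for f in frags])
        assert np.allclose(closed.coords, stacked, atol=1e-6)
        assert closed.residue_indices("A") == list(range(1, 19))

    def test_gapped_junctions_close_to_bonding_distance(self):
        frags, screw = self.fragments(0.8)
        pre = np.vstack([f.coords for f in frags])
        closed = springs.close_backbone(frags, screw)
        drifts = []
        for r in range(3, 18, 3):
            o3 = closed.atom("A", r, "O3'").position
            p = closed.atom("A", r + 1, "P").position
            assert abs(np.linalg.norm(o3 - p) - 1.6) < 0.2
        p_idx = [i for i, a in enumerate(closed.atoms) if a.name == "P"]
        o3_moves = []
        for i, a in enumerate(closed.atoms):
            d = np.linalg.norm(closed.coords[i] - pre[i])
            if a.name == "P":
                drifts.append(d)
            if a.name == "O3'" and a.residue_index % 3 == 0 and a.residue_index < 18:
                o3_moves.append(d)
        assert max(drifts) < 0.5                 # anchored phosphates stay put
        assert max(drifts) < min(o3_moves)       # closure happens at the bond

    def test_oversized_gap_raises_with_junction_index(self):
        frags, screw = self.fragments(12.0)
        with pytest.raises(ClosureError) as err:
            springs.close_backbone(frags, screw)
        assert err.value.junction_index is not None


@pytest.fixture(scope="module")
def strand():
    return ff.build_filament_strand("T" * 9, ff.HelicalParams(radius=12.0))


class TestRadialPull:

    def test_noop_at_current_radius(self, strand):
        pulled = springs.radial_pull(strand, [1, 2, 4, 5, 7, 8], 12.0)
        assert np.allclose(pulled.coords, strand.coords, atol=0.05)

    def test_selected_phosphates_reach_target(self, strand):
        """Thymine phosphates 1,2,4,5,7,8 pulled from 12 Å to the favorable
        15 Å site-II radius."""
        pulled = springs.radial_pull(strand, [1, 2, 4, 5, 7, 8], 15.0)
        axis = ff.Axis(np.zeros(3), [0, 0, 1])
        radii = axis.radii(pulled.atom_positions("A", "P", [1, 2, 4, 5, 7, 8]))
        assert abs(radii.mean() - 15.0) <= 0.3
        assert np.all(np.abs(radii - 15.0) <= 0.3)

    def test_helical_symmetry_preserved(self, strand):
        """Constant-helical-symmetry condition: the period-3 screw of the
        strand survives the pull within 1%."""
        pulled = springs.radial_pull(strand, [1, 2, 4, 5, 7, 8], 15.0)
        pre = ff.fit_screw(strand.select(residues=[1, 2, 3]).coords,
                           strand.select(residues=[4, 5, 6]).coords)
        post = ff.fit_screw(pulled.select(residues=[1, 2, 3]).coords,
                            pulled.select(residues=[4, 5, 6]).coords)
        assert abs(post.angle_per_step - pre.angle_per_step) <= 0.01 * abs(pre.angle_per_step)
        assert abs(post.translation_per_step - pre.translation_per_step) \
            <= 0.01 * abs(pre.translation_per_step)

    def test_azimuthal_ordering_preserved(self, strand):
        pulled = springs.radial_pull(strand, [1, 2, 4, 5, 7, 8], 15.0)
        p = pulled.atom_positions("A", "P")
        phis = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
        assert np.all(np.diff(np.unwrap(np.radians(phis))) > 0)   # no pass-through

    def test_invalid_target_rejected(self, strand):
        with pytest.raises(ValueError):
            springs.radial_pull(strand, [1], -2.0)
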