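import math

import numpy as np
import pytest

import filamentforge as ff
from filamentforge import config as cfg
from filamentforge import metrics
from filamentforge.builder import (DegenerateModelError, FlipStateError,
                                   SequenceError)


class TestBDna:
    def test_single_pair_duplex(self):
        d = ff.build_bdna("A")
        assert set(d.chains()) == {"A", "B"}
        assert len(d.residue_indices("A")) == 1
        assert len(d.residue_indices("B")) == 1
        assert d.atoms[0].residue_name == "DA"

    def test_axial_length_closed_form(self):
        d = ff.build_bdna("A" * 30)
        p = d.atom_positions("A", "P")
        assert p[-1, 2] - p[0, 2] == pytest.approx(29 * 3.38, abs=1e-9)

    def test_net_twist_closed_form(self):
        d = ff.build_bdna("ACGTACGTAC")
        steps = ff.step_parameters(d.select(chain_id="A"))
        assert sum(s.twist for s in steps) == pytest.approx(9 * 36.0, abs=1e-9)

    def test_extension_factor_is_unity(self):
        assert ff.extension_factor(ff.build_bdna("ACGTAC")) == pytest.approx(1.0)

    def test_invalid_character_rejected(self):
        with pytest.raises(SequenceError):
            ff.build_bdna("ACGU")

    def test_complementary_strand_sequence(self):
        d = ff.build_bdna("ACG")
        names_b = [d.atom("B", r, "P").residue_name for r in (1, 2, 3)]
        assert names_b == ["DC", "DG", "DT"]   # reverse complement 5'->3'


class TestFilamentStrand:
    def test_mean_rise_and_twist_over_whole_triplets(self, filament_strand_18):
        tm = ff.triplet_means(ff.step_parameters(filament_strand_18))
        assert tm["rise"] == pytest.approx(5.1, abs=1e-9)
        assert tm["twist"] == pytest.approx(20.0, abs=1e-9)

    def test_net_twist_one_turn_per_18_nt(self, filament_strand_18):
        tm = ff.triplet_means(ff.step_parameters(filament_strand_18))
        assert 18 * tm["twist"] == pytest.approx(360.0, abs=1e-6)

    def test_bform_parameters_reproduce_bdna_strand(self):
        strand = ff.build_filament_strand("ACGTAC", ff.HelicalParams.bform())
        duplex = ff.build_bdna("ACGTAC")
        a = duplex.select(chain_id="A").coords
        rmsd = np.sqrt(np.mean(np.sum((strand.coords - a) ** 2, axis=1)))
        assert rmsd < 1e-6

    def test_uniform_helix_pp_matches_chord_formula(self):
        params = ff.HelicalParams.uniform(5.1, 20.0, 15.0)
        s = ff.build_filament_strand("T" * 9, params)
        steps = ff.step_parameters(s, ff.Axis(np.zeros(3), [0, 0, 1]))
        chord = math.sqrt((2 * 15.0 * math.sin(math.radians(10.0))) ** 2 + 5.1 ** 2)
        for st in steps:
            assert st.pp_distance == pytest.approx(chord, abs=1e-9)
        assert chord == pytest.approx(7.29, abs=0.01)

    def test_non_multiple_of_three_warns(self):
        with pytest.warns(UserWarning):
            ff.build_filament_strand("TTTT")

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            ff.HelicalParams(radius=-1.0)

    def test_mean_invariant_of_params(self):
        p = ff.HelicalParams()
        assert (2 * p.intra_rise + p.inter_rise) / 3 == pytest.approx(p.mean_rise)
        assert (2 * p.intra_twist + p.inter_twist) / 3 == pytest.approx(p.mean_twist)
        assert p.mean_rise == pytest.approx(5.1)
        assert p.mean_twist == pytest.approx(20.0)


class TestSynapticModel:
    def test_roles_and_chains(self, default_model):
        assert default_model.roles == {"I": ff.INITIATING, "C": ff.COMPLEMENTARY,
                                       "O": ff.OUTGOING}
        assert len(default_model.residue_indices("I")) == 6
        assert len(default_model.residue_indices("C")) == 18
        assert len(default_model.residue_indices("O")) == 18

    def test_strand_radii(self, default_model):
        axis = ff.Axis(np.zeros(3), [0, 0, 1])
        rngs = default_model.metadata["site2"]["ranges"]
        for chain, expected in (("I", 9.0), ("C", 12.0), ("O", 15.0)):
            lo, hi = rngs[chain]
            seg = default_model.select(chain_id=chain, residues=range(lo, hi + 1))
            _, mean = ff.strand_radius(seg, axis)
            assert mean == pytest.approx(expected, abs=1e-9)

    def test_registration_slab(self, default_model):
        verdict, _ = ff.registration_check(default_model)
        assert verdict == [True, True]

    def test_pp_ordering_outgoing_exceeds_initiating(self, default_model):
        axis = ff.Axis(np.zeros(3), [0, 0, 1])
        rngs = default_model.metadata["site2"]["ranges"]
        pp = {}
        for chain in ("I", "O"):
            lo, hi = rngs[chain]
            seg = default_model.select(chain_id=chain, residues=range(lo, hi + 1))
            pp[chain] = ff.triplet_means(ff.step_parameters(seg, axis))["pp"]
        assert pp["O"] > pp["I"]

    def test_within_triplet_backbone_connectivity(self, default_model):
        """Consecutive P-P stays below 8 Å inside triplets (the stretched
        inter-triplet step is the stacking interruption)."""
        rngs = default_model.metadata["site2"]["ranges"]
        for chain in ("I", "C", "O"):
            lo, hi = rngs[chain]
            p = default_model.atom_positions(chain, "P", list(range(lo, hi + 1)))
            d = np.linalg.norm(np.diff(p, axis=0), axis=1)
            for k, dist in enumerate(d):
                if k % 3 != 2:          # within-triplet steps
                    assert dist < 8.0

    def test_smallest_valid_model(self):
        stub = ff.build_synaptic_model("TTT", ff.TripletPattern(1, 0, 0))
        assert len(stub.residue_indices("C")) == 3
        verdict, _ = ff.registration_check(stub)
        assert verdict == [True]

    def test_insufficient_sequence_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            ff.build_synaptic_model("TTT", ff.TripletPattern(2, 6, 6))

    def test_degenerate_model_rejected(self):
        with pytest.raises(DegenerateModelError):
            ff.build_synaptic_model("TTT", ff.TripletPattern(0, 0, 0))

    def test_junction_gap_bounded(self, default_model):
        """The O3'-P linkage across each junction is at bonding distance
        before any relaxation."""
        for chain in ("C", "O"):
            p = default_model.atom_positions(chain, "P")
            residues = default_model.residue_indices(chain)
            for r in residues[:-1]:
                o3 = default_model.atom(chain, r, "O3'").position
                nxt = default_model.atom(chain, r + 1, "P").position
                assert np.linalg.norm(o3 - nxt) == pytest.approx(1.6, abs=1e-9)


class TestJunction:
    @pytest.mark.parametrize("bend", [0.0, 45.0, 90.0, 120.0])
    def test_bend_angle_recovered_from_synaptic_tails(self, bend):
        m = ff.build_synaptic_model("T" * 20, ff.TripletPattern(2, 6, 6, bend))
        for angle in ff.junction_angles(m):
            assert angle == pytest.approx(bend, abs=0.5)

    def test_standalone_junction_operator(self):
        fil = ff.make_postsynaptic_reference(9)
        tail = ff.build_bdna("ACGTAC")
        joined = ff.build_junction(tail, fil, 90.0)
        assert ff.junction_angle(joined) == pytest.approx(90.0, abs=0.5)

    def test_standalone_junction_gap_small_for_matched_duplexes(self):
        fil = ff.build_bdna("ACGTAC")
        moved = fil.copy()
        for a in moved.atoms:
            a.chain_id = {"A": "X", "B": "Y"}[a.chain_id]
        tail = ff.build_bdna("GGCCTT")
        joined = ff.build_junction(tail, moved, 0.0)
        # attachment gap per strand: B-form continuation is nearly seamless
        top_x = joined.atom("X", 6, "P").position
        first_a = joined.atom("A", 1, "P").position
        assert np.linalg.norm(top_x - first_a) < 2.0 + cfg.JUNCTION_STEP

    def test_shared_chain_ids_rejected(self):
        fil = ff.build_bdna("ACGTAC")
        with pytest.raises(ValueError, match="chain ids"):
            ff.build_junction(ff.build_bdna("ACGTAC"), fil, 90.0)


class TestDupletFlip:
    def test_preconditions_and_postconditions(self, default_model):
        pre = metrics.all_basepair_metrics(default_model)
        d1_ref, _ = metrics.paired_reference()
        for bp in pre:
            assert bp.D1 > d1_ref          # all complementary bases start far
            assert bp.state == "unflipped"
        flipped = ff.flip_duplet(default_model, 1)
        post = {b.pair_index: b for b in metrics.all_basepair_metrics(flipped)}
        # triplet 1 = pairs 1..3; the comp 5'-duplet are pairs 2 and 3
        assert post[2].state == "paired" and post[3].state == "paired"
        assert post[2].D1 == pytest.approx(d1_ref, abs=1e-9)
        assert post[1].state == "unflipped"          # 3' base did not flip
        for i in (4, 5, 6):
            assert post[i].state == "unflipped"

    def test_outgoing_strand_untouched_and_move_is_local(self, default_model):
        flipped = ff.flip_duplet(default_model, 1)
        before, after = default_model.coords, flipped.coords
        moved = {}
        for a_before, a_after, atom in zip(before, after, default_model.atoms):
            if not np.allclose(a_before, a_after, atol=1e-12):
                moved.setdefault(atom.chain_id, set()).add((atom.residue_index, atom.name))
        assert set(moved) == {"C"}
        res_moved = {r for r, _ in moved["C"]}
        full_nucleotides = {r for r in res_moved
                            if {"P", "C1'", "CEN"} <= {n for rr, n in moved["C"] if rr == r}}
        assert len(full_nucleotides) == 2            # exactly the duplet
        linking_only = res_moved - full_nucleotides
        for r in linking_only:
            assert {n for rr, n in moved["C"] if rr == r} <= {"O3'"}

    def test_flip_moves_bases_radially_registration_kept(self, default_model):
        flipped = ff.flip_duplet(ff.flip_duplet(default_model, 1), 2)
        verdict, _ = ff.registration_check(flipped)
        assert verdict == [True, True]

    def test_two_triplet_flip_pattern(self, default_model):
        """Both duplets exchanged: flipped duplet / unflipped pair /
        flipped duplet along the complementary strand."""
        flipped = ff.flip_duplet(ff.flip_duplet(default_model, 1), 2)
        states = {b.pair_index: b.state for b in metrics.all_basepair_metrics(flipped)}
        assert [states[i] for i in range(1, 7)] == [
            "unflipped", "paired", "paired", "unflipped", "paired", "paired"]

    def test_double_flip_rejected(self, default_model):
        once = ff.flip_duplet(default_model, 1)
        with pytest.raises(FlipStateError):
            ff.flip_duplet(once, 1)

    def test_flip_outside_site_ii_rejected(self, default_model):
        with pytest.raises(IndexError):
            ff.flip_duplet(default_model, 3)


class TestPostsynapticReference:
    def test_all_pairs_classify_paired(self, postsynaptic):
        for bp in metrics.all_basepair_metrics(postsynaptic):
            assert bp.state == "paired"
            assert bp.D1 == pytest.approx(10.4, abs=1e-9)

    def test_extension_factor_filament_value(self, postsynaptic):
        assert ff.extension_factor(postsynaptic) == pytest.approx(1.51, abs=0.01)

    def test_registration_passes(self, postsynaptic):
        verdict, _ = ff.registration_check(postsynaptic)
        assert verdict == [True, True, True]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ff.make_postsynaptic_reference(2)
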