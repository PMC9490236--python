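"""Data model, internal-coordinate building and symmetry transforms."""

import numpy as np
import pytest

from cyclodesign.geometry import IDEAL, dihedral, place_atom, wrap_angle
from cyclodesign.model import (MacrocycleSequence, ResidueSpec,
                               build_from_torsions, measure_torsions,
                               mirror, cyclic_permute, thread_sequence)

from conftest import random_torsions


class TestResidueSpec:
    def test_achiral_identities_reject_handedness(self):
        with pytest.raises(ValueError):
            ResidueSpec("GLY", "L")
        with pytest.raises(ValueError):
            ResidueSpec("AIB", "D")

    def test_proline_cannot_be_n_methylated(self):
        with pytest.raises(ValueError):
            ResidueSpec("PRO", "L", n_methyl=True)

    def test_code_round_trip(self):
        for code in ("ALA", "D-LEU", "GLY", "DPR", "AIB"):
            r = ResidueSpec.from_code(code)
            assert ResidueSpec.from_code(r.code) == r

    def test_d_residues_use_component_dictionary_names(self):
        assert ResidueSpec("PRO", "D").pdb_name == "DPR"
        assert ResidueSpec("PHE", "D").pdb_name == "DPH"

    def test_nh_presence(self):
        assert not ResidueSpec("PRO", "L").has_nh
        assert not ResidueSpec("VAL", "L", True).has_nh
        assert ResidueSpec("VAL", "L").has_nh


class TestSequence:
    def test_cyclic_indexing(self):
        seq = MacrocycleSequence.polyglycine(6)
        assert seq[6] is seq[0]
        assert seq[-1] is seq[5]

    def test_equality_is_positionwise(self):
        seq = MacrocycleSequence([ResidueSpec("ALA", "L"),
                                  ResidueSpec("VAL", "L")])
        assert seq != seq.permuted(1)
        assert seq == MacrocycleSequence(list(seq.residues))

    def test_json_round_trip(self, mixed_seq8):
        again = MacrocycleSequence.from_json_obj(mixed_seq8.to_json_obj())
        assert again == mixed_seq8


class TestPlaceAtom:
    @pytest.mark.parametrize("tor", [-150.0, -60.0, 0.0, 60.0, 120.0, 180.0])
    def test_inverse_pair_with_dihedral(self, tor):
        a = np.array([0.2, -0.1, 0.3])
        b = np.array([1.5, 0.0, 0.1])
        c = np.array([2.0, 1.4, -0.2])
        d = place_atom(a, b, c, 1.33, 114.0, tor)
        assert dihedral(a, b, c, d) == pytest.approx(tor, abs=1e-9)
        assert np.linalg.norm(d - c) == pytest.approx(1.33, abs=1e-12)


class TestBuildMeasure:
    def test_round_trip_on_closed_ring(self, ring8):
        rebuilt = build_from_torsions(ring8.sequence, ring8.torsions)
        m = measure_torsions(rebuilt)
        assert np.abs(wrap_angle(m - ring8.torsions)).max() < 1e-6

    def test_round_trip_non_cut_torsions_open_chain(self):
        rng = np.random.default_rng(0)
        seq = MacrocycleSequence.polyglycine(7)
        t = random_torsions(rng, 7)
        m = measure_torsions(build_from_torsions(seq, t))
        dev = np.abs(wrap_angle(m - t))
        dev[0, 0] = dev[6, 1] = dev[6, 2] = 0.0  # cut-crossing torsions
        assert dev.max() < 1e-6

    def test_trans_ca_ca_distance_matches_closed_form(self):
        # law-of-cosines chain on the ideal peptide-bond internal
        # coordinates, omega = 180 (planar trans)
        g = IDEAL
        seq = MacrocycleSequence.polyglycine(6)
        t = np.zeros((6, 3))
        t[:, 0], t[:, 1], t[:, 2] = -70.0, -40.0, 180.0
        conf = build_from_torsions(seq, t)
        d = np.linalg.norm(conf.atom("CA", 1) - conf.atom("CA", 0))

        def _expected(omega_deg):
            ca_c, c_n, n_ca = g.ca_c, g.c_n, g.n_ca
            a1 = np.deg2rad(g.ca_c_n)
            a2 = np.deg2rad(g.c_n_ca)
            w = np.deg2rad(omega_deg)
            # explicit trigonometric chain CA-C-N-CA
            c_pos = np.array([ca_c, 0.0, 0.0])
            n_pos = c_pos + c_n * np.array([-np.cos(a1), np.sin(a1), 0.0])
            e = (c_pos - n_pos) / np.linalg.norm(c_pos - n_pos)
            perp = np.array([-e[1], e[0], 0.0])
            ca2 = (n_pos + n_ca * (np.cos(a2) * e +
                                   np.sin(a2) * (np.cos(w) * -perp +
                                                 np.sin(w) *
                                                 np.array([0.0, 0.0, 1.0]))))
            return np.linalg.norm(ca2)

        expected = max(_expected(180.0), _expected(0.0))
        assert d == pytest.approx(3.8, abs=0.05)
        assert d == pytest.approx(expected, abs=1e-6)

    def test_cis_bond_shortens_ca_ca(self):
        seq = MacrocycleSequence.polyglycine(6)
        t = np.zeros((6, 3))
        t[:, 0], t[:, 1] = -70.0, -40.0
        t[:, 2] = 180.0
        d_trans = np.linalg.norm(build_from_torsions(seq, t).atom("CA", 1) -
                                 build_from_torsions(seq, t).atom("CA", 0))
        t[:, 2] = 0.0
        c = build_from_torsions(seq, t)
        d_cis = np.linalg.norm(c.atom("CA", 1) - c.atom("CA", 0))
        assert d_cis < d_trans

    def test_rejects_wrong_shapes_and_nonfinite(self):
        seq = MacrocycleSequence.polyglycine(6)
        with pytest.raises(ValueError):
            build_from_torsions(seq, np.zeros((5, 3)))
        bad = np.zeros((6, 3))
        bad[2, 1] = np.nan
        with pytest.raises(ValueError):
            build_from_torsions(seq, bad)

    def test_measured_torsions_rotation_invariant(self, ring8):
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = ring8.copy()
        for k, arr in moved.coords.items():
            moved.coords[k] = arr @ rot.T + np.array([5.0, -3.0, 2.0])
        dev = np.abs(wrap_angle(measure_torsions(moved) - ring8.torsions))
        assert dev.max() < 1e-8


class TestSymmetryTransforms:
    def test_mirror_is_involution(self, ring8):
        back = mirror(mirror(ring8))
        for k in ring8.coords:
            assert np.allclose(back.coords[k], ring8.coords[k],
                               atol=1e-12, equal_nan=True)
        assert back.sequence == ring8.sequence

    def test_mirror_negates_torsions_and_swaps_chirality(self, mixed_seq8):
        rng = np.random.default_rng(4)
        conf = build_from_torsions(mixed_seq8, random_torsions(rng, 8))
        m = mirror(conf)
        assert np.abs(wrap_angle(m.torsions + conf.torsions)).max() < 1e-9
        assert np.abs(wrap_angle(measure_torsions(m) +
                                 measure_torsions(conf))).max() < 1e-6
        for a, b in zip(conf.sequence, m.sequence):
            if a.chirality == "achiral":
                assert b.chirality == "achiral"
            else:
                assert {a.chirality, b.chirality} == {"L", "D"}

    def test_cyclic_permute_identity_and_inverse(self, ring8):
        assert np.allclose(cyclic_permute(ring8, 0).torsions, ring8.torsions)
        n = len(ring8)
        back = cyclic_permute(cyclic_permute(ring8, 3), n - 3)
        for k in ring8.coords:
            assert np.allclose(back.coords[k], ring8.coords[k],
                               equal_nan=True)

    def test_permute_commutes_with_build(self, ring8):
        k = 3
        perm = cyclic_permute(ring8, k)
        rebuilt = build_from_torsions(perm.sequence, perm.torsions)
        from cyclodesign.landscape import backbone_rmsd
        assert backbone_rmsd(rebuilt, perm) < 1e-6

    def test_thread_sequence_replaces_identities(self, ring8, mixed_seq8):
        threaded = thread_sequence(ring8, mixed_seq8)
        assert threaded.sequence == mixed_seq8
        assert np.allclose(threaded.torsions, ring8.torsions)
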