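"""Surrogate scoring: invariances, H-bond detection, satisfaction analysis."""

import numpy as np
import pytest

from cyclodesign.model import (MacrocycleSequence, ResidueSpec, Conformation,
                               build_from_torsions, mirror, cyclic_permute,
                               thread_sequence)
from cyclodesign.energetics import (score, detect_backbone_hbonds,
                                    count_internal_hbonds,
                                    find_unsatisfied_nh,
                                    check_oversaturated_acceptors,
                                    _hbond_energy, WEIGHT_SETS)
from cyclodesign.ramachandran import rama_prepro_check, rama_energy

from conftest import random_torsions


class TestInvariances:
    @pytest.mark.parametrize("n", [6, 8, 11])
    def test_mirror_and_permutation_term_by_term(self, n, mixed_seq8):
        rng = np.random.default_rng(n)
        seq = mixed_seq8 if n == 8 else MacrocycleSequence.polyglycine(n)
        for _ in range(5):
            conf = build_from_torsions(
                seq, random_torsions(rng, n, (0.0, 180.0)))
            b = score(conf, "standard")
            bm = score(mirror(conf), "standard")
            bp = score(cyclic_permute(conf, int(rng.integers(1, n))),
                       "standard")
            for k, v in b.terms.items():
                assert bm.terms[k] == pytest.approx(v, rel=1e-9, abs=1e-9)
                assert bp.terms[k] == pytest.approx(v, rel=1e-9, abs=1e-9)

    def test_total_is_weighted_sum(self, ring8):
        b = score(ring8, "closure_selection")
        w = WEIGHT_SETS["closure_selection"]
        assert b.total == pytest.approx(
            sum(w[k] * v for k, v in b.terms.items()), abs=1e-12)

    def test_hbond_terms_equal_sum_of_detected_bonds(self, helix8):
        b = score(helix8, "standard")
        total = sum(hb.energy for hb in detect_backbone_hbonds(helix8))
        assert b.terms["hbond_sr_bb"] + b.terms["hbond_lr_bb"] == \
            pytest.approx(total, abs=1e-9)


class TestHbondDetection:
    def test_helix_donors_found(self, helix8):
        hbs = detect_backbone_hbonds(helix8)
        pairs = {(h.donor, h.acceptor) for h in hbs}
        assert pairs == {(4, 0), (5, 1), (6, 2), (7, 3)}
        for h in hbs:
            assert h.energy <= -0.25

    def test_near_ideal_geometry_reaches_minus_one(self):
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([1.01, 0.0, 0.0])
        o = np.array([2.91, 0.0, 0.0])
        # carbonyl C at 120 deg from the H...O axis
        c = o + 1.231 * np.array([np.cos(np.deg2rad(60.0)),
                                  np.sin(np.deg2rad(60.0)), 0.0])
        e = _hbond_energy(h, n, o, c)
        assert e == pytest.approx(-1.0, abs=0.05)

    def test_distant_pair_not_reported(self):
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([1.01, 0.0, 0.0])
        o = np.array([1.01 + 4.5, 0.0, 0.0])
        c = o + np.array([0.6, 1.07, 0.0])
        assert _hbond_energy(h, n, o, c) > -0.25

    def test_weakening_distance_never_strengthens(self):
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([1.01, 0.0, 0.0])
        c_off = np.array([np.cos(np.deg2rad(60.0)),
                          np.sin(np.deg2rad(60.0)), 0.0])
        last = -np.inf
        for d in np.linspace(1.9, 3.6, 40):
            o = np.array([1.01 + d, 0.0, 0.0])
            e = _hbond_energy(h, n, o, o + 1.231 * c_off)
            assert e >= last - 1e-12
            last = e

    def test_sequence_neighbors_excluded(self, helix8):
        # append an artificial perfect partner at separation 2: must be
        # ignored by the cyclic-separation rule
        hbs = detect_backbone_hbonds(helix8, energy_cutoff=0.0)
        assert all(min((h.donor - h.acceptor) % 8,
                       (h.acceptor - h.donor) % 8) >= 3 for h in hbs)

    def test_count_deduplicates(self, helix8):
        assert count_internal_hbonds(helix8) == \
            len(detect_backbone_hbonds(helix8))


class TestSatisfaction:
    def test_prolines_and_nmethyls_never_unsatisfied(self, ring8):
        seq = MacrocycleSequence(
            [ResidueSpec("PRO", "L"), ResidueSpec("VAL", "L", True)] +
            [ResidueSpec("GLY", "achiral") for _ in range(6)])
        conf = thread_sequence(ring8, seq)
        unsat = find_unsatisfied_nh(conf)
        assert 0 not in unsat and 1 not in unsat

    def test_fully_bonded_donors_give_empty_set(self, helix8):
        # residues 0-3 cannot donate (N-methylated); 4-7 all donate
        seq = MacrocycleSequence(
            [ResidueSpec("GLY", "achiral", n_methyl=(i < 4))
             for i in range(8)])
        conf = thread_sequence(helix8, seq)
        assert find_unsatisfied_nh(conf) == set()

    def test_unsatisfied_reported_for_helix_start(self, helix8):
        assert find_unsatisfied_nh(helix8) == {0, 1, 2, 3}


def _synthetic_acceptor_fixture(n_donors):
    """Hand-built conformation with n_donors ideal N-H...O bonds aimed at
    the carbonyl of residue 0 (synthetic geometry, not a real peptide)."""
    n_res = 8
    seq = MacrocycleSequence.polyglycine(n_res)
    coords = {k: np.full((n_res, 3), np.nan) for k in
              ("N", "CA", "C", "O", "H", "CN")}
    # spread all atoms far apart by default
    for i in range(n_res):
        base = np.array([60.0 * i, 200.0, 0.0])
        coords["N"][i] = base
        coords["CA"][i] = base + (1.458, 0.0, 0.0)
        coords["C"][i] = base + (2.0, 1.4, 0.0)
        coords["O"][i] = base + (2.1, 2.6, 0.0)
        coords["H"][i] = base + (-0.7, -0.7, 0.0)
    # acceptor carbonyl of residue 0 at the origin
    coords["O"][0] = np.array([0.0, 0.0, 0.0])
    coords["C"][0] = np.array([-1.231, 0.0, 0.0])
    for k in range(n_donors):
        i = 3 + k  # donors at cyclic separation >= 3 from residue 0
        # keep donors within the acceptor's favourable H...O=C cone
        ang = np.deg2rad(-80.0 + 90.0 * k)
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        coords["H"][i] = 1.9 * u
        coords["N"][i] = (1.9 + 1.01) * u
    conf = Conformation(seq, np.zeros((n_res, 3)), coords)
    return conf


class TestOversaturation:
    def test_no_bonds_passes(self, ring8):
        ok, offenders = check_oversaturated_acceptors(ring8)
        assert ok and offenders == []

    def test_three_donors_on_one_carbonyl_fails(self):
        conf = _synthetic_acceptor_fixture(3)
        ok, offenders = check_oversaturated_acceptors(conf)
        assert not ok
        assert offenders == [0]

    def test_two_donors_allowed(self):
        conf = _synthetic_acceptor_fixture(2)
        ok, offenders = check_oversaturated_acceptors(conf)
        assert ok and offenders == []


class TestRamaSurrogate:
    def test_helical_point_favorable_for_l_not_d(self):
        assert rama_prepro_check("ALA", "L", -60.0, -45.0, cutoff=2.0)
        assert not rama_prepro_check("ALA", "D", -60.0, -45.0, cutoff=2.0)
        assert rama_prepro_check("ALA", "D", 60.0, 45.0, cutoff=2.0)

    def test_infinite_cutoff_always_passes(self):
        assert rama_prepro_check("PRO", "L", 170.0, -170.0,
                                 cutoff=np.inf)

    def test_d_surface_is_mirror_of_l(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            phi, psi = rng.uniform(-180, 180, 2)
            assert rama_energy("LEU", "D", phi, psi) == pytest.approx(
                rama_energy("LEU", "L", -phi, -psi), abs=1e-12)

    def test_prepro_variant_differs(self):
        a = rama_energy("ALA", "L", -63.0, -43.0, prepro=False)
        b = rama_energy("ALA", "L", -63.0, -43.0, prepro=True)
        assert a != b
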