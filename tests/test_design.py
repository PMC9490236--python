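"""Sequence design: alphabets, composition penalties, remediation, protocol."""

import itertools

import numpy as np
import pytest

from cyclodesign.model import (MacrocycleSequence, ResidueSpec,
                               build_from_torsions, mirror, thread_sequence)
from cyclodesign.energetics import score
from cyclodesign.design import (DesignPolicy, CompositionConstraint,
                                PHE_CONSTRAINT, chirality_allowed_alphabet,
                                composition_penalty, design_sequence,
                                remedy_unsatisfied, run_design_protocol,
                                apply_design_filters, DesignRecord)
from cyclodesign.closure import sample_cyclic_backbones


def _seq_with_phe(n_phe, n=8):
    res = [ResidueSpec("PHE", "L") for _ in range(n_phe)]
    res += [ResidueSpec("ALA", "L") for _ in range(n - n_phe)]
    return MacrocycleSequence(res)


class TestCompositionPenalty:
    @pytest.mark.parametrize("n_phe,expected", [(0, 0.0), (1, 0.0),
                                                (2, 0.0), (3, 5.0),
                                                (4, 25.0)])
    def test_tabulated_deltas(self, n_phe, expected):
        assert composition_penalty(_seq_with_phe(n_phe),
                                   [PHE_CONSTRAINT]) == expected

    def test_d_phe_counts_toward_the_class(self):
        res = [ResidueSpec("PHE", "L"), ResidueSpec("PHE", "D"),
               ResidueSpec("PHE", "D")] + \
            [ResidueSpec("VAL", "L") for _ in range(5)]
        assert composition_penalty(MacrocycleSequence(res),
                                   [PHE_CONSTRAINT]) == 5.0

    def test_quadratic_growth_above_range(self):
        c = PHE_CONSTRAINT
        assert c.penalty(5) > c.penalty(4) > c.penalty(3)

    def test_constant_below_range(self):
        assert PHE_CONSTRAINT.penalty(0) == 0.0

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            CompositionConstraint(("ALA",), 2, -2, 2, (0, 0, 0, 5))


class TestChiralityAlphabet:
    def test_phi_sign_selects_hand(self, ring8):
        policy = DesignPolicy()
        alpha = chirality_allowed_alphabet(ring8, policy)
        for i, choices in enumerate(alpha):
            hand = {c[0] for c in choices}
            if ring8.torsions[i, 0] > 0:
                assert hand == {"D"}
            else:
                assert hand == {"L"}

    def test_mirroring_swaps_alphabets(self, ring8):
        policy = DesignPolicy()
        a = chirality_allowed_alphabet(ring8, policy)
        b = chirality_allowed_alphabet(mirror(ring8), policy)
        for x, y in zip(a, b):
            assert {c[0] for c in x} != {c[0] for c in y} or \
                all(abs(t) < 1e-12 for t in ring8.torsions[:, 0])


class TestDesignSequence:
    def test_fixed_seed_reproducible(self, ring8):
        policy = DesignPolicy()
        a = design_sequence(ring8, policy, "standard", rng_seed=5)
        b = design_sequence(ring8, policy, "standard", rng_seed=5)
        assert a == b

    def test_respects_chirality_alphabet(self, ring8):
        policy = DesignPolicy()
        seq = design_sequence(ring8, policy, "standard", rng_seed=5)
        for i, r in enumerate(seq):
            if ring8.torsions[i, 0] > 0:
                assert r.chirality == "D"
            else:
                assert r.chirality == "L"

    def test_matches_exhaustive_optimum_on_small_alphabet(self, ring6):
        policy = DesignPolicy(l_alphabet=("ALA", "LEU"),
                              d_alphabet=("ALA", "LEU"))
        best = design_sequence(ring6, policy, "standard", rng_seed=3,
                               passes=40)
        e_best = score(thread_sequence(ring6, best), "standard").total

        hands = ["D" if ring6.torsions[i, 0] > 0 else "L" for i in range(6)]
        e_opt = np.inf
        for combo in itertools.product(("ALA", "LEU"), repeat=6):
            seq = MacrocycleSequence(
                [ResidueSpec(aa, hands[i]) for i, aa in enumerate(combo)])
            e = score(thread_sequence(ring6, seq), "standard").total
            e_opt = min(e_opt, e)
        assert e_best == pytest.approx(e_opt, abs=1e-9)


class TestRemedy:
    def test_satisfied_sequence_unchanged(self, helix8):
        seq = MacrocycleSequence(
            [ResidueSpec("GLY", "achiral", n_methyl=(i < 4))
             for i in range(8)])
        conf = thread_sequence(helix8, seq)
        assert remedy_unsatisfied(conf) == seq

    def test_proline_bin_positions_become_proline(self, helix8):
        # unsatisfied helix-start donors sit at (-57, -47): inside the
        # L-proline-compatible bin
        out = remedy_unsatisfied(helix8)
        for i in (0, 1, 2, 3):
            assert out[i].aa == "PRO" and out[i].chirality == "L"

    def test_strand_positions_become_n_methylated(self):
        seq = MacrocycleSequence.polyglycine(8)
        t = np.zeros((8, 3))
        t[:, 0], t[:, 1], t[:, 2] = -120.0, 130.0, 180.0
        conf = build_from_torsions(seq, t)
        out = remedy_unsatisfied(conf)
        from cyclodesign.energetics import find_unsatisfied_nh
        for i in find_unsatisfied_nh(conf):
            assert out[i].n_methyl

    def test_already_methylated_unsat_is_contract_violation(self, helix8):
        from cyclodesign import design as dz
        seq = MacrocycleSequence(
            [ResidueSpec("GLY", "achiral", n_methyl=(i < 4))
             for i in range(8)])
        conf = thread_sequence(helix8, seq)
        # forge an impossible unsat report
        orig = dz.find_unsatisfied_nh
        try:
            dz.find_unsatisfied_nh = lambda c: {0}
            with pytest.raises(ValueError, match="contract"):
                remedy_unsatisfied(conf)
        finally:
            dz.find_unsatisfied_nh = orig


@pytest.fixture(scope="module")
def backbones():
    seq = MacrocycleSequence.polyglycine(7)
    confs = sample_cyclic_backbones(seq, 400, 31)
    assert confs
    return confs[:2]


class TestProtocol:
    def test_end_to_end_reproducible(self, backbones):
        a = run_design_protocol(backbones[0], rng_seed=9)
        b = run_design_protocol(backbones[0], rng_seed=9)
        assert a.sequence == b.sequence
        assert a.energy.total == pytest.approx(b.energy.total, abs=1e-12)

    def test_verdicts_reverify_from_coordinates(self, backbones):
        policy = DesignPolicy()
        for k, bb in enumerate(backbones):
            rec = run_design_protocol(bb, policy, rng_seed=k)
            again = DesignRecord(rec.sequence, rec.conformation, rec.energy,
                                 rec.hbond_count, rec.n_methyl_count,
                                 rec.unsatisfied)
            assert apply_design_filters(again, policy) == rec.verdicts
            if rec.passed:
                assert not rec.unsatisfied
                assert rec.n_methyl_count <= policy.max_n_methyl

    def test_nmethyl_count_within_limit_or_flagged(self, backbones):
        rec = run_design_protocol(backbones[0], rng_seed=2)
        if rec.n_methyl_count > 5:
            assert not rec.verdicts["max_n_methyl"]
        else:
            assert rec.verdicts["max_n_methyl"]
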