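"""Deterministic fixture generation: closed rings for testing and demos.

Every fixture is produced by the package's own sampling machinery from a
fixed seed, so tests and examples need no external structure files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Conformation, MacrocycleSequence, ResidueSpec
from .closure import (ClosureProblem, solve_closure, default_pivots,
                      loop_bump_check)
from .ramachandran import FLAT_SYMM_L_REGIONS

__all__ = ["make_fixture_ring", "RunConfig"]


@dataclass
class RunConfig:
    """Run-level configuration: seed, weight set and output handling."""

    seed: int = 0
    weights: str = "standard"
    out_dir: str = "."
    verbosity: int = 1


def _draw_region(rng, rects):
    areas = np.array([(r[1] - r[0]) * (r[3] - r[2]) for r in rects])
    k = rng.choice(len(rects), p=areas / areas.sum())
    lo, hi, plo, phi = rects[k]
    return rng.uniform(lo, hi), rng.uniform(plo, phi)


def _motif_rects(motif: str):
    helix = [FLAT_SYMM_L_REGIONS[0]]
    helix_d = [(-hi, -lo, -phi, -plo) for lo, hi, plo, phi in helix]
    strand = [FLAT_SYMM_L_REGIONS[1]]
    strand_d = [(-hi, -lo, -phi, -plo) for lo, hi, plo, phi in strand]
    if motif == "all_trans_helix":
        return helix + helix_d
    if motif == "beta_hairpin_like":
        return strand + strand_d + helix + helix_d
    raise ValueError(f"unknown motif {motif!r}")


def _closed_ring(seq, rng, rects, omega=None, max_tries=400,
                 require_bump=True):
    n = len(seq)
    for _ in range(max_tries):
        t = np.zeros((n, 3))
        t[:, 2] = 180.0 if omega is None else omega
        for i in range(n):
            t[i, 0], t[i, 1] = _draw_region(rng, rects)
        anchor = int(rng.integers(n))
        problem = ClosureProblem(seq, default_pivots(n, anchor), t,
                                 anchor=anchor)
        for sol in solve_closure(problem):
            conf = sol.conformation
            if not require_bump or loop_bump_check(conf):
                return conf
    raise RuntimeError("could not close a fixture ring within the retry "
                       "budget")


def make_fixture_ring(length: int, motif: str = "all_trans_helix",
                      seed: int = 0):
    """Deterministic closed ring(s) for a given motif.

    ``all_trans_helix`` and ``beta_hairpin_like`` return a single closed
    polyglycine Conformation sampled from the corresponding torsion
    regions. ``two_state_pair`` returns two conformations of one sequence
    bearing a single N-methylated position, differing by the cis/trans
    state of the peptide bond preceding it.
    """
    if not 6 <= length <= 12:
        raise ValueError("fixture length must be in [6, 12]")
    rng = np.random.default_rng(seed)
    if motif in ("all_trans_helix", "beta_hairpin_like"):
        seq = MacrocycleSequence.polyglycine(length)
        return _closed_ring(seq, rng, _motif_rects(motif))
    if motif == "two_state_pair":
        nme_pos = 2  # 0-based position of the single N-methyl
        residues = []
        for i in range(length):
            residues.append(ResidueSpec("GLY", "achiral",
                                        n_methyl=(i == nme_pos), index=i + 1))
        seq = MacrocycleSequence(residues)
        rects = _motif_rects("beta_hairpin_like")
        trans = _closed_ring(seq, rng, rects)
        # flip the bond preceding the N-methylated residue to cis and
        # re-close with the same non-pivot torsions
        flip_bond = (nme_pos - 1) % length
        t = trans.torsions.copy()
        t[flip_bond, 2] = 0.0
        anchor = (nme_pos + length // 2) % length
        problem = ClosureProblem(seq, default_pivots(length, anchor), t,
                                 anchor=anchor)
        sols = [s for s in solve_closure(problem)
                if loop_bump_check(s.conformation)]
        if not sols:
            # fall back: search fresh cis rings
            cis_conf = None
            for _ in range(200):
                t2 = trans.torsions.copy()
                t2[flip_bond, 2] = 0.0
                for i in (anchor,):
                    t2[i, 0], t2[i, 1] = _draw_region(rng, rects)
                for s in solve_closure(ClosureProblem(
                        seq, default_pivots(length, anchor), t2,
                        anchor=anchor)):
                    if loop_bump_check(s.conformation):
                        cis_conf = s.conformation
                        break
                if cis_conf is not None:
                    break
            if cis_conf is None:
                raise RuntimeError("could not close the cis state")
            return trans, cis_conf
        return trans, sols[0].conformation
    raise ValueError(f"unknown motif {motif!r}")
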