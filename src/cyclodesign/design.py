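"""Iterative sequence design with N-methylation of unsatisfied NH donors.

The protocol mirrors the design loop used for membrane-permeable
macrocycles: starting from a closed polyglycine backbone, hydrophobic
identities are designed onto the backbone (D-amino acids only at positive
phi, L only at negative phi), residues whose backbone NH donates no
internal hydrogen bond are remedied — to proline when their phi/psi lie in
the proline-compatible bin, otherwise to their N-methylated variant — and
the design is repeated for three rounds: the first with 5x-upweighted
backbone H-bond terms, the later rounds with the standard weight set, the
last followed by a continuous torsion-space minimization. Designs must end
with zero unsatisfied NH groups, at most five N-methyls, the
length-dependent internal H-bond minimum and no oversaturated acceptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (Conformation, MacrocycleSequence, ResidueSpec,
                    thread_sequence)
from .energetics import (WEIGHT_SETS, WeightSet, score, count_internal_hbonds,
                         find_unsatisfied_nh, check_oversaturated_acceptors)
from .closure import min_hbonds_for_length
from .ramachandran import in_proline_bin

__all__ = [
    "DesignPolicy", "CompositionConstraint", "DesignRecord",
    "chirality_allowed_alphabet", "design_sequence", "remedy_unsatisfied",
    "composition_penalty", "run_design_protocol", "apply_design_filters",
    "PHE_CONSTRAINT",
]


@dataclass(frozen=True)
class DesignPolicy:
    l_alphabet: tuple = ("ALA", "VAL", "LEU", "PHE", "ILE", "PRO")
    d_alphabet: tuple = ("ALA", "PHE", "ILE", "LEU", "PRO", "VAL")
    allow_achiral: bool = False
    min_hbonds: int | None = None          # None -> length schedule
    max_n_methyl: int = 5
    rounds: int = 3

    def required_hbonds(self, n: int) -> int:
        if self.min_hbonds is not None:
            return self.min_hbonds
        return min_hbonds_for_length(n)


@dataclass(frozen=True)
class CompositionConstraint:
    """A tabulated composition penalty for one residue class.

    ``members`` are display codes counted toward the class (for example
    ``("PHE", "D-PHE")``); ``delta`` is the count minus the absolute
    target, looked up in ``penalties`` over ``[delta_start, delta_end]``
    with constant extrapolation below the range and quadratic growth
    above it.
    """

    members: tuple
    absolute: int
    delta_start: int
    delta_end: int
    penalties: tuple
    before_function: str = "CONSTANT"
    after_function: str = "QUADRATIC"

    def __post_init__(self):
        if len(self.penalties) != self.delta_end - self.delta_start + 1:
            raise ValueError("penalty table does not span the delta range")
        if any(p < 0 for p in self.penalties):
            raise ValueError("penalties must be non-negative")

    def penalty(self, count: int) -> float:
        delta = count - self.absolute
        if delta < self.delta_start:
            return float(self.penalties[0])
        if delta <= self.delta_end:
            return float(self.penalties[delta - self.delta_start])
        # quadratic continuation beyond the tabulated range
        p_end = float(self.penalties[-1])
        over = delta - self.delta_end
        return p_end * (over + 1) ** 2


# The PHE/D-PHE composition constraint with the tabulated deltas used for
# global design runs: absolute target 2, deltas -2..+2, penalties
# 0 0 0 5 25, constant below range and quadratic above.
PHE_CONSTRAINT = CompositionConstraint(
    members=("PHE", "D-PHE"), absolute=2, delta_start=-2, delta_end=2,
    penalties=(0, 0, 0, 5, 25))


def composition_penalty(seq: MacrocycleSequence, constraints) -> float:
    """Summed composition penalty of a sequence under the constraints."""
    total = 0.0
    for c in constraints:
        count = sum(1 for r in seq if r.code in c.members)
        total += c.penalty(count)
    return total


@dataclass
class DesignRecord:
    sequence: MacrocycleSequence
    conformation: Conformation
    energy: object                       # EnergyBreakdown
    hbond_count: int
    n_methyl_count: int
    unsatisfied: set
    verdicts: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return bool(self.verdicts) and all(self.verdicts.values())


def chirality_allowed_alphabet(conf: Conformation,
                               policy: DesignPolicy) -> list:
    """Allowed identities per position, from the sign of phi.

    Positive phi admits only D-amino acids, negative phi only L; phi
    exactly zero counts as negative (deterministic tie-break). Achiral
    identities are appended on both sides when the policy enables them.
    """
    out = []
    for i in range(len(conf)):
        phi = conf.torsions[i, 0]
        if phi > 0:
            ids = [("D", aa) for aa in policy.d_alphabet]
        else:
            ids = [("L", aa) for aa in policy.l_alphabet]
        if policy.allow_achiral:
            ids += [("achiral", aa) for aa in ("GLY", "AIB")]
        out.append(ids)
    return out


def _allowed_specs(conf, policy):
    """Per-position candidate ResidueSpec lists honoring N-methyl flags."""
    alpha = chirality_allowed_alphabet(conf, policy)
    out = []
    for i, choices in enumerate(alpha):
        cur = conf.sequence[i]
        specs = []
        for chir, aa in choices:
            if cur.n_methyl and aa == "PRO":
                continue  # proline nitrogen cannot carry the methyl
            nm = cur.n_methyl and aa != "PRO"
            specs.append(ResidueSpec(aa, "achiral" if aa in ("GLY", "AIB")
                                     else chir, nm, i + 1))
        if not specs:
            raise ValueError(f"empty design alphabet at position {i + 1}")
        out.append(specs)
    return out


def design_sequence(conf: Conformation, policy: DesignPolicy,
                    weights: WeightSet | str = "standard",
                    rng_seed: int = 0, constraints=(),
                    passes: int = 12, t_start: float = 4.0,
                    t_end: float = 0.05,
                    unsat_penalty: float = 0.0) -> MacrocycleSequence:
    """Simulated-annealing combinatorial sequence optimization.

    Minimizes the weighted surrogate total plus composition penalties over
    per-position identity choices from the chirality-restricted alphabet;
    ``unsat_penalty`` adds a per-residue cost for every backbone NH left
    without an internal H-bond, discouraging later design rounds from
    re-exposing donors that earlier remediation buried. Deterministic
    under a fixed seed.
    """
    if isinstance(weights, str):
        weights = WEIGHT_SETS[weights]
    rng = np.random.default_rng(rng_seed)
    n = len(conf)
    cands = _allowed_specs(conf, policy)

    def _energy(specs):
        seq = MacrocycleSequence(specs)
        c = thread_sequence(conf, seq)
        e = score(c, weights, constraints).total
        if unsat_penalty:
            e += unsat_penalty * len(find_unsatisfied_nh(c))
        return e, seq

    cur = [c[int(rng.integers(len(c)))] for c in cands]
    cur_e, cur_seq = _energy(cur)
    best_e, best_seq = cur_e, cur_seq
    steps = max(1, passes * n)
    temps = t_start * (t_end / t_start) ** (np.arange(steps) / max(1, steps - 1))
    for temp in temps:
        i = int(rng.integers(n))
        if len(cands[i]) == 1:
            continue
        prop = list(cur)
        choice = cands[i][int(rng.integers(len(cands[i])))]
        if choice == cur[i]:
            continue
        prop[i] = choice
        e, seq = _energy(prop)
        if e <= cur_e or rng.random() < np.exp(-(e - cur_e) / temp):
            cur, cur_e, cur_seq = prop, e, seq
            if e < best_e:
                best_e, best_seq = e, seq
    return best_seq


def remedy_unsatisfied(conf: Conformation,
                       seq: MacrocycleSequence | None = None,
                       ) -> MacrocycleSequence:
    """Remove exposed NH donors by proline substitution or N-methylation.

    Each residue whose backbone NH donates no internal H-bond becomes
    (D-)proline when its phi/psi lie in the proline-compatible bin (the
    hand chosen by the sign of phi), otherwise its N-methylated variant.
    Satisfied positions are untouched.
    """
    if seq is not None:
        conf = thread_sequence(conf, seq)
    unsat = find_unsatisfied_nh(conf)
    out = list(conf.sequence.residues)
    for i in sorted(unsat):
        r = out[i]
        if r.n_methyl:
            raise ValueError(
                f"position {i + 1} is N-methylated yet reported as an "
                "unsatisfied donor (contract violation)")
        phi, psi = conf.torsions[i, 0], conf.torsions[i, 1]
        hand = "D" if phi > 0 else "L"
        if in_proline_bin(phi, psi, hand):
            out[i] = ResidueSpec("PRO", hand, False, i + 1)
        else:
            out[i] = replace(r, n_methyl=True)
    return MacrocycleSequence(out)


def apply_design_filters(record: DesignRecord,
                         policy: DesignPolicy) -> dict:
    """Pass/fail verdicts recomputed from the stored conformation."""
    conf = record.conformation
    n = len(conf)
    hb = count_internal_hbonds(conf)
    unsat = find_unsatisfied_nh(conf)
    nme = sum(1 for r in conf.sequence if r.n_methyl)
    oversat_ok, _ = check_oversaturated_acceptors(conf)
    return {
        "min_hbonds": hb >= policy.required_hbonds(n),
        "max_n_methyl": nme <= policy.max_n_methyl,
        "no_unsatisfied_nh": len(unsat) == 0,
        "oversaturation": oversat_ok,
    }


def run_design_protocol(backbone: Conformation,
                        policy: DesignPolicy | None = None,
                        rng_seed: int = 0, constraints=(),
                        minimize_final: bool = True,
                        minimize_iter: int = 25,
                        design_passes: int = 10) -> DesignRecord:
    """Three design rounds with NH remediation in between.

    Round 1 uses the H-bond-upweighted weight set to favour internal
    backbone-backbone hydrogen bonds; rounds 2 and 3 use the standard set;
    the final round is followed by a torsion-space minimization with the
    chainbreak penalty active.
    """
    policy = policy or DesignPolicy()
    rng = np.random.default_rng(rng_seed)
    conf = backbone
    round_weights = ["hbond_upweighted"] + \
        ["standard"] * (policy.rounds - 1)
    seq = conf.sequence
    for rnd, wname in enumerate(round_weights):
        seed = int(rng.integers(2 ** 31))
        seq = design_sequence(conf, policy, wname, seed, constraints,
                              passes=design_passes,
                              unsat_penalty=0.0 if rnd == 0 else 2.0)
        conf = thread_sequence(conf, seq)
        if rnd < len(round_weights) - 1:
            seq = remedy_unsatisfied(conf)
            conf = thread_sequence(conf, seq)
    if minimize_final:
        from .landscape import minimize
        conf = minimize(conf, "standard", max_iter=minimize_iter)
    seq = conf.sequence
    record = DesignRecord(
        sequence=seq, conformation=conf,
        energy=score(conf, "standard", constraints),
        hbond_count=count_internal_hbonds(conf),
        n_methyl_count=sum(1 for r in seq if r.n_methyl),
        unsatisfied=find_unsatisfied_nh(conf))
    record.verdicts = apply_design_filters(record, policy)
    return record
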