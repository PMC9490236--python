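"""Multistate design of chameleonic macrocycles by genetic algorithm.

A chameleonic (conformation-switching) macrocycle has two near-isoenergetic
low-energy states, typically separated by a cis/trans peptide-bond flip at
a proline or N-methylated position. Given two backbone states A and B, the
GA searches sequence space for variants that score well — and nearly
equally — on both: each variant is threaded onto both backbones, filtered
(both energies below a ceiling, inter-state gap below a gap ceiling) and
ranked by the fitness

    f = -5 * |eA - eB| - (eA - eB)

which is bounded above by 0, attained exactly when eA = eB (f = -4*gap
when eA < eB and -6*gap when eA > eB), so maximizing f selects
isoenergetic pairs with a mild preference for stabilizing state A less.
Survivors each contribute one point mutant per generation; mutations
respect the original chirality and N-methylation pattern.

``switch_scan`` converts a single-state design into switch candidates by
scanning every position x allowed identity, relaxing each mutant and
looking for a second low-energy minimum within the isoenergetic
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Conformation, MacrocycleSequence, ResidueSpec, \
    thread_sequence
from .energetics import score
from .landscape import (minimize, predict_landscape,
                        detect_isoenergetic_states)

__all__ = [
    "GAParams", "GAVariant", "thread_and_score", "ga_fitness", "ga_filter",
    "run_multistate_ga", "switch_scan", "PAPER_SCALE_GA",
]

_L_SET = ("ALA", "VAL", "LEU", "ILE", "PHE")
_ACHIRAL_SET = ("GLY", "AIB")


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm parameters.

    Desk-scale defaults; :data:`PAPER_SCALE_GA` carries the full-scale
    values (population 1000, survivors 500, 1000 generations).
    """

    population: int = 60
    survivors: int = 30
    generations: int = 50
    energy_ceiling: float = 10.0     # per-backbone total, score units
    gap_ceiling: float = 6.0         # |eA - eB| ceiling, score units
    init_mutations: tuple = (1, 3)   # point mutations per initial variant
    rng_seed: int = 0

    def __post_init__(self):
        if self.survivors > self.population:
            raise ValueError("survivors must not exceed population")
        if self.energy_ceiling <= 0 or self.gap_ceiling <= 0:
            raise ValueError("ceilings must be positive")


PAPER_SCALE_GA = GAParams(population=1000, survivors=500, generations=1000)


@dataclass
class GAVariant:
    sequence: MacrocycleSequence
    eA: float
    eB: float

    @property
    def fitness(self) -> float:
        return ga_fitness(self.eA, self.eB)


def thread_and_score(seq: MacrocycleSequence, backbone: Conformation,
                     weights: str = "standard",
                     relax_iter: int = 10) -> float:
    """Thread identities onto the fixed backbone, briefly relax, score."""
    conf = thread_sequence(backbone, seq)
    if relax_iter > 0:
        conf = minimize(conf, weights, max_iter=relax_iter)
    return score(conf, weights).total


def ga_fitness(eA: float, eB: float) -> float:
    """Multistate fitness: -5*|eA - eB| - (eA - eB); larger is better."""
    return -5.0 * abs(eA - eB) - (eA - eB)


def ga_filter(eA: float, eB: float, params: GAParams) -> bool:
    """Both state energies under the ceiling, gap under the gap ceiling."""
    return (eA < params.energy_ceiling and eB < params.energy_ceiling
            and abs(eA - eB) < params.gap_ceiling)


def _mutation_choices(spec: ResidueSpec, alphabet=None):
    """Identities a position may mutate to, preserving chirality and
    N-methylation."""
    if alphabet is not None:
        pool = alphabet
    elif spec.chirality == "achiral":
        pool = _ACHIRAL_SET
    else:
        pool = _L_SET
    out = []
    for aa in pool:
        if aa == spec.aa:
            continue
        chir = "achiral" if aa in ("GLY", "AIB") else (
            spec.chirality if spec.chirality in ("L", "D") else "L")
        out.append(ResidueSpec(aa, chir, spec.n_methyl and aa != "PRO",
                               spec.index))
    return out


def _point_mutant(seq: MacrocycleSequence, rng, alphabet=None, avoid=None):
    """One random point mutation; prefers sequences not in *avoid*.

    When a survivor's whole single-mutation neighborhood has already been
    evaluated the walk is allowed to step once more (still point mutations,
    applied successively) so that desk-scale runs stay ergodic instead of
    endlessly re-proposing known sequences.
    """
    n = len(seq)

    def _one(s):
        order = rng.permutation(n)
        for i in order:
            choices = _mutation_choices(s[int(i)], alphabet)
            if not choices:
                continue
            res = list(s.residues)
            res[int(i)] = choices[int(rng.integers(len(choices)))]
            yield MacrocycleSequence(res)

    frontier = seq
    for _depth in range(3):
        fallback = None
        for cand in _one(frontier):
            if fallback is None:
                fallback = cand
            if avoid is None or _seq_key(cand) not in avoid:
                return cand
        if fallback is None:
            return seq
        frontier = fallback  # neighborhood exhausted: walk one step on
    return frontier


def _seq_key(seq: MacrocycleSequence) -> tuple:
    return tuple((r.aa, r.chirality, r.n_methyl) for r in seq)


def run_multistate_ga(start_seq: MacrocycleSequence,
                      backbone_A: Conformation, backbone_B: Conformation,
                      params: GAParams | None = None,
                      energy_fn=None, alphabet=None):
    """Evolve sequences toward two isoenergetic states.

    ``energy_fn(seq, backbone) -> float`` defaults to
    :func:`thread_and_score`; a transparent toy model can be injected for
    testing. Returns ``(best GAVariant or None, per-generation log)``.
    Ranking maximizes fitness with ties broken by lower eA+eB then
    lexicographic sequence; the best survivor is elitist (never lost), so
    best fitness is non-decreasing across generations.
    """
    params = params or GAParams()
    for bb in (backbone_A, backbone_B):
        if isinstance(bb, Conformation) and len(bb) != len(start_seq):
            raise ValueError("backbone lengths must match the sequence")
    rng = np.random.default_rng(params.rng_seed)
    if energy_fn is None:
        energy_fn = thread_and_score

    cache: dict = {}

    def _eval(seq):
        key = _seq_key(seq)
        if key not in cache:
            cache[key] = (float(energy_fn(seq, backbone_A)),
                          float(energy_fn(seq, backbone_B)))
        return cache[key]

    population = [start_seq]
    for _ in range(params.population - 1):
        s = start_seq
        for _ in range(int(rng.integers(params.init_mutations[0],
                                        params.init_mutations[1] + 1))):
            s = _point_mutant(s, rng, alphabet)
        population.append(s)

    log = []
    survivors = []
    for gen in range(params.generations):
        scored = []
        seen = set()
        for seq in population:
            key = _seq_key(seq)
            if key in seen:
                continue
            seen.add(key)
            eA, eB = _eval(seq)
            if ga_filter(eA, eB, params):
                scored.append(GAVariant(seq, eA, eB))
        if not scored:
            # every variant filtered out: repopulate from survivor mutants
            base = survivors if survivors else [
                GAVariant(s, *_eval(s)) for s in population[:1]]
            population = [v.sequence for v in base] + [
                _point_mutant(v.sequence, rng, alphabet) for v in base]
            log.append({"generation": gen, "warning": "all filtered"})
            continue
        scored.sort(key=lambda v: (-v.fitness, v.eA + v.eB,
                                   _seq_key(v.sequence)))
        survivors = scored[:params.survivors]
        best = survivors[0]
        log.append({"generation": gen, "best_fitness": best.fitness,
                    "eA": best.eA, "eB": best.eB,
                    "sequence": repr(best.sequence)})
        population = [v.sequence for v in survivors] + \
            [_point_mutant(v.sequence, rng, alphabet, avoid=set(cache))
             for v in survivors]
    return (survivors[0] if survivors else None), log


def switch_scan(record, n_samples: int = 20, rng_seed: int = 0,
                threshold: float = 5.0, alphabet=None,
                minimize_iter: int = 30):
    """Scan point mutants of a design for two-minimum (switch) behaviour.

    For every position x allowed identity the mutant is threaded, relaxed
    and a reduced conformational landscape is predicted; mutants whose
    landscape shows a second cluster within the isoenergetic threshold are
    reported, annotated with whether the minima differ by a cis/trans flip
    at a proline/N-methyl position.
    """
    conf = record.conformation if hasattr(record, "conformation") else record
    seq = conf.sequence
    rng = np.random.default_rng(rng_seed)
    candidates = []
    scanned = 0
    for i in range(len(seq)):
        for spec in _mutation_choices(seq[i], alphabet):
            scanned += 1
            res = list(seq.residues)
            res[i] = spec
            mseq = MacrocycleSequence(res)
            mconf = minimize(thread_sequence(conf, mseq),
                             max_iter=minimize_iter)
            pts, summary = predict_landscape(
                mseq, mconf, n_samples, int(rng.integers(2 ** 31)),
                minimize_iter=minimize_iter)
            states = detect_isoenergetic_states(summary.clusters, threshold,
                                                mseq)
            if states:
                candidates.append({"position": i + 1, "mutation": spec.code,
                                   "sequence": mseq, "states": states,
                                   "summary": summary})
    return candidates, scanned
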