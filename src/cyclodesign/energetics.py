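"""Surrogate scoring function, backbone H-bond detection and NH-satisfaction.

The score mirrors the *roles* of the terms used for macrocycle design and
closure selection — fa_rep / fa_atr (split Lennard-Jones over backbone
heavy atoms plus one CB-centred side-chain sphere per residue),
hbond_sr_bb / hbond_lr_bb (geometric backbone-backbone hydrogen bonds),
rama_prepro and p_aa_pp (surrogate torsion tables, D mirrored from L),
omega (harmonic to the nearest planar amide), chainbreak (deviation of
peptide-bond geometry from ideal, summed over every bond so the value is
invariant under cyclic permutation) and aa_composition — but the numeric
constants are this package's own, documented here and in
:mod:`cyclodesign.ramachandran`. Energies are in arbitrary "score units"
treated as kcal/mol-equivalent where thresholds are quoted in kcal/mol.

Hydrogen-bond model: for donor N-H and acceptor O=C,

    E = -1.34 * exp(-(d_HO - 1.9)^2 / (2 * 0.45^2))
             * ((1 - cos t_NHO) / 2)^2 * ((1 - cos t_HOC) / 2)

which reaches about -1.0 at ideal linear geometry (d = 1.9 A,
t_NHO = 180 deg, t_HOC = 120 deg) so the -0.25 reporting cutoff retains
its meaning. Donor-acceptor pairs closer than 3 residues along the cycle
are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx

from .geometry import IDEAL, place_atom, wrap_angle
from .model import Conformation
from .ramachandran import p_aa_pp_energy, rama_energy

__all__ = [
    "WeightSet", "WEIGHT_SETS", "EnergyBreakdown", "HBond",
    "score", "detect_backbone_hbonds", "count_internal_hbonds",
    "find_unsatisfied_nh", "check_oversaturated_acceptors",
    "side_chain_sphere",
]

TERMS = ("fa_rep", "fa_atr", "hbond_sr_bb", "hbond_lr_bb", "rama_prepro",
         "p_aa_pp", "omega", "chainbreak", "aa_composition")

# --- Lennard-Jones surrogate constants -------------------------------------
LJ_EPS = 0.1
LJ_CUTOFF = 6.0
ATOM_RADII = {"N": 1.55, "CA": 1.7, "C": 1.7, "O": 1.52, "CN": 1.7}
# side-chain sphere radius by residue bulk; GLY has no sphere
CB_RADII = {"ALA": 1.9, "VAL": 2.3, "LEU": 2.45, "ILE": 2.45,
            "PHE": 2.6, "PRO": 2.1, "AIB": 2.0}

# --- H-bond constants ------------------------------------------------------
HB_SCALE = -1.34
HB_D0 = 1.9
HB_SIGMA = 0.45
HB_DMAX = 3.6
HB_MIN_SEP = 3          # minimum cyclic donor-acceptor separation
HB_SR_MAX_SEP = 4       # short-range vs long-range split
DEFAULT_HB_CUTOFF = -0.25

# --- omega / chainbreak constants ------------------------------------------
OMEGA_K = 0.005         # score units per squared degree
CB_K_LEN = 500.0        # per squared Angstrom of bond-length deviation
CB_K_ANG = 0.1          # per squared degree of bond-angle deviation
CB_K_TOR = 0.1          # per squared degree of realized-vs-set omega


@dataclass(frozen=True)
class WeightSet:
    name: str
    weights: dict

    def __getitem__(self, term):
        return self.weights.get(term, 0.0)

    def scaled(self, name, **overrides) -> "WeightSet":
        w = dict(self.weights)
        w.update(overrides)
        return WeightSet(name, w)


_STANDARD = {
    "fa_rep": 0.55, "fa_atr": 1.0, "hbond_sr_bb": 1.0, "hbond_lr_bb": 1.0,
    "rama_prepro": 0.45, "p_aa_pp": 0.4, "omega": 0.4, "chainbreak": 1.0,
    "aa_composition": 1.0,
}
WEIGHT_SETS = {
    "standard": WeightSet("standard", _STANDARD),
    # closure-selection function: only the terms used to rank KIC solutions
    "closure_selection": WeightSet("closure_selection", {
        "fa_rep": 0.1, "fa_atr": 0.2, "hbond_sr_bb": 2.0, "hbond_lr_bb": 2.0,
        "rama_prepro": 0.45, "omega": 0.4, "p_aa_pp": 0.6,
    }),
    # round-1 design function: backbone H-bond terms upweighted 5x
    "hbond_upweighted": WeightSet("hbond_upweighted", {
        **_STANDARD, "hbond_sr_bb": 5.0, "hbond_lr_bb": 5.0,
    }),
}


@dataclass
class EnergyBreakdown:
    terms: dict
    weights: WeightSet

    @property
    def total(self) -> float:
        return float(sum(self.weights[t] * v for t, v in self.terms.items()))

    def __getattr__(self, name):
        if name in TERMS:
            return self.terms[name]
        raise AttributeError(name)

    def as_dict(self) -> dict:
        d = dict(self.terms)
        d["total"] = self.total
        return d


@dataclass(frozen=True)
class HBond:
    donor: int      # residue index (0-based) providing the N-H
    acceptor: int   # residue index providing the C=O
    energy: float


def side_chain_sphere(conf: Conformation, i: int,
                      geom=IDEAL) -> np.ndarray | None:
    """Centre of the single side-chain sphere of residue i, or None (GLY).

    L and D residues branch to opposite sides of the backbone frame; the
    achiral AIB sphere sits on the mirror-symmetric bisector of the two, so
    the energy stays exactly mirror-invariant.
    """
    r = conf.sequence[i]
    if r.aa == "GLY":
        return None
    n, c, ca = conf.atom("N", i), conf.atom("C", i), conf.atom("CA", i)

    def _cb(sign):
        return place_atom(n, c, ca, geom.ca_cb, geom.n_ca_cb,
                          sign * geom.cb_branch)

    if r.chirality == "L":
        return _cb(+1.0)
    if r.chirality == "D":
        return _cb(-1.0)
    # achiral (AIB): bisector of the two enantiomeric placements
    v = (_cb(+1.0) - ca) + (_cb(-1.0) - ca)
    v /= np.linalg.norm(v)
    return ca + geom.ca_cb * v


def _atom_list(conf: Conformation):
    """Flat list of (residue, name, coord, radius) for LJ interactions."""
    atoms = []
    for i, r in enumerate(conf.sequence):
        for name in ("N", "CA", "C", "O"):
            atoms.append((i, name, conf.atom(name, i), ATOM_RADII[name]))
        if conf.has_atom("CN", i):
            atoms.append((i, "CN", conf.atom("CN", i), ATOM_RADII["CN"]))
        cb = side_chain_sphere(conf, i)
        if cb is not None:
            atoms.append((i, "CB", cb, CB_RADII[r.aa]))
    return atoms


def _bond_graph(conf: Conformation) -> nx.Graph:
    g = nx.Graph()
    n = len(conf)
    for i, r in enumerate(conf.sequence):
        g.add_edge((i, "N"), (i, "CA"))
        g.add_edge((i, "CA"), (i, "C"))
        g.add_edge((i, "C"), (i, "O"))
        g.add_edge((i, "C"), ((i + 1) % n, "N"))  # incl. the closure bond
        if r.has_nh:
            g.add_edge((i, "N"), (i, "H"))
        if r.n_methyl:
            g.add_edge((i, "N"), (i, "CN"))
        if r.aa != "GLY":
            g.add_edge((i, "CA"), (i, "CB"))
        if r.aa == "PRO":  # pyrrolidine ring closes N to the side chain
            g.add_edge((i, "N"), (i, "CB"))
    return g


_SEP_CACHE: dict = {}


def _bond_separation(conf: Conformation, keys, cutoff=4):
    """Matrix of bonded path lengths (capped at cutoff+1) between atoms."""
    pattern = (len(conf), tuple((r.aa, r.n_methyl, r.has_nh)
                                for r in conf.sequence), cutoff,
               tuple(keys))
    sep = _SEP_CACHE.get(pattern)
    if sep is not None:
        return sep
    g = _bond_graph(conf)
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=cutoff))
    m = len(keys)
    sep = np.full((m, m), cutoff + 1, dtype=int)
    for a in range(m):
        row = dist.get(keys[a], {})
        for b in range(m):
            d = row.get(keys[b])
            if d is not None:
                sep[a, b] = d
    if len(_SEP_CACHE) > 64:
        _SEP_CACHE.pop(next(iter(_SEP_CACHE)))
    _SEP_CACHE[pattern] = sep
    return sep


def _lj_terms(conf: Conformation):
    atoms = _atom_list(conf)
    keys = [(i, nm) for i, nm, _, _ in atoms]
    xyz = np.array([a[2] for a in atoms])
    rad = np.array([a[3] for a in atoms])
    sep = _bond_separation(conf, keys)
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    sigma = rad[:, None] + rad[None, :]
    iu = np.triu_indices(len(atoms), k=1)
    d, sigma, sep = d[iu], sigma[iu], sep[iu]
    # pairs separated by fewer than 4 bonds are excluded entirely
    mask = (sep >= 4) & (d < LJ_CUTOFF) & (d > 1e-6)
    d, sigma = d[mask], sigma[mask]
    x6 = (sigma / d) ** 6
    lj = LJ_EPS * (x6 * x6 - 2.0 * x6)
    inside = d < sigma
    rep = float(np.sum((lj[inside] + LJ_EPS)))
    atr = float(np.sum(lj[~inside]) - LJ_EPS * np.sum(inside))
    return rep, atr


def _hbond_energy(h, n, o, c) -> float:
    d = float(np.linalg.norm(o - h))
    if d > HB_DMAX or d < 1e-6:
        return 0.0
    def _cos(u, v):
        return float(np.dot(u, v) /
                     (np.linalg.norm(u) * np.linalg.norm(v)))

    cos_nho = _cos(n - h, o - h)   # angle N-H...O, measured at H
    cos_hoc = _cos(h - o, c - o)   # angle H...O=C, measured at O
    f_dist = np.exp(-((d - HB_D0) ** 2) / (2.0 * HB_SIGMA ** 2))
    f1 = ((1.0 - cos_nho) / 2.0) ** 2
    f2 = (1.0 - cos_hoc) / 2.0
    return float(HB_SCALE * f_dist * f1 * f2)


def detect_backbone_hbonds(conf: Conformation,
                           energy_cutoff: float = DEFAULT_HB_CUTOFF):
    """Backbone-backbone H-bonds with energy at or below the cutoff.

    Donors are residues with an amide H (not proline, not N-methylated);
    acceptors are carbonyl oxygens. Pairs within cyclic separation 2 are
    excluded.
    """
    n = len(conf)
    donors = [i for i, r in enumerate(conf.sequence)
              if r.has_nh and conf.has_atom("H", i)]
    if not donors:
        return []
    H = conf.coords["H"][donors]
    N = conf.coords["N"][donors]
    O = conf.coords["O"]
    C = conf.coords["C"]
    ho = O[None, :, :] - H[:, None, :]
    d = np.sqrt((ho ** 2).sum(-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        nh = N - H
        nh_n = nh / np.linalg.norm(nh, axis=1, keepdims=True)
        cos_nho = (ho * nh_n[:, None, :]).sum(-1) / np.maximum(d, 1e-12)
        co = C - O
        co_n = co / np.linalg.norm(co, axis=1, keepdims=True)
        cos_hoc = (-ho * co_n[None, :, :]).sum(-1) / np.maximum(d, 1e-12)
    f_dist = np.exp(-((d - HB_D0) ** 2) / (2.0 * HB_SIGMA ** 2))
    f1 = ((1.0 - cos_nho) / 2.0) ** 2
    f2 = (1.0 - cos_hoc) / 2.0
    e = HB_SCALE * f_dist * f1 * f2
    di = np.array(donors)[:, None]
    aj = np.arange(n)[None, :]
    sep = np.minimum((di - aj) % n, (aj - di) % n)
    mask = (sep >= HB_MIN_SEP) & (d <= HB_DMAX) & (e <= energy_cutoff)
    out = []
    for a, b in zip(*np.nonzero(mask)):
        out.append(HBond(donors[a], int(b), float(e[a, b])))
    return out


def count_internal_hbonds(conf: Conformation,
                          energy_cutoff: float = DEFAULT_HB_CUTOFF) -> int:
    """Number of unique internal backbone-backbone H-bonds."""
    return len({(hb.donor, hb.acceptor)
                for hb in detect_backbone_hbonds(conf, energy_cutoff)})


def find_unsatisfied_nh(conf: Conformation,
                        energy_cutoff: float = DEFAULT_HB_CUTOFF) -> set:
    """Residue indices (0-based) whose backbone NH donates no H-bond."""
    donors = {hb.donor for hb in detect_backbone_hbonds(conf, energy_cutoff)}
    return {i for i, r in enumerate(conf.sequence)
            if r.has_nh and i not in donors}


def check_oversaturated_acceptors(conf: Conformation, max_allowed: int = 0,
                                  per_acceptor_max: int = 2,
                                  energy_cutoff: float = DEFAULT_HB_CUTOFF):
    """Check that no more than *max_allowed* carbonyls accept too many bonds.

    Returns ``(passed, offenders)`` where offenders lists acceptor residue
    indices receiving more than *per_acceptor_max* H-bonds.
    """
    counts: dict = {}
    for hb in detect_backbone_hbonds(conf, energy_cutoff):
        counts[hb.acceptor] = counts.get(hb.acceptor, 0) + 1
    offenders = sorted(a for a, c in counts.items() if c > per_acceptor_max)
    return len(offenders) <= max_allowed, offenders


def score(conf: Conformation, weights: WeightSet | str = "standard",
          composition_constraints=None,
          hb_cutoff: float = DEFAULT_HB_CUTOFF) -> EnergyBreakdown:
    """Full surrogate energy breakdown of a conformation."""
    if isinstance(weights, str):
        weights = WEIGHT_SETS[weights]
    n = len(conf)
    rep, atr = _lj_terms(conf)
    hb_sr = hb_lr = 0.0
    for hb in detect_backbone_hbonds(conf, hb_cutoff):
        sep = min((hb.donor - hb.acceptor) % n, (hb.acceptor - hb.donor) % n)
        if sep <= HB_SR_MAX_SEP:
            hb_sr += hb.energy
        else:
            hb_lr += hb.energy
    rama = paapp = 0.0
    t = conf.torsions
    for i, r in enumerate(conf.sequence):
        nxt = conf.sequence[(i + 1) % n]
        prepro = (nxt.aa == "PRO") or nxt.n_methyl
        rama += rama_energy(r.aa, r.chirality, t[i, 0], t[i, 1], prepro)
        paapp += p_aa_pp_energy(r.aa, r.chirality, t[i, 0], t[i, 1])
    omega_dev = np.minimum(np.abs(wrap_angle(t[:, 2])),
                           np.abs(wrap_angle(t[:, 2] - 180.0)))
    omega_e = float(OMEGA_K * np.sum(omega_dev ** 2))
    chainbreak = _chainbreak(conf)
    comp = 0.0
    if composition_constraints:
        from .design import composition_penalty
        comp = composition_penalty(conf.sequence, composition_constraints)
    terms = {"fa_rep": rep, "fa_atr": atr, "hbond_sr_bb": hb_sr,
             "hbond_lr_bb": hb_lr, "rama_prepro": rama, "p_aa_pp": paapp,
             "omega": omega_e, "chainbreak": chainbreak,
             "aa_composition": comp}
    return EnergyBreakdown(terms, weights)


def _chainbreak(conf: Conformation, geom=IDEAL) -> float:
    """Summed harmonic deviation of every peptide bond from ideal geometry.

    For chains built from torsions all mid-chain bonds are exactly ideal,
    so this equals the closure-bond penalty; summing over all bonds makes
    the term invariant under cyclic permutation.
    """
    C = conf.coords["C"]
    CA = conf.coords["CA"]
    Nn = np.roll(conf.coords["N"], -1, axis=0)
    CAn = np.roll(CA, -1, axis=0)
    cn = Nn - C
    blen = np.linalg.norm(cn, axis=1)

    def _ang(u, v):
        cu = (u * v).sum(-1) / (np.linalg.norm(u, axis=1) *
                                np.linalg.norm(v, axis=1))
        return np.degrees(np.arccos(np.clip(cu, -1.0, 1.0)))

    ang_c = _ang(CA - C, cn)
    ang_n = _ang(C - Nn, CAn - Nn)
    # realized peptide-bond dihedral vs the stored omega torsion: exactly
    # zero for bonds built from torsions, nonzero only across an open cut
    b1 = cn / np.maximum(blen, 1e-12)[:, None]
    v = (CA - C) - ((CA - C) * b1).sum(-1, keepdims=True) * b1
    w = (CAn - Nn) - ((CAn - Nn) * b1).sum(-1, keepdims=True) * b1
    x = (v * w).sum(-1)
    y = (np.cross(b1, v) * w).sum(-1)
    omega_real = np.degrees(np.arctan2(y, x))
    d_tor = wrap_angle(omega_real - conf.torsions[:, 2])
    return float(CB_K_LEN * np.sum((blen - geom.c_n) ** 2) +
                 CB_K_ANG * (np.sum((ang_c - geom.ca_c_n) ** 2) +
                             np.sum((ang_n - geom.c_n_ca) ** 2)) +
                 CB_K_TOR * np.sum(d_tor ** 2))
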