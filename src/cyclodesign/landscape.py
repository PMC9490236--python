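"""Energy-landscape structure prediction, funnel analysis and clustering.

For a fixed designed sequence, alternative closed conformations are
generated with the kinematic-closure sampler, energy-minimized in torsion
space (the chainbreak penalty keeps the ring closed) and plotted as energy
versus backbone RMSD to the design model. A funnel-shaped landscape whose
lowest energies converge on the design, with a clear energy gap (dE) to
the best alternative state, indicates a well-structured design; clusters
of low-energy structures are labelled LE_0, LE_1, ... by the energy rank
of their lowest member, LE_0 being seeded by local minimization of the
design model itself.

Backbone RMSD follows the macrocycle conventions: least-squares proper
superposition over the backbone heavy atoms N, CA, C, O plus the N-methyl
carbon CN where both structures carry it, optionally minimized over cyclic
permutations of the residue numbering and/or the mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .model import (Conformation, MacrocycleSequence, build_from_torsions,
                    mirror as mirror_conf, cyclic_permute)
from .energetics import WEIGHT_SETS, WeightSet, score
from .closure import BackboneAcceptancePolicy, sample_cyclic_backbones

__all__ = [
    "backbone_rmsd", "minimize", "LandscapePoint", "FunnelSummary",
    "predict_landscape", "energy_based_cluster",
    "detect_isoenergetic_states", "omega_signature",
]


def _paired_coords(a: Conformation, b: Conformation):
    """Matched backbone heavy-atom coordinate arrays of two conformations."""
    if len(a) != len(b):
        raise ValueError("conformations differ in length")
    xa, xb = [], []
    for i in range(len(a)):
        for name in ("N", "CA", "C", "O"):
            xa.append(a.atom(name, i))
            xb.append(b.atom(name, i))
        if a.has_atom("CN", i) and b.has_atom("CN", i):
            xa.append(a.atom("CN", i))
            xb.append(b.atom("CN", i))
    return np.array(xa), np.array(xb)


def _kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares RMSD after optimal proper-rotation superposition."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    resid = xc @ r.T - yc
    return float(np.sqrt((resid ** 2).sum() / len(x)))


def backbone_rmsd(a: Conformation, b: Conformation,
                  allow_cyclic_perm: bool = False,
                  allow_mirror: bool = False) -> float:
    """Backbone heavy-atom RMSD (A) between two macrocycle conformations.

    With ``allow_cyclic_perm`` the minimum over all rotations of b's
    residue numbering is returned; with ``allow_mirror`` the minimum over
    b and its mirror image (handled by explicit reflection followed by
    proper superposition).
    """
    variants = [b]
    if allow_mirror:
        variants.append(mirror_conf(b))
    best = np.inf
    for v in variants:
        shifts = range(len(b)) if allow_cyclic_perm else (0,)
        for k in shifts:
            vb = cyclic_permute(v, k) if k else v
            x, y = _paired_coords(a, vb)
            best = min(best, _kabsch_rmsd(x, y))
    return best


def minimize(conf: Conformation, weights: WeightSet | str = "standard",
             max_iter: int = 80, move_omega: bool = True) -> Conformation:
    """Local torsion-space descent of the surrogate energy.

    The chainbreak penalty is part of the objective, so the closure bond
    cannot drift open. The best conformation visited is returned; its
    energy never exceeds the input energy.
    """
    if isinstance(weights, str):
        weights = WEIGHT_SETS[weights]
    seq = conf.sequence
    n = len(conf)
    t0 = conf.torsions.copy()
    if move_omega:
        idx = [(i, j) for i in range(n) for j in range(3)]
    else:
        idx = [(i, j) for i in range(n) for j in range(2)]
    x0 = np.array([t0[i, j] for i, j in idx])
    best = {"e": score(conf, weights).total, "x": x0.copy()}

    def obj(x):
        t = t0.copy()
        for k, (i, j) in enumerate(idx):
            t[i, j] = x[k]
        c = build_from_torsions(seq, t)
        e = score(c, weights).total
        if e < best["e"]:
            best["e"] = e
            best["x"] = x.copy()
        return e

    # central differences keep the descent mirror-equivariant (a forward
    # difference biases the two enantiomers differently)
    _scipy_minimize(obj, x0, method="L-BFGS-B", jac="3-point",
                    options={"maxiter": max_iter, "eps": 1e-3})
    t = t0.copy()
    for k, (i, j) in enumerate(idx):
        t[i, j] = best["x"][k]
    return build_from_torsions(seq, t)


def omega_signature(conf: Conformation) -> str:
    """Per-residue cis/trans signature of the peptide bonds ('c'/'t')."""
    return "".join("c" if abs(w) < 90.0 else "t"
                   for w in conf.torsions[:, 2])


@dataclass
class LandscapePoint:
    point_id: str
    energy: float
    rmsd: float
    signature: str
    conformation: Conformation
    is_design_minimum: bool = False


@dataclass
class Cluster:
    label: str
    center: LandscapePoint
    members: list


@dataclass
class FunnelSummary:
    lowest: LandscapePoint
    delta_e: float | None
    clusters: list

    def as_dict(self):
        return {
            "lowest_energy": self.lowest.energy,
            "lowest_rmsd": self.lowest.rmsd,
            "delta_e": self.delta_e,
            "clusters": [{"label": c.label, "energy": c.center.energy,
                          "rmsd": c.center.rmsd, "size": len(c.members),
                          "signature": c.center.signature}
                         for c in self.clusters],
        }


def energy_based_cluster(points, n_lowest: int = 250,
                         rmsd_cutoff: float = 1.0) -> list:
    """Greedy leader clustering of the lowest-energy structures.

    Repeatedly takes the lowest-energy unassigned structure as a cluster
    center and assigns every structure within the RMSD cutoff to it;
    clusters are labelled LE_0, LE_1, ... by the energy of their center.
    Ties are broken by insertion order, so the partition is deterministic.
    """
    if not points:
        return []
    pool = sorted(points, key=lambda p: (p.energy, p.point_id))[:n_lowest]
    unassigned = list(pool)
    clusters = []
    while unassigned:
        center = unassigned[0]
        members = []
        rest = []
        for p in unassigned:
            if backbone_rmsd(center.conformation, p.conformation) \
                    <= rmsd_cutoff:
                members.append(p)
            else:
                rest.append(p)
        clusters.append(Cluster(f"LE_{len(clusters)}", center, members))
        unassigned = rest
    return clusters


def predict_landscape(seq: MacrocycleSequence, design_ref: Conformation,
                      n_samples: int, rng_seed: int,
                      acceptance: BackboneAcceptancePolicy | None = None,
                      weights: str = "standard",
                      minimize_iter: int = 40,
                      rmsd_split: float = 2.0,
                      n_lowest: int = 250,
                      rmsd_cutoff: float = 1.0):
    """Sample, minimize and score alternative conformations of a sequence.

    Returns ``(points, summary)``. The design model's own local minimum is
    always included (and seeds cluster LE_0 when it is the lowest); dE is
    the energy of the lowest point farther than ``rmsd_split`` from the
    design minus the lowest point within it.
    """
    policy = acceptance or BackboneAcceptancePolicy(min_hbonds=0)
    points = []
    le0_conf = minimize(design_ref, weights, max_iter=minimize_iter)
    le0 = LandscapePoint("design_min", score(le0_conf, weights).total,
                         backbone_rmsd(le0_conf, design_ref),
                         omega_signature(le0_conf), le0_conf,
                         is_design_minimum=True)
    points.append(le0)
    if n_samples > 0:
        sampled = sample_cyclic_backbones(seq, n_samples, rng_seed, policy)
        for k, conf in enumerate(sampled):
            m = minimize(conf, weights, max_iter=minimize_iter)
            points.append(LandscapePoint(
                f"sample_{k}", score(m, weights).total,
                backbone_rmsd(m, design_ref), omega_signature(m), m))
    near = [p for p in points if p.rmsd <= rmsd_split]
    far = [p for p in points if p.rmsd > rmsd_split]
    delta_e = None
    if near and far:
        delta_e = min(p.energy for p in far) - min(p.energy for p in near)
    clusters = energy_based_cluster(points, n_lowest, rmsd_cutoff)
    lowest = min(points, key=lambda p: (p.energy, p.point_id))
    return points, FunnelSummary(lowest, delta_e, clusters)


def detect_isoenergetic_states(clusters, threshold: float = 5.0,
                               sequence: MacrocycleSequence | None = None):
    """Pairs of cluster minima closer in energy than the threshold.

    Each pair is annotated with the residue positions where the cis/trans
    signatures of the two minima differ, and whether any such position is
    proline or N-methylated (a candidate cis/trans switch).
    """
    out = []
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            a, b = clusters[i].center, clusters[j].center
            if abs(a.energy - b.energy) >= threshold:
                continue
            flips = [k for k, (x, y) in
                     enumerate(zip(a.signature, b.signature)) if x != y]
            switch = False
            if sequence is not None:
                for k in flips:
                    nxt = sequence[(k + 1) % len(sequence)]
                    if nxt.aa == "PRO" or nxt.n_methyl:
                        switch = True
            out.append({"pair": (clusters[i].label, clusters[j].label),
                        "delta_e": abs(a.energy - b.energy),
                        "omega_flips": flips,
                        "cis_trans_switch": switch})
    return out
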