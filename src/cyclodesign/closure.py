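"""Analytic kinematic closure of N-to-C cyclic peptide backbones.

Closing a macrocycle leaves six backbone torsions — phi and psi of three
"pivot" residues — to be solved so that the C(n)->N(1) bond has ideal
amide geometry. With all other torsions fixed, the three chain segments
between consecutive pivot CA atoms are rigid bodies, so the problem
reduces to the classic tripeptide-closure geometry: a triangle of pivot
CA atoms with fixed side lengths, each rigid segment free to spin about
its triangle edge, and one bond-angle constraint (N-CA-C) at each vertex.

Writing each vertex constraint in half-tangent variables of the three
spin angles gives three biquadratic equations, each coupling two
consecutive spins. The solver eliminates two variables with exact
Sylvester resultants (the bivariate coefficient arrays are convolved
numerically, no symbolic algebra), leaving a degree-16 polynomial in the
last half-tangent whose real roots seed Newton polishing of the full
3x3 trigonometric system. Every real closure solution corresponds to a
root, up to the 16 solutions the formulation admits. Two passes with
different spin-reference offsets guard against the tan(s/2) pole.

The backbone sampler draws non-pivot phi/psi from the flat-bottom
mirror-symmetric Ramachandran region, solves closure, filters solutions
(pivot rama check, bump check, minimum internal H-bond count) and keeps
the lowest-energy surviving solution per attempt under the
closure-selection weight set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .geometry import IDEAL, IdealGeometry, dihedral, place_atom, wrap_angle
from .model import Conformation, MacrocycleSequence, build_from_torsions
from .energetics import count_internal_hbonds, score
from .ramachandran import rama_prepro_check, sample_flat_symm

__all__ = [
    "ClosureProblem", "ClosureSolution", "solve_closure",
    "BackboneAcceptancePolicy", "sample_cyclic_backbones",
    "loop_bump_check", "default_pivots", "min_hbonds_for_length",
]

_THETA = IDEAL.n_ca_c  # bond angle constrained at each pivot CA
_OFFSET_SETS = ((0.9, 1.9, 2.9), (2.1, 0.6, 1.4))


@dataclass
class ClosureProblem:
    """A closure instance: fixed torsions everywhere except pivot phi/psi."""

    sequence: MacrocycleSequence
    pivots: tuple
    torsions: np.ndarray
    anchor: int | None = None
    geom: IdealGeometry = field(default_factory=lambda: IDEAL)

    def __post_init__(self):
        self.torsions = np.asarray(self.torsions, dtype=float)
        n = len(self.sequence)
        p = tuple(sorted(int(x) % n for x in self.pivots))
        if len(set(p)) != 3:
            raise ValueError("three distinct pivot residues required")
        if self.anchor is not None and self.anchor % n in p:
            raise ValueError("anchor residue cannot be a pivot")
        self.pivots = p
        if self.torsions.shape != (n, 3):
            raise ValueError("torsions must be (n, 3)")


@dataclass
class ClosureSolution:
    torsions: np.ndarray          # full (n, 3) with solved pivot phi/psi
    conformation: Conformation
    pivot_torsions: np.ndarray    # (3, 2) phi/psi at the pivots


def default_pivots(n: int, anchor: int) -> tuple:
    """Three pivots roughly equally spaced around the cycle, anchor excluded."""
    return tuple(sorted((anchor + 1 + (k * (n - 1)) // 3) % n
                        for k in range(3)))


def min_hbonds_for_length(n: int) -> int:
    """Length schedule for the required internal H-bond count."""
    if n <= 7:
        return 1
    if n <= 9:
        return 2
    return 3


# ---------------------------------------------------------------------------
# rigid inter-pivot units
# ---------------------------------------------------------------------------

def _build_unit(problem: ClosureProblem, p: int, q: int):
    """Build the rigid segment CA(p)..CA(q) in its own frame.

    Returns (atoms, d, b_pendant, a_pendant) where atoms maps
    (residue, name) -> local coordinates, d is the CA(p)-CA(q) distance
    and the pendants are the unit vectors CA(p)->C(p) and CA(q)->N(q).
    """
    g = problem.geom
    n = len(problem.sequence)
    t = problem.torsions
    atoms = {}
    ca_p = np.zeros(3)
    c_p = np.array([g.ca_c, 0.0, 0.0])
    atoms[(p, "CA")] = ca_p
    atoms[(p, "C")] = c_p
    # azimuth of the first amide N is arbitrary: it defines the unit frame
    n_next = place_atom(np.array([0.0, 1.0, 0.0]), ca_p, c_p,
                        g.c_n, g.ca_c_n, 0.0)
    j = (p + 1) % n
    atoms[(j, "N")] = n_next
    prev = {"N": None, "CA": ca_p, "C": c_p}
    cur_n = n_next
    res = p
    while True:
        nxt = (res + 1) % n
        ca_next = place_atom(prev["CA"], prev["C"], cur_n,
                             g.n_ca, g.c_n_ca, t[res, 2])     # omega(res)
        atoms[(nxt, "CA")] = ca_next
        if nxt == q:
            break
        c_next = place_atom(prev["C"], cur_n, ca_next,
                            g.ca_c, g.n_ca_c, t[nxt, 0])       # phi(nxt)
        atoms[(nxt, "C")] = c_next
        n_after = place_atom(cur_n, ca_next, c_next,
                             g.c_n, g.ca_c_n, t[nxt, 1])       # psi(nxt)
        atoms[((nxt + 1) % n, "N")] = n_after
        prev = {"N": cur_n, "CA": ca_next, "C": c_next}
        cur_n = n_after
        res = nxt
    ca_q = atoms[(q, "CA")]
    d = float(np.linalg.norm(ca_q - ca_p))
    b_pend = (c_p - ca_p) / np.linalg.norm(c_p - ca_p)
    n_q = atoms[(q, "N")]
    a_pend = (n_q - ca_q) / np.linalg.norm(n_q - ca_q)
    return atoms, d, b_pend, a_pend, ca_q


def _frame(e: np.ndarray, helper: np.ndarray, offset: float):
    """Right-handed frame (e, m, n) with m/n rotated by *offset* about e."""
    m = helper - np.dot(helper, e) * e
    nm = np.linalg.norm(m)
    if nm < 1e-8:
        helper = np.array([0.0, 0.0, 1.0])
        m = helper - np.dot(helper, e) * e
        nm = np.linalg.norm(m)
        if nm < 1e-8:
            helper = np.array([0.0, 1.0, 0.0])
            m = helper - np.dot(helper, e) * e
            nm = np.linalg.norm(m)
    m /= nm
    nvec = np.cross(e, m)
    c, s = np.cos(offset), np.sin(offset)
    return e, c * m + s * nvec, -s * m + c * nvec


def _pendant_basis(v, frame):
    """Decompose pendant v so v(sigma) = A0 + Ac*cos(sigma) + As*sin(sigma)
    in the world edge frame."""
    e, m, nvec = frame
    return float(np.dot(v, e)), float(np.dot(v, m)), float(np.dot(v, nvec))


# half-tangent basis rows: (1+t^2)*[1, cos, sin] = sum_k t^k * _R[k]
_R = np.array([[1.0, 1.0, 0.0],
               [0.0, 0.0, 2.0],
               [1.0, -1.0, 0.0]])


def _vertex_matrix(a_comp, edge_a_world, b_comp, edge_b_world, cos_theta):
    """3x3 matrix M with g = [1,c,s]_a M [1,c,s]_b^T - handled via M[0,0]."""
    aa, ab, ag = a_comp
    ba, bb, bg = b_comp
    ea, ma, na = edge_a_world
    eb, mb, nb = edge_b_world
    A = [aa * ea, ab * ma + ag * na, -ag * ma + ab * na]
    B = [ba * eb, bb * mb + bg * nb, -bg * mb + bb * nb]
    M = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            M[i, j] = float(np.dot(A[i], B[j]))
    M[0, 0] -= cos_theta
    return M


def _biquadratic(M):
    """Coefficient matrix C with P(x, y) = sum C[j,k] x^j y^k from M."""
    return _R @ M @ _R.T


def _poly_mul2(a, b):
    return convolve2d(a, b)


def _quad_roots(c0, c1, c2, tol=1e-9):
    """Real roots of c2 x^2 + c1 x + c0, tolerant of degree collapse."""
    scale = max(abs(c0), abs(c1), abs(c2), 1e-30)
    c0, c1, c2 = c0 / scale, c1 / scale, c2 / scale
    if abs(c2) < 1e-12:
        if abs(c1) < 1e-12:
            return []
        return [-c0 / c1]
    disc = c1 * c1 - 4.0 * c2 * c0
    if disc < -tol:
        return []
    disc = max(disc, 0.0)
    sq = np.sqrt(disc)
    return [(-c1 + sq) / (2 * c2), (-c1 - sq) / (2 * c2)]


def _solve_spin_system(Ms, max_newton=60):
    """All real (s1, s2, s3) with u(s_prev)^T M_i u(s_i) = 0 at each vertex.

    Ms[i] couples spin i-1 (rows) and spin i (cols), i = 0, 1, 2 for the
    vertices at pivots 1..3; spin indices are edges 3, 1, 2 in sequence
    (vertex i couples edge i-1 and edge i).
    """
    C1 = _biquadratic(Ms[0])   # (t3, t1)
    C2 = _biquadratic(Ms[1])   # (t1, t2)
    C3 = _biquadratic(Ms[2])   # (t2, t3)

    # eliminate t1: P1 quadratic in t1 (coeffs poly in t3), P2 quadratic in
    # t1 (coeffs poly in t2)
    A = [C1[:, k].reshape(3, 1) for k in range(3)]   # poly in t3 (rows)
    B = [C2[k, :].reshape(1, 3) for k in range(3)]   # poly in t2 (cols)

    def _bi(ai, bj):
        return _poly_mul2(A[ai], B[bj])

    d20 = _bi(2, 0) - _bi(0, 2)
    d21 = _bi(2, 1) - _bi(1, 2)
    d10 = _bi(1, 0) - _bi(0, 1)
    Rm = _poly_mul2(d20, d20) - _poly_mul2(d21, d10)   # rows t3, cols t2

    # Sylvester elimination of t2 between Rm (deg<=4) and P3 (deg<=2 in t2)
    deg_r = Rm.shape[1] - 1
    Rcoef = [Rm[:, k] for k in range(Rm.shape[1])]     # poly in t3, asc t2
    Pcoef = [C3[k, :] for k in range(3)]               # poly in t3, asc t2

    npts = 41
    xs = 3.0 * np.cos(np.pi * np.arange(npts) / (npts - 1))
    size = deg_r + 2
    dets = np.empty(npts)
    from numpy.polynomial import polynomial as P
    for m, x in enumerate(xs):
        rvals = [float(P.polyval(x, c)) for c in Rcoef]
        pvals = [float(P.polyval(x, c)) for c in Pcoef]
        S = np.zeros((size, size))
        # rows of R (2 shifts), rows of P3 (deg_r shifts)
        for sh in range(2):
            for k, v in enumerate(rvals):
                S[sh, sh + (deg_r - k)] = v
        for sh in range(deg_r):
            for k, v in enumerate(pvals):
                S[2 + sh, sh + (2 - k)] = v
        dets[m] = np.linalg.det(S)
    scale = np.max(np.abs(dets))
    if not np.isfinite(scale) or scale < 1e-250:
        t3_seeds = np.tan(np.linspace(-np.pi / 2 + 0.01,
                                      np.pi / 2 - 0.01, 181))
    else:
        from numpy.polynomial import chebyshev as Ch
        coeffs = Ch.chebfit(xs / 3.0, dets / scale, 16)
        roots = Ch.chebroots(coeffs) * 3.0
        t3_seeds = [float(r.real) for r in roots
                    if abs(r.imag) <= 1e-4 * (1.0 + abs(r.real))]

    M = [m.tolist() for m in Ms]
    pairs = ((2, 0), (0, 1), (1, 2))

    def _g(s):
        u = [(1.0, math.cos(x), math.sin(x)) for x in s]
        out = []
        for i, (a, b) in enumerate(pairs):
            ua, ub, mi = u[a], u[b], M[i]
            out.append(sum(ua[r] * (mi[r][0] * ub[0] + mi[r][1] * ub[1] +
                                    mi[r][2] * ub[2]) for r in range(3)))
        return out

    def _newton(s):
        s = list(s)
        for _ in range(max_newton):
            u = [(1.0, math.cos(x), math.sin(x)) for x in s]
            du = [(0.0, -math.sin(x), math.cos(x)) for x in s]
            g = [0.0, 0.0, 0.0]
            J = [[0.0] * 3 for _ in range(3)]
            for i, (a, b) in enumerate(pairs):
                mi = M[i]
                mu = [mi[r][0] * u[b][0] + mi[r][1] * u[b][1] +
                      mi[r][2] * u[b][2] for r in range(3)]
                mdu = [mi[r][0] * du[b][0] + mi[r][1] * du[b][1] +
                       mi[r][2] * du[b][2] for r in range(3)]
                g[i] = u[a][0] * mu[0] + u[a][1] * mu[1] + u[a][2] * mu[2]
                J[i][a] += du[a][0] * mu[0] + du[a][1] * mu[1] + \
                    du[a][2] * mu[2]
                J[i][b] += u[a][0] * mdu[0] + u[a][1] * mdu[1] + \
                    u[a][2] * mdu[2]
            if max(abs(x) for x in g) < 1e-12:
                return s, True
            det = (J[0][0] * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
                   - J[0][1] * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
                   + J[0][2] * (J[1][0] * J[2][1] - J[1][1] * J[2][0]))
            if abs(det) < 1e-14:
                return s, False
            # Cramer's rule for the 3x3 Newton step
            inv = 1.0 / det
            b0, b1, b2 = -g[0], -g[1], -g[2]
            dx = (b0 * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
                  - J[0][1] * (b1 * J[2][2] - J[1][2] * b2)
                  + J[0][2] * (b1 * J[2][1] - J[1][1] * b2)) * inv
            dy = (J[0][0] * (b1 * J[2][2] - J[1][2] * b2)
                  - b0 * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
                  + J[0][2] * (J[1][0] * b2 - b1 * J[2][0])) * inv
            dz = (J[0][0] * (J[1][1] * b2 - b1 * J[2][1])
                  - J[0][1] * (J[1][0] * b2 - b1 * J[2][0])
                  + b0 * (J[1][0] * J[2][1] - J[1][1] * J[2][0])) * inv
            s[0] += max(-0.5, min(0.5, dx))
            s[1] += max(-0.5, min(0.5, dy))
            s[2] += max(-0.5, min(0.5, dz))
        g = _g(s)
        return s, max(abs(x) for x in g) < 1e-10

    from numpy.polynomial import polynomial as P

    sols = []
    for t3 in t3_seeds:
        # P1 coefficients of t1 given t3 (C1 rows are t3 powers)
        c_t1 = [float(P.polyval(t3, C1[:, k])) for k in range(3)]
        for t1 in _quad_roots(c_t1[0], c_t1[1], c_t1[2]):
            c_t2 = [float(P.polyval(t1, C2[:, k])) for k in range(3)]
            for t2 in _quad_roots(c_t2[0], c_t2[1], c_t2[2]):
                s0 = (2 * math.atan(t1), 2 * math.atan(t2),
                      2 * math.atan(t3))
                # spurious branch pairings fail the third equation by O(1)
                if max(abs(x) for x in _g(s0)) > 5e-2:
                    continue
                s, ok = _newton(s0)
                if ok:
                    sa = np.deg2rad(wrap_angle(np.degrees(np.array(s))))
                    if not any(np.max(np.abs(wrap_angle(
                            np.degrees(sa - s0_)))) < 1e-4 for s0_ in sols):
                        sols.append(sa)
    return sols


def solve_closure(problem: ClosureProblem) -> list:
    """All real closure solutions for the six pivot torsions.

    Returns a (possibly empty) list of :class:`ClosureSolution`; each
    solution's rebuilt conformation has the prescribed closure-bond
    geometry to numerical precision.
    """
    p1, p2, p3 = problem.pivots
    units = []
    for (p, q) in ((p1, p2), (p2, p3), (p3, p1)):
        units.append(_build_unit(problem, p, q))
    d1, d2, d3 = (u[1] for u in units)
    # canonical triangle: V1 origin, V2 on +x, V3 in the upper half-plane
    x3 = (d1 * d1 + d3 * d3 - d2 * d2) / (2.0 * d1)
    y3sq = d3 * d3 - x3 * x3
    if y3sq <= 1e-12:
        return []
    V = [np.zeros(3), np.array([d1, 0.0, 0.0]),
         np.array([x3, np.sqrt(y3sq), 0.0])]
    edges_world = []
    for k in range(3):
        e = V[(k + 1) % 3] - V[k]
        e = e / np.linalg.norm(e)
        edges_world.append(e)

    cos_theta = np.cos(np.deg2rad(_THETA))
    found = []
    for offsets in _OFFSET_SETS:
        frames_w = [_frame(edges_world[k], np.array([0.0, 0.0, 1.0]), 0.0)
                    for k in range(3)]
        # local frames per unit, rotated by the pass offset
        frames_l = []
        pend_a = []
        pend_b = []
        for k, (atoms, d, b_p, a_p, ca_q) in enumerate(units):
            e_l = ca_q / np.linalg.norm(ca_q)
            fl = _frame(e_l, b_p, offsets[k])
            frames_l.append(fl)
            pend_b.append(_pendant_basis(b_p, fl))
            pend_a.append(_pendant_basis(a_p, fl))
        Ms = []
        for i in range(3):
            prev = (i + 2) % 3   # unit ending at vertex i
            Ms.append(_vertex_matrix(pend_a[prev], frames_w[prev],
                                     pend_b[i], frames_w[i], cos_theta))
        for s in _solve_spin_system(Ms):
            sol = _assemble(problem, units, frames_l, frames_w, V, s)
            if sol is None:
                continue
            if not any(np.max(np.abs(wrap_angle(
                    sol.pivot_torsions - s0.pivot_torsions))) < 1e-5
                    for s0 in found):
                found.append(sol)
    return found


def _assemble(problem, units, frames_l, frames_w, V, spins):
    """Place units on the triangle with the solved spins, measure pivot
    torsions, rebuild the ring from torsions and validate closure."""
    n = len(problem.sequence)
    world = {}
    for k, (atoms, d, b_p, a_p, ca_q) in enumerate(units):
        e_l, m_l, n_l = frames_l[k]
        e_w, m_w, n_w = frames_w[k]
        c, s = np.cos(spins[k]), np.sin(spins[k])
        for key, x in atoms.items():
            al = float(np.dot(x, e_l))
            be = float(np.dot(x, m_l))
            ga = float(np.dot(x, n_l))
            world[key] = (V[k] + al * e_w + (be * c - ga * s) * m_w +
                          (be * s + ga * c) * n_w)
    t = problem.torsions.copy()
    pivots = problem.pivots
    piv_t = np.empty((3, 2))
    for j, p in enumerate(pivots):
        phi = dihedral(world[((p - 1) % n, "C")], world[(p, "N")],
                       world[(p, "CA")], world[(p, "C")])
        psi = dihedral(world[(p, "N")], world[(p, "CA")],
                       world[(p, "C")], world[((p + 1) % n, "N")])
        t[p, 0], t[p, 1] = phi, psi
        piv_t[j] = (phi, psi)
    conf = build_from_torsions(problem.sequence, t, problem.geom)
    if not conf.is_closed(tol_bond=1e-4, tol_ang=1e-3):
        return None
    return ClosureSolution(conf.torsions.copy(), conf, piv_t)


# ---------------------------------------------------------------------------
# bump check and backbone sampling
# ---------------------------------------------------------------------------

def loop_bump_check(conf: Conformation, clash_distance: float = 2.6) -> bool:
    """True iff no pair of backbone heavy atoms separated by more than two
    bonds sits closer than the clash distance."""
    from .energetics import _atom_list, _bond_separation
    atoms = [(i, nm, x, r) for (i, nm, x, r) in _atom_list(conf)
             if nm != "CB"]
    keys = [(i, nm) for i, nm, _, _ in atoms]
    xyz = np.array([a[2] for a in atoms])
    sep = _bond_separation(conf, keys, cutoff=2)
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(len(atoms), k=1)
    bad = (sep[iu] > 2) & (d[iu] < clash_distance)
    return not bool(np.any(bad))


@dataclass
class BackboneAcceptancePolicy:
    """Filters applied to closure solutions during backbone sampling."""

    min_hbonds: int | None = None      # None -> length schedule
    rama_cutoff: float = 2.0
    clash_distance: float = 2.6
    hb_cutoff: float = -0.25
    cis_probability: float = 0.0       # at proline / N-methyl positions only
    weights: str = "closure_selection"

    def required_hbonds(self, n: int) -> int:
        if self.min_hbonds is not None:
            return self.min_hbonds
        return min_hbonds_for_length(n)


def _accept_solution(sol: ClosureSolution, problem: ClosureProblem,
                     policy: BackboneAcceptancePolicy):
    conf = sol.conformation
    n = len(conf)
    for j, p in enumerate(problem.pivots):
        r = conf.sequence[p]
        nxt = conf.sequence[(p + 1) % n]
        prepro = (nxt.aa == "PRO") or nxt.n_methyl
        if not rama_prepro_check(r.aa, r.chirality, sol.pivot_torsions[j, 0],
                                 sol.pivot_torsions[j, 1],
                                 policy.rama_cutoff, prepro):
            return None
    if not loop_bump_check(conf, policy.clash_distance):
        return None
    if count_internal_hbonds(conf, policy.hb_cutoff) < \
            policy.required_hbonds(n):
        return None
    return score(conf, policy.weights).total


def sample_cyclic_backbones(seq: MacrocycleSequence, n_attempts: int,
                            rng_seed: int,
                            acceptance: BackboneAcceptancePolicy | None = None,
                            ) -> list:
    """Sample closed backbones; returns accepted Conformations (possibly
    empty), lowest-energy closure solution per successful attempt."""
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    policy = acceptance or BackboneAcceptancePolicy()
    rng = np.random.default_rng(rng_seed)
    n = len(seq)
    out = []
    for _ in range(n_attempts):
        anchor = int(rng.integers(n))
        pivots = default_pivots(n, anchor)
        t = np.zeros((n, 3))
        t[:, 2] = 180.0
        if policy.cis_probability > 0.0:
            for i, r in enumerate(seq):
                nxt = seq[(i + 1) % n]
                if (nxt.aa == "PRO" or nxt.n_methyl) and \
                        rng.random() < policy.cis_probability:
                    t[i, 2] = 0.0
        draws = sample_flat_symm(rng, n)
        t[:, 0] = draws[:, 0]
        t[:, 1] = draws[:, 1]
        problem = ClosureProblem(seq, pivots, t, anchor=anchor)
        best = None
        best_e = None
        for sol in solve_closure(problem):
            e = _accept_solution(sol, problem, policy)
            if e is not None and (best_e is None or e < best_e):
                best, best_e = sol, e
        if best is not None:
            out.append(best.conformation)
    return out
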