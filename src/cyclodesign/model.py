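"""Macrocycle data model: residues, sequences and backbone conformations.

A macrocycle is a head-to-tail (N-to-C) cyclized peptide of 6-12 residues
drawn from a hydrophobic alphabet of L- and D-amino acids, optionally
N-methylated. A :class:`Conformation` couples a sequence with per-residue
(phi, psi, omega) torsions and Cartesian backbone coordinates (N, CA, C, O,
plus the amide H where an NH exists and the CN methyl carbon where the
nitrogen is methylated).

Torsion conventions
-------------------
Degrees, wrapped to (-180, 180]. ``omega[i]`` is the peptide bond between
residue ``i`` and ``i+1``, cyclically: ``omega[n-1]`` (0-based) spans the
closure bond C(n)->N(1). ``phi[0]``, ``psi[n-1]`` and ``omega[n-1]`` cross
the cut; they are realized against virtual extension atoms when building
and measured across the actual closure bond, so build/measure round-trips
are exact for closed rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import IDEAL, IdealGeometry, dihedral, place_atom, wrap_angle

__all__ = [
    "ResidueSpec",
    "MacrocycleSequence",
    "Conformation",
    "build_from_torsions",
    "measure_torsions",
    "mirror",
    "cyclic_permute",
    "L_ALPHABET",
    "D_ALPHABET",
    "ACHIRAL",
]

# Base identities of the hydrophobic design alphabet (L-form 3-letter codes).
L_ALPHABET = ("ALA", "VAL", "LEU", "ILE", "PHE", "PRO")
D_ALPHABET = tuple("D-" + aa for aa in L_ALPHABET)
ACHIRAL = ("GLY", "AIB")

_KNOWN_AA = set(L_ALPHABET) | set(ACHIRAL)

# PDB chemical-component names for the D-amino acids.
PDB_D_NAMES = {
    "ALA": "DAL", "PHE": "DPH", "ILE": "DIL",
    "LEU": "DLE", "PRO": "DPR", "VAL": "DVA",
}
PDB_D_NAMES_INV = {v: k for k, v in PDB_D_NAMES.items()}


@dataclass(frozen=True)
class ResidueSpec:
    """One residue of a macrocycle.

    ``aa`` is the base (L-form) 3-letter identity; ``chirality`` is one of
    ``"L"``, ``"D"`` or ``"achiral"``. GLY and AIB are achiral; proline
    cannot be N-methylated (its nitrogen has no substitutable H).
    """

    aa: str
    chirality: str = "L"
    n_methyl: bool = False
    index: int = 0  # 1-based position in the cycle

    def __post_init__(self):
        if self.aa not in _KNOWN_AA:
            raise ValueError(f"unknown residue identity {self.aa!r}")
        if self.aa in ACHIRAL:
            if self.chirality != "achiral":
                raise ValueError(f"{self.aa} is achiral")
        elif self.chirality not in ("L", "D"):
            raise ValueError(f"bad chirality {self.chirality!r} for {self.aa}")
        if self.aa == "PRO" and self.n_methyl:
            raise ValueError("proline cannot be N-methylated")

    @property
    def code(self) -> str:
        """Display code, e.g. ``ALA``, ``D-ALA``, ``GLY``."""
        return ("D-" + self.aa) if self.chirality == "D" else self.aa

    @property
    def pdb_name(self) -> str:
        """PDB chemical-component residue name (DAL, DPH, ... for D)."""
        if self.chirality == "D":
            return PDB_D_NAMES[self.aa]
        return self.aa

    @property
    def has_nh(self) -> bool:
        """True when the backbone nitrogen bears an amide hydrogen."""
        return self.aa != "PRO" and not self.n_methyl

    def mirrored(self) -> "ResidueSpec":
        if self.chirality == "achiral":
            return self
        flip = "D" if self.chirality == "L" else "L"
        return replace(self, chirality=flip)

    @staticmethod
    def from_code(code: str, n_methyl: bool = False,
                  index: int = 0) -> "ResidueSpec":
        """Build from a display/PDB code such as ``D-LEU`` or ``DLE``."""
        code = code.upper()
        if code.startswith("D-"):
            return ResidueSpec(code[2:], "D", n_methyl, index)
        if code in PDB_D_NAMES_INV:
            return ResidueSpec(PDB_D_NAMES_INV[code], "D", n_methyl, index)
        chir = "achiral" if code in ACHIRAL else "L"
        return ResidueSpec(code, chir, n_methyl, index)


class MacrocycleSequence:
    """Ordered cyclic list of :class:`ResidueSpec`.

    Indexing is cyclic (``seq[i]`` accepts any integer); equality is
    position-wise with no implicit rotation.
    """

    def __init__(self, residues):
        residues = [replace(r, index=i + 1) for i, r in enumerate(residues)]
        if not residues:
            raise ValueError("empty sequence")
        self.residues = tuple(residues)

    def __len__(self):
        return len(self.residues)

    def __getitem__(self, i: int) -> ResidueSpec:
        return self.residues[i % len(self.residues)]

    def __iter__(self):
        return iter(self.residues)

    def __eq__(self, other):
        if not isinstance(other, MacrocycleSequence):
            return NotImplemented
        return self.residues == other.residues

    def __hash__(self):
        return hash(self.residues)

    def __repr__(self):
        parts = [r.code + ("(NMe)" if r.n_methyl else "")
                 for r in self.residues]
        return "cyclo-[" + "-".join(parts) + "]"

    def mirrored(self) -> "MacrocycleSequence":
        return MacrocycleSequence([r.mirrored() for r in self.residues])

    def permuted(self, k: int) -> "MacrocycleSequence":
        n = len(self)
        k %= n
        return MacrocycleSequence([self[i + k] for i in range(n)])

    @staticmethod
    def polyglycine(n: int) -> "MacrocycleSequence":
        return MacrocycleSequence(
            [ResidueSpec("GLY", "achiral") for _ in range(n)])

    def to_json_obj(self):
        return [{"aa": r.code, "chirality": r.chirality,
                 "n_methyl": r.n_methyl} for r in self.residues]

    @staticmethod
    def from_json_obj(obj) -> "MacrocycleSequence":
        res = []
        for i, d in enumerate(obj):
            r = ResidueSpec.from_code(d["aa"], bool(d.get("n_methyl", False)),
                                      i + 1)
            if "chirality" in d and d["chirality"] != r.chirality:
                raise ValueError(
                    f"chirality {d['chirality']!r} inconsistent with "
                    f"identity {d['aa']!r} at position {i + 1}")
            res.append(r)
        return MacrocycleSequence(res)


@dataclass
class Conformation:
    """A macrocycle backbone: sequence + torsions + Cartesian coordinates.

    ``coords`` maps atom names (``N``, ``CA``, ``C``, ``O``, ``H``, ``CN``)
    to ``(n, 3)`` float arrays; rows of ``H``/``CN`` are NaN where the atom
    does not exist for that residue.
    """

    sequence: MacrocycleSequence
    torsions: np.ndarray          # (n, 3) phi, psi, omega in degrees
    coords: dict = field(default_factory=dict)

    def __post_init__(self):
        self.torsions = np.asarray(self.torsions, dtype=float)
        if self.torsions.shape != (len(self.sequence), 3):
            raise ValueError("torsion array must be (n, 3)")

    def __len__(self):
        return len(self.sequence)

    def copy(self) -> "Conformation":
        return Conformation(self.sequence, self.torsions.copy(),
                            {k: v.copy() for k, v in self.coords.items()})

    def atom(self, name: str, i: int) -> np.ndarray:
        """Coordinates of atom *name* of residue *i* (0-based, cyclic)."""
        return self.coords[name][i % len(self)]

    def has_atom(self, name: str, i: int) -> bool:
        if name not in self.coords:
            return False
        return bool(np.all(np.isfinite(self.coords[name][i % len(self)])))

    def backbone_heavy(self) -> np.ndarray:
        """Stacked finite heavy-atom coordinates (N, CA, C, O, CN)."""
        rows = []
        for name in ("N", "CA", "C", "O", "CN"):
            if name in self.coords:
                arr = self.coords[name]
                rows.append(arr[np.all(np.isfinite(arr), axis=1)])
        return np.vstack(rows)

    def closure_residual(self, geom: IdealGeometry = IDEAL):
        """Deviation of the C(n)->N(1) bond from ideal closure geometry.

        Returns (d_bond [A], d_angle_C, d_angle_N, d_omega [deg]) absolute
        deviations.
        """
        from .geometry import bond_angle
        n = len(self)
        c = self.atom("C", n - 1)
        n1 = self.atom("N", 0)
        blen = float(np.linalg.norm(n1 - c))
        ang_c = bond_angle(self.atom("CA", n - 1), c, n1)
        ang_n = bond_angle(c, n1, self.atom("CA", 0))
        omega = dihedral(self.atom("CA", n - 1), c, n1, self.atom("CA", 0))
        return (abs(blen - geom.c_n), abs(ang_c - geom.ca_c_n),
                abs(ang_n - geom.c_n_ca),
                abs(wrap_angle(omega - geom.closure_omega)))

    def is_closed(self, tol_bond=1e-4, tol_ang=1e-3) -> bool:
        db, dac, dan, dw = self.closure_residual()
        return db <= tol_bond and dac <= tol_ang and dan <= tol_ang \
            and dw <= tol_ang


def _place_dependent_atoms(seq: MacrocycleSequence, N, CA, C,
                           psi, geom: IdealGeometry,
                           prev_c=None):
    """Place O for every residue and H/CN where they exist.

    ``prev_c[i]`` must give the carbonyl-carbon position preceding residue
    i's nitrogen (the cyclic predecessor, or a virtual atom for an open
    chain's first residue).
    """
    n = len(seq)
    O = np.empty((n, 3))
    H = np.full((n, 3), np.nan)
    CN = np.full((n, 3), np.nan)
    for i, r in enumerate(seq):
        O[i] = place_atom(N[i], CA[i], C[i], geom.c_o, geom.ca_c_o,
                          psi[i] - 180.0)
        pc = prev_c[i]
        if pc is None:
            continue
        if r.has_nh:
            H[i] = place_atom(CA[i], pc, N[i], geom.n_h, geom.c_n_h, 180.0)
        elif r.n_methyl:
            CN[i] = place_atom(CA[i], pc, N[i], geom.n_cn, geom.c_n_cn, 180.0)
    return O, H, CN


def build_from_torsions(seq: MacrocycleSequence, torsions,
                        geom: IdealGeometry = IDEAL) -> Conformation:
    """Build Cartesian backbone coordinates from (phi, psi, omega).

    Sequential natural-extension placement with ideal geometry. No closure
    is enforced: the C(n)->N(1) gap may be open. The cut-crossing torsions
    (phi of residue 1, psi/omega of residue n) are realized against virtual
    extension atoms, so a torsion set that admits a closed ring rebuilds
    that ring exactly.
    """
    torsions = np.asarray(torsions, dtype=float)
    n = len(seq)
    if torsions.shape != (n, 3):
        raise ValueError(
            f"expected ({n}, 3) torsions, got {torsions.shape}")
    if not np.all(np.isfinite(torsions)):
        raise ValueError("non-finite torsion angles")
    phi, psi, omega = torsions[:, 0], torsions[:, 1], torsions[:, 2]

    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))
    # Seed frame: N1 at origin, CA1 on +x, C1 in the xy-plane.
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (geom.n_ca, 0.0, 0.0)
    a = np.deg2rad(geom.n_ca_c)
    C[0] = CA[0] + geom.ca_c * np.array([-np.cos(a), np.sin(a), 0.0])
    for i in range(n - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], geom.c_n, geom.ca_c_n,
                              psi[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], geom.n_ca, geom.c_n_ca,
                               omega[i])
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], geom.ca_c,
                              geom.n_ca_c, phi[i + 1])
    # Virtual predecessor carbonyl for residue 1 realizes phi[0]
    # (dihedral(C0, N1, CA1, C1) == dihedral(C1, CA1, N1, C0)).
    virtual_c0 = place_atom(C[0], CA[0], N[0], geom.c_n, geom.c_n_ca, phi[0])

    prev_c = [virtual_c0] + [C[i] for i in range(n - 1)]
    O, H, CN = _place_dependent_atoms(seq, N, CA, C, psi, geom, prev_c)
    coords = {"N": N, "CA": CA, "C": C, "O": O, "H": H, "CN": CN}
    t = np.column_stack([wrap_angle(phi), wrap_angle(psi), wrap_angle(omega)])
    return Conformation(seq, t, coords)


def measure_torsions(conf: Conformation) -> np.ndarray:
    """Measure per-residue (phi, psi, omega) from coordinates, cyclically.

    omega(i) is the dihedral CA(i)-C(i)-N(i+1)-CA(i+1); the last omega and
    the first phi are measured across the closure bond.
    """
    n = len(conf)
    for name in ("N", "CA", "C"):
        arr = conf.coords.get(name)
        if arr is None or not np.all(np.isfinite(arr)):
            raise ValueError(f"missing backbone atom coordinates: {name}")
    out = np.empty((n, 3))
    for i in range(n):
        out[i, 0] = dihedral(conf.atom("C", i - 1), conf.atom("N", i),
                             conf.atom("CA", i), conf.atom("C", i))
        out[i, 1] = dihedral(conf.atom("N", i), conf.atom("CA", i),
                             conf.atom("C", i), conf.atom("N", i + 1))
        out[i, 2] = dihedral(conf.atom("CA", i), conf.atom("C", i),
                             conf.atom("N", i + 1), conf.atom("CA", i + 1))
    return wrap_angle(out)


def thread_sequence(conf: Conformation,
                    seq: MacrocycleSequence) -> Conformation:
    """Place a new sequence on the conformation's backbone torsions.

    The backbone is rebuilt from the stored torsions with the new identities
    (which updates H/CN placement and the derived side-chain spheres).
    """
    if len(seq) != len(conf):
        raise ValueError("sequence length does not match backbone")
    return build_from_torsions(seq, conf.torsions)


def mirror(conf: Conformation) -> Conformation:
    """Mirror image: reflect coordinates, swap L<->D, negate torsions."""
    seq = conf.sequence.mirrored()
    coords = {}
    for name, arr in conf.coords.items():
        out = arr.copy()
        out[:, 0] *= -1.0  # reflect through the x=0 plane
        coords[name] = out
    t = conf.torsions.copy()
    t = wrap_angle(-t)
    return Conformation(seq, t, coords)


def cyclic_permute(conf: Conformation, k: int) -> Conformation:
    """Relabel residue i as residue i-k (mod n); coordinates unchanged."""
    n = len(conf)
    k %= n
    seq = conf.sequence.permuted(k)
    coords = {name: np.roll(arr, -k, axis=0)
              for name, arr in conf.coords.items()}
    t = np.roll(conf.torsions, -k, axis=0)
    return Conformation(seq, t, coords)
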