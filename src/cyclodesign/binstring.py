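"""Torsion-bin strings and canonicalization under cyclic/mirror symmetry.

Each residue of a macrocycle is assigned one of six torsion bins:

* ``A`` — right-handed helical region (phi < 0, trans following bond,
  psi inside the A interval),
* ``B`` — right-handed strand region (phi < 0, trans, psi outside A),
* ``X`` / ``Y`` — exact mirrors of A and B (phi > 0),
* ``O`` / ``Z`` — cis peptide bond between residue i and i+1, with
  phi < 0 (O) or phi > 0 (Z).

The per-residue characters concatenate into a cyclic bin string. Because
the starting residue of a cycle is arbitrary and both membrane
permeability and fold propensity are invariant to mirroring, two strings
name the same structural cluster when they match under circular
permutation and/or the mirror mapping A<->X, B<->Y, O<->Z. The canonical
form is the lexicographic minimum (A < B < O < X < Y < Z) over all
rotations of the string and of its mirror image; chain direction is never
reversed (a physical mirror does not reverse a peptide's N-to-C sense).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Conformation

__all__ = [
    "BinBoundaries", "assign_bin", "binstring", "mirror_string",
    "canonical_form", "cluster_designs_by_binstring",
]

ALPHABET = "ABOXYZ"
MIRROR_MAP = str.maketrans("ABOXYZ", "XYZABO")


@dataclass(frozen=True)
class BinBoundaries:
    """Configurable bin geometry (degrees)."""

    a_psi_min: float = -80.0    # A region: psi in (a_psi_min, a_psi_max]
    a_psi_max: float = 50.0
    cis_max_abs_omega: float = 90.0


DEFAULT_BOUNDS = BinBoundaries()


def assign_bin(phi: float, psi: float, omega_next: float,
               bounds: BinBoundaries = DEFAULT_BOUNDS) -> str:
    """Torsion bin of one residue; phi == 0 counts as negative."""
    cis = abs(omega_next) < bounds.cis_max_abs_omega
    if cis:
        return "O" if phi <= 0 else "Z"
    if phi <= 0:
        in_a = bounds.a_psi_min < psi <= bounds.a_psi_max
        return "A" if in_a else "B"
    in_x = bounds.a_psi_min < -psi <= bounds.a_psi_max
    return "X" if in_x else "Y"


def binstring(conf: Conformation,
              bounds: BinBoundaries = DEFAULT_BOUNDS) -> str:
    """Cyclic bin string of a conformation, one character per residue."""
    t = conf.torsions
    return "".join(assign_bin(t[i, 0], t[i, 1], t[i, 2], bounds)
                   for i in range(len(conf)))


def mirror_string(s: str) -> str:
    """Apply the mirror bin mapping A<->X, B<->Y, O<->Z."""
    return s.translate(MIRROR_MAP)


def _least_rotation(s: str) -> str:
    """Lexicographically least rotation (Booth's algorithm)."""
    ss = s + s
    n = len(s)
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k:k + n]


def canonical_form(s: str) -> str:
    """Canonical representative under rotations and mirror inversion."""
    if any(ch not in ALPHABET for ch in s):
        raise ValueError(f"bin string contains characters outside "
                         f"{ALPHABET!r}: {s!r}")
    return min(_least_rotation(s), _least_rotation(mirror_string(s)))


def cluster_designs_by_binstring(records) -> dict:
    """Group design records (or (key, string) pairs) by canonical form.

    Accepts objects with a ``conformation`` attribute, conformations, or
    raw strings; returns {canonical form: [records]} with insertion order
    preserved within groups.
    """
    groups: dict = {}
    for rec in records:
        if isinstance(rec, str):
            s = rec
        elif isinstance(rec, Conformation):
            s = binstring(rec)
        else:
            s = binstring(rec.conformation)
        groups.setdefault(canonical_form(s), []).append(rec)
    return groups
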