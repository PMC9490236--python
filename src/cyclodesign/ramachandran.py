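"""Surrogate Ramachandran-style torsion potentials and sampling regions.

The scoring terms ``rama_prepro`` and ``p_aa_pp`` are smooth pseudo-energy
surfaces built from a small set of quadratic wells per residue class; the
constants below are the single documented site for them. They are *not* a
reproduction of any published force field: they exist to give the design
and sampling machinery realistic qualitative behaviour (favourable
helical/strand basins, mirrored D surfaces, distinct pre-proline /
pre-N-methyl variants, restricted proline basins) at desk scale.

Surfaces for D-residues are exact mirrors of the L surfaces
(``E_D(phi, psi) = E_L(-phi, -psi)``), which makes every score term built
on them exactly mirror-invariant.

Units: degrees in, score units out. Each well is
``(phi0, psi0, sigma_phi, sigma_psi, depth)`` and contributes
``depth + ((dphi/sigma_phi)^2 + (dpsi/sigma_psi)^2)``; the surface is the
minimum over wells, clipped above at :data:`E_MAX`.
"""

from __future__ import annotations

import numpy as np

from .geometry import wrap_angle

__all__ = [
    "rama_energy",
    "rama_prepro_check",
    "p_aa_pp_energy",
    "sample_flat_symm",
    "FLAT_SYMM_L_REGIONS",
    "in_proline_bin",
]

E_MAX = 20.0

# Wells per residue class (L-handed reference; D is mirrored).
_WELLS = {
    # generic hydrophobic L-amino acid: alpha-helical + strand/PPII basins
    "generic": [(-63.0, -43.0, 35.0, 35.0, -2.0),
                (-120.0, 135.0, 40.0, 35.0, -2.0)],
    # residues preceding proline or an N-methylated residue: extended
    # conformations preferred, helical basin shallow
    "prepro": [(-120.0, 140.0, 40.0, 30.0, -2.0),
               (-63.0, -25.0, 25.0, 25.0, -0.5)],
    # proline: phi restricted near -63
    "pro": [(-63.0, -35.0, 15.0, 25.0, -2.0),
            (-63.0, 145.0, 15.0, 25.0, -2.0)],
    "pro_prepro": [(-63.0, 145.0, 15.0, 25.0, -2.0),
                   (-63.0, -25.0, 15.0, 20.0, -0.5)],
    # glycine: mirror-symmetric, shallow and permissive (glycine occupies
    # most of Ramachandran space)
    "gly": [(-63.0, -43.0, 65.0, 65.0, -1.5),
            (63.0, 43.0, 65.0, 65.0, -1.5),
            (-120.0, 135.0, 65.0, 60.0, -1.5),
            (120.0, -135.0, 65.0, 60.0, -1.5),
            (85.0, 0.0, 60.0, 65.0, -1.5),
            (-85.0, 0.0, 60.0, 65.0, -1.5)],
    # alpha-aminoisobutyric acid: tight helical basins of both hands
    "aib": [(-57.0, -47.0, 20.0, 20.0, -2.0),
            (57.0, 47.0, 20.0, 20.0, -2.0)],
}


def _class_of(aa: str, prepro: bool) -> str:
    if aa == "GLY":
        return "gly"
    if aa == "AIB":
        return "aib"
    if aa == "PRO":
        return "pro_prepro" if prepro else "pro"
    return "prepro" if prepro else "generic"


_WELL_ARRAYS = {k: np.array(v, dtype=float) for k, v in _WELLS.items()}


def _well_energy(wells: np.ndarray, phi: float, psi: float) -> float:
    dp = ((phi - wells[:, 0] + 180.0) % 360.0 - 180.0) / wells[:, 2]
    ds = ((psi - wells[:, 1] + 180.0) % 360.0 - 180.0) / wells[:, 3]
    return float(min(E_MAX, np.min(wells[:, 4] + dp * dp + ds * ds)))


def rama_energy(aa: str, chirality: str, phi: float, psi: float,
                prepro: bool = False) -> float:
    """Surrogate rama_prepro pseudo-energy for one residue.

    ``prepro`` selects the variant table used when the *next* residue in
    the cycle is proline or N-methylated. D-residues evaluate the mirrored
    L surface; achiral classes (GLY, AIB) have intrinsically symmetric
    wells.
    """
    wells = _WELL_ARRAYS.get(_class_of(aa, prepro))
    if wells is None:
        raise KeyError(f"no rama table for residue class {aa!r}")
    if chirality == "D":
        return _well_energy(wells, -phi, -psi)
    return _well_energy(wells, phi, psi)


def rama_prepro_check(aa: str, chirality: str, phi: float, psi: float,
                      cutoff: float, prepro: bool = False) -> bool:
    """True iff the rama pseudo-energy is at or below *cutoff*."""
    return rama_energy(aa, chirality, phi, psi, prepro) <= cutoff


# Small per-identity backbone-propensity offsets for p_aa_pp.
_P_AA_OFFSET = {"ALA": 0.00, "VAL": 0.10, "LEU": 0.05, "ILE": 0.10,
                "PHE": 0.15, "PRO": -0.10, "GLY": 0.20, "AIB": 0.30}


def p_aa_pp_energy(aa: str, chirality: str, phi: float, psi: float) -> float:
    """Surrogate amino-acid-given-backbone propensity term."""
    base = rama_energy(aa, chirality, phi, psi, prepro=False)
    return 0.2 * base + _P_AA_OFFSET[aa]


# Flat-bottom mirror-symmetric sampling regions (the "flat_symm" table):
# uniform over the union of generously bounded L-favourable rectangles and
# their mirror images. Each rectangle is (phi_lo, phi_hi, psi_lo, psi_hi).
FLAT_SYMM_L_REGIONS = [
    (-160.0, -45.0, -80.0, 50.0),    # helical (bin A)
    (-180.0, -45.0, 50.0, 180.0),    # strand / PPII (bin B)
]


def sample_flat_symm(rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw (phi, psi) uniformly from the symmetric flat-bottom region.

    The region is the union of the L rectangles and their point mirrors;
    rectangles are weighted by area, so the draw is uniform over the union.
    """
    rects = []
    for lo, hi, plo, phi_ in FLAT_SYMM_L_REGIONS:
        rects.append((lo, hi, plo, phi_))
        rects.append((-hi, -lo, -phi_, -plo))  # mirror image
    areas = np.array([(r[1] - r[0]) * (r[3] - r[2]) for r in rects])
    probs = areas / areas.sum()
    out = np.empty((size, 2))
    choice = rng.choice(len(rects), size=size, p=probs)
    for k in range(size):
        lo, hi, plo, phi_ = rects[choice[k]]
        out[k, 0] = rng.uniform(lo, hi)
        out[k, 1] = rng.uniform(plo, phi_)
    return wrap_angle(out)


# Proline-compatible phi/psi bin (L-handed reference; D mirrored):
# phi near -63 with either an alpha-like or a PPII-like psi.
_PRO_BIN_L = [(-90.0, -40.0, -75.0, 10.0),
              (-90.0, -40.0, 110.0, 180.0)]


def in_proline_bin(phi: float, psi: float, chirality: str = "L") -> bool:
    """True when (phi, psi) is compatible with (D-)proline substitution."""
    if chirality == "D":
        phi, psi = -phi, -psi
    for lo, hi, plo, phi_ in _PRO_BIN_L:
        if lo <= phi <= hi and plo <= psi <= phi_:
            return True
    return False
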