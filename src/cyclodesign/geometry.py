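"""Ideal backbone geometry and internal-coordinate primitives.

All bond lengths are in Angstrom, all angles in degrees. The single source
of truth for the idealized peptide geometry used throughout the package is
:data:`IDEAL`. The closure-bond geometry (the C(n)->N(1) bond of the
macrocycle) uses the same amide constants, so a correctly solved ring is
geometrically indistinguishable from a mid-chain peptide bond.

The non-amide constants are standard small-molecule amide geometry in the
Engh/Huber spirit; they are configuration constants of this package, chosen
once and documented here, not fitted quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IdealGeometry",
    "IDEAL",
    "place_atom",
    "dihedral",
    "bond_angle",
    "wrap_angle",
]


@dataclass(frozen=True)
class IdealGeometry:
    """Idealized backbone internal coordinates (Angstrom / degrees)."""

    n_ca: float = 1.458          # N-CA bond
    ca_c: float = 1.525          # CA-C bond
    c_n: float = 1.328685        # C-N amide bond (also the closure bond)
    c_o: float = 1.231           # C=O
    n_h: float = 1.010           # amide N-H
    n_cn: float = 1.455          # N-CH3 (N-methyl) bond

    n_ca_c: float = 111.2        # backbone angle at CA
    ca_c_n: float = 116.199993   # angle at C  (closure "angle2")
    c_n_ca: float = 121.69997    # angle at N  (closure "angle1")
    ca_c_o: float = 120.5        # carbonyl placement angle
    c_n_h: float = 119.3         # amide H placement angle
    c_n_cn: float = 119.3        # N-methyl carbon placement angle

    ca_cb: float = 1.530         # CA-CB for the single side-chain sphere
    n_ca_cb: float = 110.5
    # Torsion C(prev)-N-CA-CB relative to phi; +122.6 puts CB on the L side.
    cb_branch: float = 122.6

    closure_omega: float = 180.0


IDEAL = IdealGeometry()


def wrap_angle(a):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return w if w.ndim else float(w)


def place_atom(a, b, c, bond: float, angle: float,
               torsion: float) -> np.ndarray:
    """Place atom D from reference atoms A, B, C (natural extension frame).

    D is positioned so that ``|CD| = bond``, the angle B-C-D equals *angle*
    and the dihedral A-B-C-D equals *torsion* (degrees).
    """
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    ib = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * ib, bcy * ib, bcz * ib
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-12:
        # colinear reference; pick an arbitrary perpendicular
        hx, hy, hz = (0.0, 1.0, 0.0) if abs(bcx) > 0.9 else (1.0, 0.0, 0.0)
        nx = hy * bcz - hz * bcy
        ny = hz * bcx - hx * bcz
        nz = hx * bcy - hy * bcx
        nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(ang)
    d1 = bond * math.sin(ang) * math.cos(tor)
    d2 = bond * math.sin(ang) * math.sin(tor)
    return np.array([c[0] + d0 * bcx + d1 * mx + d2 * nx,
                     c[1] + d0 * bcy + d1 * my + d2 * ny,
                     c[2] + d0 * bcz + d1 * mz + d2 * nz])


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0x, b0y, b0z = p0[0] - p1[0], p0[1] - p1[1], p0[2] - p1[2]
    b1x, b1y, b1z = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    b2x, b2y, b2z = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    ib = 1.0 / math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    b1x, b1y, b1z = b1x * ib, b1y * ib, b1z * ib
    d0 = b0x * b1x + b0y * b1y + b0z * b1z
    vx, vy, vz = b0x - d0 * b1x, b0y - d0 * b1y, b0z - d0 * b1z
    d2 = b2x * b1x + b2y * b1y + b2z * b1z
    wx, wy, wz = b2x - d2 * b1x, b2y - d2 * b1y, b2z - d2 * b1z
    x = vx * wx + vy * wy + vz * wz
    cx = b1y * vz - b1z * vy
    cy = b1z * vx - b1x * vz
    cz = b1x * vy - b1y * vx
    y = cx * wx + cy * wy + cz * wz
    return math.degrees(math.atan2(y, x))


def bond_angle(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    ux, uy, uz = p0[0] - p1[0], p0[1] - p1[1], p0[2] - p1[2]
    vx, vy, vz = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    c = ((ux * vx + uy * vy + uz * vz) /
         math.sqrt((ux * ux + uy * uy + uz * uz) *
                   (vx * vx + vy * vy + vz * vz)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))
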