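"""PDB input/output for macrocycle conformations (single chain).

D-amino acids are written with their chemical-component-dictionary names
(DAL, DPH, DIL, DLE, DPR, DVA); the N-methyl carbon is written as atom
``CN`` bonded to the backbone nitrogen, and its presence flags the residue
as N-methylated on read. gemmi does the actual format work.
"""

from __future__ import annotations

import numpy as np
import gemmi

from .model import (Conformation, MacrocycleSequence, ResidueSpec,
                    PDB_D_NAMES_INV, ACHIRAL, L_ALPHABET, measure_torsions)

__all__ = ["read_pdb", "write_pdb"]

_BACKBONE = ("N", "CA", "C", "O")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "H": "H", "CN": "C"}


def write_pdb(conf: Conformation, path) -> None:
    """Write a conformation as single-chain PDB ATOM records."""
    st = gemmi.Structure()
    st.name = "macrocycle"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, r in enumerate(conf.sequence):
        res = gemmi.Residue()
        res.name = r.pdb_name
        res.seqid = gemmi.SeqId(i + 1, " ")
        for name in ("N", "CA", "C", "O", "H", "CN"):
            if not conf.has_atom(name, i):
                continue
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(_ELEMENTS[name])
            x, y, z = conf.atom(name, i)
            at.pos = gemmi.Position(x, y, z)
            at.occ = 1.0
            at.b_iso = 0.0
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def read_pdb(path) -> Conformation:
    """Read a single-chain macrocycle PDB file."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError("no model in PDB file")
    model = st[0]
    chains = [ch for ch in model if len(ch) > 0]
    if len(chains) != 1:
        raise ValueError(f"expected one peptide chain, found {len(chains)}")
    chain = chains[0]
    specs = []
    rows = {name: [] for name in ("N", "CA", "C", "O", "H", "CN")}
    for idx, res in enumerate(chain):
        name = res.name.strip().upper()
        if name in PDB_D_NAMES_INV:
            aa, chir = PDB_D_NAMES_INV[name], "D"
        elif name in ACHIRAL:
            aa, chir = name, "achiral"
        elif name in L_ALPHABET:
            aa, chir = name, "L"
        else:
            raise ValueError(f"unknown residue name {name!r} at residue "
                             f"{idx + 1}")
        atom_pos = {}
        for at in res:
            atom_pos[at.name.strip().upper()] = np.array(
                [at.pos.x, at.pos.y, at.pos.z])
        for bb in _BACKBONE:
            if bb not in atom_pos:
                raise ValueError(
                    f"residue {idx + 1} ({name}) missing backbone atom {bb}")
        n_methyl = "CN" in atom_pos
        specs.append(ResidueSpec(aa, chir, n_methyl, idx + 1))
        for key in rows:
            rows[key].append(atom_pos.get(key, np.full(3, np.nan)))
    seq = MacrocycleSequence(specs)
    coords = {k: np.array(v) for k, v in rows.items()}
    conf = Conformation(seq, np.zeros((len(seq), 3)), coords)
    conf.torsions = measure_torsions(conf)
    return conf
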