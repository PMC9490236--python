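# cyclodesign

Desk-scale computational design of membrane-permeable peptide macrocycles.

Head-to-tail cyclized peptides of 6–12 residues can cross lipid membranes
passively — but only when every backbone amide N–H is either hydrogen-bonded
internally or removed altogether (proline, N-methylation). `cyclodesign`
implements the complete in-silico pipeline around that principle, for
structural bioinformaticians and peptide designers who want a transparent,
fully testable implementation they can run on a laptop:

* **Kinematic closure** — analytic closure of N-to-C cyclic backbones.
  All but six torsions (φ/ψ of three *pivot* residues) are drawn from a
  flat-bottom mirror-symmetric Ramachandran region; the remaining six are
  solved exactly so the closure bond has ideal amide geometry
  (C–N 1.328685 Å, C–N–CA 121.69997°, CA–C–N 116.199993°, ω 180°).
  The tripeptide closure is reduced to three biquadratic spin equations on
  the pivot-CA triangle and solved through numeric Sylvester resultants
  (a degree-16 polynomial), then Newton-polished.
* **Sequence design with N-methylation** — simulated-annealing design over
  a hydrophobic alphabet (ALA/VAL/LEU/ILE/PHE/PRO and D-counterparts),
  D-amino acids only at positive φ, with tabulated amino-acid composition
  penalties; three design rounds with remediation of unsatisfied NH donors
  in between (proline where the φ/ψ bin allows it, otherwise N-methylation),
  the first round with 5× upweighted backbone H-bond terms.
* **Energy landscapes** — structure prediction for a fixed sequence,
  energy-vs-RMSD funnels, ΔE gaps, and greedy energy-based clustering with
  LE_0/LE_1/… labels; backbone RMSD over N, CA, C, O (and the N-methyl CN)
  with optional cyclic-permutation and mirror minimization.
* **Torsion-bin strings** — per-residue bins A/B/X/Y/O/Z and canonical
  forms under circular permutation and mirror inversion (A↔X, B↔Y, O↔Z),
  e.g. `XYABOX → AABXYZ`, for nondegenerate structural clustering.
* **Chameleonic (multistate) design** — a genetic algorithm that threads
  sequences onto two backbone states and maximizes the fitness
  `−5·|eA − eB| − (eA − eB)` under per-state (<10) and gap (<6) energy
  ceilings, plus a mutation scan that converts single-state designs into
  cis/trans switch candidates.
* **PAMPA permeability** — apparent permeability from donor/acceptor
  concentrations, `Ce = (CD·VD + CA·VA)/(VD + VA)` and
  `Papp = −ln(1 − CA/Ce) / [A·(1/VD + 1/VA)·t]` (cm/s), with the
  10⁻⁷ / 10⁻⁶ / 10⁻⁵ cm/s classification bars.

Scoring uses a documented *surrogate* energy function with the standard
term roles (fa_rep, fa_atr, hbond_sr_bb, hbond_lr_bb, rama_prepro,
p_aa_pp, omega, chainbreak, aa_composition); it is not a reimplementation
of any published force field. All constants live in
`src/cyclodesign/energetics.py` and `src/cyclodesign/ramachandran.py`;
see `docs/methods.md`.

## Worked example

```python
import numpy as np
from cyclodesign import sample_cyclic_backbones, score, count_internal_hbonds
from cyclodesign.model import MacrocycleSequence
from cyclodesign.design import run_design_protocol

# 1. sample closed cyclo-(Gly)8 backbones (analytic closure + filters)
backbones = sample_cyclic_backbones(MacrocycleSequence.polyglycine(8),
                                    n_attempts=800, rng_seed=5)
print(len(backbones), "accepted backbones")

# 2. design one of them: three rounds + NH remediation + minimization
rec = run_design_protocol(backbones[1], rng_seed=1)
print(rec.sequence)
print("hbonds:", rec.hbond_count, "n-methyls:", rec.n_methyl_count,
      "unsatisfied:", rec.unsatisfied, "passed:", rec.passed)
```

Output:

```
13 accepted backbones
cyclo-[ALA-PRO-D-PRO-ALA-D-ALA-D-PHE(NMe)-D-PHE(NMe)-ALA]
hbonds: 4 n-methyls: 2 unsatisfied: set() passed: True
```

Thirteen of 800 closure attempts survived the bump, Ramachandran and
internal-H-bond filters (2 bonds required at length 8). The design run
placed D-residues at the positive-φ positions, used prolines at
proline-compatible unsatisfied positions and N-methylated the remaining
two exposed donors; the final record passes all four design filters — no
exposed NH, ≤5 N-methyls, the length's H-bond minimum, no oversaturated
carbonyl. (Not every backbone designs successfully: `backbones[0]` under
the same seed ends with two donors still exposed and is flagged
`passed: False`.)

The same pipeline is scriptable from the shell:

```bash
cyclodesign sample-backbones --length 8 --attempts 800 --seed 5 --out bb/
cyclodesign design --length 8 --n-backbones 3 --seed 1 --out designs/
cyclodesign binstring --in designs/design_0000.pdb
cyclodesign papp --in measurements.tsv
cyclodesign rmsd a.pdb b.pdb --mirror --cyclic
```

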