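# Methods

This note documents the models, numerical choices and limitations of
`cyclodesign`. Everything here is implemented and exercised by the test
suite; no empirical claim is made beyond what the tests and
`scripts/acceptance.py` compute.

## Backbone model and geometry

A macrocycle conformation is a cyclic sequence plus per-residue (φ, ψ, ω)
torsions and Cartesian coordinates for N, CA, C, O, the amide H where an
NH exists, and a single CN pseudo-atom for the N-methyl carbon. Torsions
are in degrees on (−180, 180]; ω(i) belongs to the bond i→i+1, cyclically,
so the last ω spans the closure bond C(n)→N(1).

Chains are built by sequential natural-extension (NeRF) placement with a
single idealized geometry table (`geometry.IdealGeometry`): N–CA 1.458 Å,
CA–C 1.525 Å, C=O 1.231 Å, N–H 1.01 Å, N–CN 1.455 Å; angles N–CA–C 111.2°,
CA–C–N 116.199993°, C–N–CA 121.69997°. The closure bond uses the same
amide constants (C–N 1.328685 Å), which makes a correctly closed ring
geometrically indistinguishable from a mid-chain bond — and, downstream,
makes the chainbreak score exactly invariant under cyclic permutation.
The non-amide constants are standard Engh–Huber-style values chosen once
here; they are this package's configuration, not a published table.

The three torsions that cross the cut (φ₁, ψₙ, ωₙ) are realized against
virtual extension atoms when building, and measured across the actual
closure bond. Build→measure round trips are therefore exact (≤10⁻⁶°) for
closed rings and for all non-cut torsions of open chains.

Side chains are modelled as a single sphere at the CB position, with radius
by residue bulk (ALA 1.9 … PHE 2.6 Å); glycine has none. L and D residues
branch to opposite sides; the achiral AIB sphere sits on the
mirror-symmetric bisector of the two enantiomeric CB directions so that
mirror invariance of the energy is exact. The freely rotating N-methyl
group is collapsed to the single CN pseudo-atom.

## Surrogate energy function

The score mirrors the term *roles* of the design and closure-selection
functions used for macrocycle work, with this package's own documented
constants (all in `energetics.py` / `ramachandran.py`). Energies are in
arbitrary "score units", treated as kcal/mol-equivalent wherever a
threshold is quoted in kcal/mol.

* `fa_rep` / `fa_atr`: split 12-6 Lennard-Jones (ε = 0.1, cutoff 6 Å) over
  backbone heavy atoms + CB spheres; pairs closer than four covalent bonds
  are excluded (bond topology includes the closure bond and the proline
  N–CB ring closure).
* `hbond_sr_bb` / `hbond_lr_bb`: sum of detected backbone–backbone H-bond
  energies, split at cyclic separation 4. The H-bond energy is
  `−1.34 · exp(−(d−1.9)²/(2·0.45²)) · ((1−cos θ_NHO)/2)² · ((1−cos θ_HOC)/2)`,
  ≈ −1 at ideal geometry so the −0.25 reporting cutoff is meaningful; it
  is monotone in the H···O distance beyond the optimum, permissive to
  DSSP-grade distortion (hard cap 3.6 Å), and donors within cyclic
  separation 2 of the acceptor are never counted. Donors are residues
  with an amide H — never proline or N-methylated positions.
* `rama_prepro` / `p_aa_pp`: smooth pseudo-energies built from a few
  quadratic wells per residue class (generic, pre-proline/pre-N-methyl,
  proline, glycine, AIB), clipped at +20. D surfaces are exact mirrors of
  L; glycine's wells are wide (σ ≈ 60–65°) to reflect its permissive map.
  The pre-proline variant applies when the next residue is proline *or*
  N-methylated.
* `omega`: harmonic to the nearest of {0°, 180°}, 0.005 per deg².
* `chainbreak`: per-bond harmonic deviations of bond length (500 /Ų),
  the two flanking angles (0.1 /deg²) and the realized-vs-stored bond
  dihedral (0.1 /deg²), summed over *every* peptide bond. For
  torsion-built chains all mid-chain contributions are exactly zero, so
  the term equals the closure-gap penalty while remaining invariant under
  cyclic permutation and mirroring. The dihedral part exists because
  torsion-space minimization could otherwise keep the stored ω planar
  while the actual cut dihedral drifted.
* `aa_composition`: tabulated per-class penalties (below).

Weight sets: `standard`; `closure_selection` (fa_rep 0.1, fa_atr 0.2,
hbond_sr/lr_bb 2.0, rama_prepro 0.45, omega 0.4, p_aa_pp 0.6) used to rank
closure solutions; `hbond_upweighted` (backbone H-bond weights ×5) used in
design round 1.

Every term is invariant under mirroring and cyclic permutation to ≤10⁻⁹
relative — verified exhaustively in the tests.

## Kinematic closure

With all non-pivot torsions fixed, the three chain segments between
consecutive pivot CA atoms are rigid. Their end-to-end lengths fix a
triangle; each segment retains one spin about its triangle edge, and the
N–CA–C bond angle at each pivot gives one constraint coupling two
consecutive spins. In half-tangent variables each constraint is
biquadratic; eliminating two of the three via exact bivariate Sylvester
resultants (coefficient arrays convolved numerically) leaves a degree-16
polynomial whose roots are recovered from a Chebyshev fit of the 6×6
Sylvester determinant sampled at 41 nodes, then back-substituted and
Newton-polished to ‖g‖ < 10⁻¹². Two passes with different spin-reference
offsets make the tan(σ/2) pole non-generic. Solutions are deduplicated in
spin space, rebuilt from torsions, and validated against the closure
geometry (1e-4 Å / 1e-3°). The erase-and-resolve self-test (erase a random
pivot triple of a known closed ring, re-solve, require the original
torsions among the solutions to 10⁻³°) passes for 100 rings per length
6–12.

Sampling: the anchor residue is uniform; pivots are spread roughly equally
around the cycle excluding the anchor. Non-pivot φ/ψ are drawn uniformly
from the flat-bottom mirror-symmetric region — the union of a helical
rectangle (φ ∈ [−160, −45], ψ ∈ [−80, 50]) and a strand rectangle
(φ ∈ [−180, −45], ψ ∈ [50, 180]) with their point mirrors, area-weighted.
ω is 180° everywhere by default, with optional cis sampling only at
proline/N-methyl positions. Accepted solutions must pass the pivot
Ramachandran check (cutoff 2 score units), a bump check (no backbone
heavy-atom pair beyond two bonds closer than 2.6 Å) and the
length-dependent internal H-bond minimum — 1 for 6–7 residues, 2 for 8–9,
3 for ≥10 (a flat minimum of 2 is available as an alternative policy);
the lowest-energy surviving solution per attempt (closure-selection
weights) is kept. Under these unbiased draws the acceptance rate is
realistically small (≈2% at length 6 down to ≈0.1–0.3% at lengths 10–12);
production-scale work simply raises the attempt count.

## Design protocol

Per backbone: positions with φ > 0 may only take D identities, φ ≤ 0 only
L (φ = 0 ties to L); alphabets are hydrophobic-only (ALA, VAL, LEU, PHE,
ILE, PRO per hand). Design is simulated annealing over per-position
identities (geometric cooling 4.0 → 0.05, ~10 sweeps), re-scoring the
threaded structure per move; N-methyl flags are preserved (proline is
excluded at methylated positions). Rounds 2–3 add 2.0 score units per
unsatisfied NH to the objective so a later round cannot costlessly undo
earlier remediation. Between rounds, every unsatisfied donor becomes
(D-)proline when its φ/ψ lies in the proline-compatible bin
(φ ∈ [−90, −40] with ψ ∈ [−75, 10] or [110, 180], mirrored for D) and its
N-methylated variant otherwise. Round 1 uses `hbond_upweighted`; the last
round ends with torsion-space minimization (chainbreak active). Final
filters: zero unsatisfied NH, ≤5 N-methyls, the length's H-bond minimum,
and no carbonyl accepting more than 2 H-bonds (oversaturation;
per-acceptor maximum configurable). All verdicts are pure functions of
the stored conformation and re-verify from raw coordinates.

Composition constraints follow the tabulated form: per class (e.g. PHE +
D-PHE) an absolute target, penalties over deltas −2…+2 (`0 0 0 5 25`),
constant extrapolation below the range and quadratic growth
`p_end·(over+1)²` above it (the above-range form is this package's
documented continuation; only the tabulated range is prescribed).

## Landscapes, RMSD, clustering

Backbone RMSD is least-squares proper superposition (SVD Kabsch with
determinant correction, residuals computed explicitly) over N, CA, C, O
plus CN where both structures carry it; flags allow minimization over
cyclic permutations and/or the explicit mirror image. Minimization is
L-BFGS-B over all torsions with central-difference gradients (forward
differences bias the two enantiomers differently and break the
mirror-equivariance of descent); the best-visited conformation is
returned, so energy never increases. Minimized rings stay closed to about
0.01 Å / 1° / ≤10° (cut dihedral).

`predict_landscape` samples alternative closed conformations of the fixed
sequence (no design), minimizes and scores each, and reports energy vs
RMSD to the design model; the design's own local minimum is always
included and marked. ΔE is the lowest energy among points with RMSD > 2 Å
minus the lowest with RMSD ≤ 2 Å (the 2 Å split is a documented choice).
Clustering is greedy leader clustering of the n lowest-energy structures
(default 250, cutoff 1.0 Å — both configurable, neither printed in the
source material): repeatedly take the lowest-energy unassigned structure
as a center and absorb everything within the cutoff; labels LE_0, LE_1, …
follow center energy rank, with index tie-breaks for determinism.
Cluster minima closer than 5 score units are reported as isoenergetic
pairs, annotated as cis/trans switches when their ω signatures differ at
a bond preceding a proline or N-methylated residue.

## Torsion-bin strings

Per residue: cis (|ω_next| < 90°) overrides to O (φ ≤ 0) or Z (φ > 0);
trans residues with φ ≤ 0 are A when ψ ∈ (−80, 50] else B; positive-φ
residues mirror to X/Y. The A/B boundary and the cis threshold are
configurable (`BinBoundaries`). Canonical form is the lexicographic
minimum (A<B<O<X<Y<Z) over all rotations of the string and of its
mirror-mapped image (A↔X, B↔Y, O↔Z), computed with Booth's
least-rotation algorithm; string reversal is *not* in the group because a
physical mirror does not reverse chain direction. The implementation is
checked against brute-force enumeration of all ≤24 transforms.

## Multistate GA

Variants are threaded onto both backbone states (identity swap, brief
relax, standard score), filtered to eA, eB < 10 and |eA − eB| < 6, and
ranked by fitness `−5·|eA−eB| − (eA−eB)`, which is ≤ 0 with equality iff
eA = eB (−4·gap when eA < eB, −6·gap when eA > eB) — so "best" means
maximal fitness, with ties broken by lower eA+eB then lexicographic
sequence. Each generation keeps the best survivors and adds one point
mutant per survivor; mutations preserve chirality and N-methylation
patterns. Proposals avoid already-evaluated sequences and may walk up to
three successive point mutations when a survivor's single-mutation
neighborhood is exhausted — at desk scale this keeps the search ergodic
instead of re-proposing known sequences. Desk-scale defaults are
population 60 / survivors 30 / 50 generations; the full-scale values
(1000/500/1000) are available as `PAPER_SCALE_GA`. The energy ceiling
applies to the total per backbone (whether it should be per-residue is
not specified; total is used and configurable). The initial population
carries 1–3 random point mutations per variant.

`switch_scan` mutates every position × allowed identity, relaxes each
mutant, predicts a reduced landscape and reports mutants with a second
cluster inside the isoenergetic threshold.

## PAMPA

`Ce = (CD·VD + CA·VA)/(VD+VA)`;
`Papp = −ln(1 − CA/Ce) / [A·(1/VD + 1/VA)·t]` in cm/s — the single
denominator grouping is fixed by dimensional analysis
(cm⁻² · cm⁻³·… · s → s/cm). Default volumes VD = 0.300, VA = 0.250 cm³;
the filter area has no default and must be supplied. Classification:
≥10⁻⁷ permeable, ≥10⁻⁶ significant, ≥10⁻⁵ high, boundaries inclusive
upward. No membrane-retention correction is applied. Replicate tables get
per-id mean ± SD.

## What the synthetic fixtures do and do not show

All test structures are generated by the package itself (closed
polyglycine rings from seeded sampling; a two-state pair differing by one
cis/trans flip at an N-methylated position; hand-built synthetic
H-bond-acceptor geometries, labelled synthetic in their docstrings). They
exercise the geometry, symmetry and bookkeeping contracts exhaustively,
but they cannot show that the surrogate energy ranks real sequences the
way a full-atom force field would, nor that designs passing the filters
are actually membrane-permeable — those claims require the excluded
experimental machinery (synthesis, PAMPA/Caco-2 measurements, crystal and
NMR structures).

## Problem sizes

The shipped tests run at desk scale by design: landscape predictions use
tens of samples, the GA oracle uses a 4-position × 3-letter toy (81
sequences), closure self-consistency uses 100 rings per length, and the
design-protocol contract samples backbones with fixed attempt budgets per
length (1200–2500), keeping at most 20 per length — at the faithful
H-bond minima, long macrocycles accept well under 1% of unbiased
attempts, so their samples are necessarily smaller. Production use simply
raises `n_attempts`, `n_samples` and the GA parameters.

## Known limitations

* The surrogate energy has no solvation, electrostatics or rotamer
  detail; side chains are spheres. Relative rankings within a backbone
  are meaningful, absolute values are not transferable.
* Only backbone (head-to-tail) cyclization is supported — no disulfides
  or side-chain bridges.
* N-methyl hydrogens are not modelled; CN is a pseudo-atom.
* The minimizer is a local torsion-space descent; "Cartesian
  minimization" is approximated by torsion moves with the chainbreak
  penalty active.
* φ = 0 ties (bin assignment, chirality alphabets) resolve to the
  negative-φ branch, deterministically.
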