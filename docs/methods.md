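# Methods

## The quantity being surveyed

Backbone amide proton chemical shifts are compared against per-residue-type
reference statistics as a Z score, `Z = (δ − δ̄_res) / σ_res`. No
secondary-structure conditioning is applied: the reference is the archive
mean and standard deviation for the residue type alone. Negative Z means
the proton resonates upfield of the mean (more shielded), positive Z
downfield. The package ships a pinned CSV snapshot of BMRB-style
statistics (`aroshift/data/bmrb_amide_stats.csv`, one row per amide-bearing
residue type; proline has no backbone amide H and is absent). The snapshot
is versioned deliberately: live statistics pages drift, and reproducible Z
scores require a fixed table. Any CSV with the same three columns can be
substituted at the API or CLI level.

## Amide-to-ring geometry

For each amide proton the survey records the distance `r` to the centroid
of the nearest aromatic ring and the azimuth `θ` between the ring-plane
normal and the proton→centroid vector.

- **Ring definitions.** Phe/Tyr: the six-membered ring (CG, CD1, CD2, CE1,
  CE2, CZ). His: the imidazole five-ring (CG, ND1, CD2, CE1, NE2). Trp
  contributes *two independent candidates* — the pyrrole five-ring (CG,
  CD1, CD2, NE1, CE2) and the benzene six-ring (CD2, CE2, CE3, CZ2, CZ3,
  CH2). The indole is never collapsed to a single union centroid; whichever
  ring is closer wins. Incomplete rings (missing atoms in any model) are
  skipped with a log message rather than silently mis-centred.
- **Centroid and normal.** The centroid is the unweighted mean of the ring
  atom coordinates. The normal is the cross product of the centre→first-atom
  and centre→second-atom vectors; its sign is arbitrary, so the azimuth is
  folded to [0°, 90°] via `θ = arccos(|v·n|/‖v‖)`. Folding makes every
  downstream statistic invariant to ring-atom ordering.
- **Ensemble averaging.** Both `r` and `θ` are means of per-model values
  over the deposited ensemble, and the nearest ring is the one minimising
  the *mean* distance (ties broken lexicographically by chain, residue,
  ring label). Averaging the azimuth the same way as the distance is a
  design choice — computing θ at a single representative model would be the
  main alternative; the ensemble mean degrades gracefully to the per-model
  value for single-model entries and does not privilege model 1.
- **Amide protons.** Deposited H/HN/H1 atoms are used as-is. When a model
  lacks amide hydrogens, H is reconstructed 1.01 Å from N in the
  C(prev)–N–CA plane, opposite the bisector of the two bond directions —
  the standard trigonal placement. An N-terminal residue with neither a
  deposited H nor a preceding carbonyl is skipped, not fatal.

## Entry eligibility

The survey is defined for single-protein entries: exactly one polypeptide
entity, one chain instance, no non-water heteroentities. Anything else is
excluded with a machine-readable reason (`nucleic_acid`, `oligomer`,
`complex`, `ligand`, or `unparseable` when entity records are missing or
unreadable). Homo-oligomer vs. heterocomplex is decided by comparing
polymer sequences. Waters never count as ligands.

## Joining shifts to structures

Records join on sequence number with residue-type agreement required;
mismatches are dropped and logged. Chain matching falls back to the single
structure chain when the shift file uses a different chain labelling
convention (entity assembly IDs vs. author asym IDs), which is the common
case for the single-chain entries the survey admits. When a deposition
carries several assigned-shift lists, the first is used and the event
logged — a deterministic rule where no principled choice exists.

## Outlier classification

Amides are classified upfield (Z ≤ −t), downfield (Z ≥ +t) or normal, with
t = 2 by default. The printed class boundaries overlap at |Z| = t; here
"normal" is the open interval (−t, t) so the partition is disjoint. Azimuth
histograms of outliers use |Z| > 3 within 8 Å of a ring, binned at 10°
(all configurable).

## NOE restraint cross-validation

Distance restraints are parsed from NMR-STAR general-distance-constraint
loops; rows sharing a constraint ID form one (possibly ambiguous) record
with all member selections retained. The save frame's declared constraint
type distinguishes NOE lists from plain "distance" lists; both are
analysed, since NOEs are frequently filed under the latter. Three
conformity filters are applied, each a literal rule:

1. an upper bound must be present (a lower bound alone is not an NOE);
2. the upper bound must be ≤ 6.0 Å (the boundary itself is kept — the
   exclusion is for bounds *greater than* 6 Å, which are inconsistent with
   NOE observability);
3. the member selections must span at most two distinct residues (a
   two-proton restraint is never "ambiguous" by this rule, however many
   member rows express it).

A surviving record links an amide to an aromatic residue when one member
resolves to a backbone amide H and another to a ring proton on a different
residue. Pseudoatoms (QD, QE, HD*, …) expand through a fixed per-residue
table to ring protons only; unknown pseudoatom names cause the record to
be skipped rather than guessed, because naming in archival restraint data
is too inconsistent to interpolate safely. Pairs aggregate restraint
counts. The restrained-proportion-vs-Z table bins Z to the nearest integer
and counts denominators only over entries that have at least one
amide–aromatic restraint at all; empty bins are absent, not zero.

## The dipole ring-current model

The perturbation is `Δδ = iB · (1 − 3 cos²θ)/r³` with one effective
constant iB (ppm·Å³) per ring. The geometric factor vanishes at the magic
angle arccos(1/√3) ≈ 54.74°, is negative (upfield) inside the axial cone
and positive (downfield) in the equatorial belt, with exactly twice the
axial magnitude at equal r.

No constants are inherited from quantum-mechanical or current-loop
parameterisations; the defaults are calibrated to two in-model anchors:
Phe/Tyr iB = 20.25 ppm·Å³ reproduces a 1.5 ppm upfield shift 3 Å above the
ring on axis, His iB = 19.65 ppm·Å³ reproduces a 0.5 ppm downfield shift
3.4 Å out in the ring plane, and Trp rings default to 1.3× the Phe value
(both Trp rings share it). All are configuration, not physics: the point
of the dipole model here is the *geometry* of the shielding/deshielding
demarcation, not quantitative shift prediction. Note the full ring-current
theories give in-plane deshielding at 3 Å that a pure dipole cannot
reproduce simultaneously with the axial anchor (the dipole fixes the
in-plane magnitude at half the axial one), so in-plane literature values
should not be used to validate this model. Geometries closer than 3 Å on
axis or 5 Å in plane are outside the dipole approximation's quantitative
domain and trigger a warning, never an error.

## The Lennard-Jones scan

A rigid idealized alanine is placed with its amide N on the ring normal of
a rigid idealized phenylalanine, H pointing at the ring centroid, and the
inter-residue 12-6 energy `ε[(Rmin/r)¹² − 2(Rmin/r)⁶]` is summed over all
atom pairs while the N-to-centroid distance is scanned (default 2.5–8.0 Å
in 0.01 Å steps). Because both residues are rigid, subtracting the
isolated-residue energies from the complex energy cancels every
intra-residue term exactly, so the inter-residue pair sum *is* the
interaction energy — this algebraic identity doubles as an internal test
oracle. Only the van der Waals term is computed; no electrostatics.

Parameters are the AMBER parm99 nonbonded set for the nine atom classes
the two templates need (amide N/H, sp3 C and its hydrogens, aromatic C/H,
carbonyl C/O), with geometric-mean ε and additive Rmin/2 combining rules.
Templates are bare residues built from standard internal coordinates with
charged termini omitted; the alanine backbone is extended, and its exact
dihedrals are a free choice the minimum location is robust to (the
dominant contacts are N, H and Cβ against the ring carbons). With these
defaults the minimum falls at 3.39 Å with a well depth of ≈ 2.9 kcal/mol
— shallow relative to the ~3 kcal/mol stabilisation enthalpy attributed
to amide–aromatic hydrogen bonds and far below a conventional hydrogen
bond, so dispersion alone permits, but does not enforce, the H-bonding
geometry. The depth is a whole-residue dispersion sum; the N–H group alone
contributes only ≈ −1.2 kcal/mol of it.

## Synthetic data: what it emulates and what it does not

The generator builds a fictitious single-chain protein as a geometric
scaffold: ideal planar rings (hexagon side 1.40 Å; pentagon side 1.40 Å;
a fused ideal indole for Trp) parked 40 Å apart, minimal N/H/CA/C/O
backbones, amide protons planted at exact requested (r, θ) relative to a
named ring, remaining residues placed ≥ 100 Å from every ring. Jittered
copies (isotropic Gaussian, default 0.2 Å over 20 models — a typical NMR
ensemble size and spread) form the ensemble; the exact scaffold underlies
shift and restraint generation. Shifts are residue mean + dipole
perturbation at the planted geometry + Gaussian noise (default 0.3 ppm,
roughly half a typical σ_res, representing all non-ring contributions);
restraints are emitted for every amide-H/ring-H pair closer than 5.0 Å
(the NOE observability horizon) with upper bound distance + 0.5 Å and
lower bound 1.8 Å. Every output is a deterministic function of the spec
including its seed; identical seeds give byte-identical files.

What this does **not** emulate: folded backbone conformations, sterics
beyond a 1.5 Å clash check, ring flips or sidechain order-parameter
dynamics, assignment incompleteness, or restraint-file inconsistencies.
Passing tests on synthetic cohorts therefore validate the *pipeline
arithmetic* (parsing, joining, averaging, classification, regression
recovery of planted constants) — not the biological claims, which require
real depositions. Two planted amides cannot be arbitrarily close: requests
whose scaffolds collide raise a generation error rather than emitting a
physically impossible file, which in practice limits each ring to one
near-axial amide.

## Numerical choices and degenerate inputs

- Azimuth folding uses |cos| with clamping, so antipodal normals and
  slight numerical overshoot are harmless; a zero-length proton→centroid
  vector is a hard error.
- Nearest-ring ties break by (chain, seq, ring label) so results are
  order-independent.
- Degenerate (collinear) rings and missing backbone N are errors naming
  the residue; a missing first-residue amide H is a logged skip.
- Restraint filtering is idempotent and order-preserving; the 6.0 Å
  boundary is inclusive by the rule's wording.
- Z binning for the restrained-proportion table rounds half-up to the
  nearest integer.
- The scan grid is inclusive of both endpoints; the reported minimum is
  the grid argmin (no interpolation), so its resolution is the step size.

## Problem sizes

Default test cohorts are tens of residues with a handful of planted
geometries per ring and ensembles of 1–50 models; the noise-calibration
check uses 500 residues. These sizes make every property exact or
statistically decisive (≥ 4σ margins) while keeping the full suite and the
acceptance script in the seconds range.

## Known limitations

- His tautomer/protonation states are not inferred; the imidazole is
  treated as one ring regardless.
- Non-standard residues and nucleic-acid bases are never ring candidates.
- Legacy PDB-format coordinate files are not parsed (mmCIF only).
- The reference-statistics snapshot is a point-in-time table; Z scores
  against a different snapshot will differ at the percent level.
- Which Trp ring (or whether the whole indole) archival surveys used for
  "the" Trp ring centre is not standardised; here both rings compete as
  candidates, which callers should keep in mind when comparing against
  published per-residue numbers.
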