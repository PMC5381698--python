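# Methods

## Scope and data model

The package analyses the quaternary architecture of homo-oligomeric protein
assemblies given two conformational states (apo and product-bound).
Structures are parsed with gemmi into a small explicit model
(`Atom`/`Residue`/`Chain`/`Assembly`).  Author residue numbering as deposited
is canonical; regions are named sets of inclusive residue ranges in a stated
numbering scheme, and chains deposited in a different scheme are reconciled
by an explicit integer offset (for the UGP system: short-isoform numbering
+ 11 = long-isoform numbering).  Parsing policy: first model only; per atom
name the highest-occupancy alternate conformer is kept, ties broken by
altloc letter, so downstream geometry always sees one conformer;
heteroatom residues (ligands) survive parsing flagged and are excluded from
protein-only selections.  All geometric criteria are heavy-atom based — the
target structures carry no hydrogens.

## Rigid superposition and displacement profiles

`kabsch_fit` minimises RMSD over proper rotations + translations via SVD of
the cross-covariance matrix with the usual determinant correction.
Collinear point sets still return a minimising transform but are flagged,
because the rotation about the degenerate axis is arbitrary.  Rotation
angle/axis extraction uses the skew-symmetric part of the matrix, switching
to the +1-eigenvector of the symmetrized matrix above 178° where the skew
part vanishes numerically; axis signs are canonicalized toward the +z
hemisphere for reproducibility.

Displacement profiles superpose two states of a chain on the Cα atoms of a
*fit region* and report, per residue of a *report region*, the Cα
displacement and the maximum displacement over side-chain heavy atoms
present in both states (glycine: undefined, excluded from side-chain
maxima).  No outlier rejection or iterative trimming is applied — maxima are
raw.  The choice of fit region dominates the reported maxima (superposing on
the mobile region itself would hide its motion), there is no uniquely
correct choice, and it is therefore an explicit parameter everywhere; the
deposited-structure script sweeps candidate fit regions and reports all
results.

## Point-group detection

Candidate symmetry operations are the pairwise chain-onto-chain Kabsch
transforms (Cα matched by residue number over the common residue set).  An
operation is accepted only if, applied globally, it maps *every* chain onto
some chain with RMSD ≤ `residual_tol` and the induced chain map is a
permutation.  Cn requires a generator with rotation angle within
`angle_tol` of 360/n whose permutation decomposes into n-cycles; Dn
additionally requires an accepted two-fold with axis perpendicular to the
principal axis.  Groups are tried highest order first (Dn with n = N/2,
then Cn over divisors of N descending); C1 is the fallback.  When the full
assembly is C1 but a proper chain subset is symmetric (e.g. one displaced
subunit in an otherwise intact ring), the full-assembly label stays C1 and
the best subset group, its chains and the outliers are reported alongside —
the label is downgraded, never silently restricted.

Defaults: `angle_tol` 5°, `residual_tol` 1.5 Å — tolerant of
crystallographic coordinate error (the motivating structures have 0.4–0.5 Å
coordinate error) while rejecting accidental near-symmetries.  The
"face-to-back" (heterologous) flag is true when the generator permutation is
a single n-cycle.  Interface typing: a chain pair is in contact at ≥ 30
heavy-atom pairs below 4.5 Å; contacting pairs are `end_to_end` when > 50 %
of those atom pairs have both atoms inside the named C-terminal strand
region(s), else `side_by_side`.

## Contacts and the lock / interlock classification

Contact candidates come from a k-d tree at the largest cutoff and are typed
by distance-only criteria: H-bond — donor-capable N/O to acceptor-capable
N/O ≤ 3.5 Å, capability from a fixed per-residue atom table (backbone amide
N donates, carbonyl O accepts; hydroxyls both); salt bridge — side-chain N
of Arg/Lys/His to side-chain O of Asp/Glu ≤ 4.0 Å; hydrophobic — side-chain
carbon pairs of apolar residues ≤ 4.5 Å.  Angular criteria are deliberately
omitted: without hydrogens and at ~3.3 Å resolution they are not reliable.
The hydrophobic convention is a declared default, not a literature value.

A binding region's stabilization is classified from the contacts touching
it: `interlock` needs ≥ 1 inter-chain stabilizing contact, `lock` ≥ 1
intra-chain contact with sequence separation ≥ 20 residues (local backbone
contacts are not tertiary stabilization; the threshold is a parameter);
`both` and `none` are allowed — the binary narrative of a given enzyme is
recovered as the dominant class.  In a symmetric oligomer the same
(region residue, partner residue) pairs should recur in every chain; a pair
is called recurring when a majority of chains shows it (strict intersection
would let a single deviating chain delete the pair from the reference set),
and chains missing a recurring pair are listed as asymmetric.

The mutation screen truncates substituted residues to the heavy atoms shared
with the replacement type (no rotamer building) and reports every contact
that involves a removed atom as abolished; the delta of a multiple
substitution is the union of the singles.  This is a geometric plausibility
check only — it cannot model gained contacts.

## Compaction metrics

Both states are measured in the symmetry frame of the product-bound
assembly (z = principal axis, x = projection of the first perpendicular
two-fold) after superposing apo onto holo over all shared Cα.  The default
volume proxy is the frame-aligned bounding box e_x·e_y·e_z — the volume
measure for this comparison is not standardized, so the convention is
declared and a convex-hull volume is computed alongside as a sensitivity
check; on isotropically scaled test bodies the two agree exactly.  A
percentile extent (p, 100−p span of the projections) can replace raw
min/max when boundary spikes are a concern; off by default.  Sign
convention: negative percentages mean compaction.  The bounding-box and
hull proxies both change faster than a linear dimension (a 0.95 linear
shrink is −14.26 % in volume); when comparing against a quoted linear or
per-axis compaction figure, use `percent_extent_changes`.

## Scalar biophysical models

* Unit-cell volume by the triclinic formula; an angle combination with a
  non-positive radicand is rejected.
* Matthews coefficient V_M = V_cell/(Z·M); solvent fraction
  (1 − 1.230/V_M)·100 %, with 1.230 Å³·Da⁻¹ the reciprocal of the
  0.813·10⁻³ convention (protein partial specific volume 0.74 cm³/g).
  V_M ≤ 1.230 leaves the solvent fraction undefined and flagged.  Chain
  masses come from average-isotope residue masses (Biopython), one water
  per chain.
* Kinetics: lmfit least squares of the Michaelis–Menten and Hill equations.
  Initialization V_max⁰ = 1.2·max(v), K⁰ = half-maximal concentration by
  interpolation, and a Hill multi-start over H⁰ ∈ {0.5, 1, 2, 4} keeping the
  lowest RSS — Hill fits are initialization-sensitive and a single start can
  land in a shallow side minimum.  Model choice is an extra-sum-of-squares
  F-test of Hill (3 parameters) against nested MM (2), cooperative model
  preferred at p < 0.05.
* Melt curves: the fluorescence signal is normalized to [0, 1] and fitted to
  F(T) = 1/(1 + exp((T_m − T)/s)); T_m is the inflection point and must lie
  in the measured range.  Default normalization uses the pre-/post-transition
  plateau means (first and last 5 points) to resist spikes; plain global
  min/max is available, and on clean fully-plateaued sigmoids the two agree.
  A signal with no rise between the plateaus is rejected as non-sigmoidal.

## Synthetic data: what it emulates, and what it does not

Toy subunits are poly-alanine-like chains (N, CA, C, O, CB at ideal bond
lengths) on an idealized helical path (Cα–Cα ≈ 3.8 Å); assemblies place
exact Cn/Dn copies about z with a radial offset large enough to avoid
clashes (< 2.5 Å rejected).  Planted contacts convert designated residues to
Arg/Asp-like side chains (pseudo atoms marching outward from CB, branch
offsets built from local backbone geometry so the construction commutes with
chain placement) and translate the partner chain's local segment so the
designated atom pair sits at the target distance ± 0.01 Å; in a dihedral
assembly the pairing runs in the conjugated direction on the flipped ring,
which keeps the planted pattern exactly group-invariant.  Hinge deformations
rigidly rotate a region about an axis mapped onto each chain through its
placement, with the expected Cα displacement given analytically by the chord
2·d·sin(θ/2).  Kinetics and melt simulators add seeded Gaussian noise to the
exact model curves.

These generators exercise the *geometry and statistics* of the analysis
code.  They do not emulate real protein sterics, rotamer chemistry, crystal
packing, coordinate error correlated along the chain, or partial occupancy —
so passing closure tests demonstrates algorithmic correctness at exact
ground truth, not robustness to every artefact of experimental structures.
Real-structure behaviour is exercised separately through
`scripts/reproduce_deposited.py` on user-supplied files.

## Problem sizes and numerical choices

The default test and acceptance runs use 24–30-residue subunits, tetramers
and octamers, 300 noisy kinetics replicates (H = 1.7, σ = 3 % of V_max,
seven concentrations spanning 0.125–8 × K), 100 model-comparison replicates
under the null, and 100 melt curves (T_m = 55.65 °C, slope 1.5 °C,
σ = 0.02, 0.5 °C grid over 20–90 °C) — sizes at which the Monte-Carlo
medians/means are stable to well under the asserted tolerances (±0.1 on H,
±0.1 °C on T_m).  All randomness descends from explicit integer seeds; the
acceptance script derives independent sub-streams from its single `--seed`.

Known limitations: point-group search is exhaustive over chain subsets only
when the full assembly fails (combinatorial, fine for ≤ 12 chains); no
helical/translational symmetry; no interface area (SASA) or energetics; the
interlock screen needs the binding region supplied per structure — it does
not locate binding sites; melt fits assume a single transition.
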