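# Methods

This note records the scientific and numerical choices behind `hintmaps`:
what each stage computes, which parameters matter, what the synthetic
fixtures do and do not emulate, and where the design was genuinely open.

## Structure handling

PDB files are parsed with biotite. Alternate locations resolve to the
highest-occupancy conformer (ties go to the first record, i.e. alphabetical
altloc order); only the first MODEL of a multi-model file is read, since
MemProtMD-style snapshots are single-model. Lipids are recognized by a
residue-name whitelist (`DPPC`, `DPP`, `PC` by default, configurable),
waters as `HOH`/`WAT`. Lipid molecules are trimmed wholesale: a lipid is
kept iff any of its atoms lies within 6.0 Å of a protein atom, so a
molecule is never split.

Hydrogens are placed geometrically, not by energy minimization. For each
heavy atom with missing hydrogens, the CCD reference residue is superposed
onto the observed atom and its bonded neighbours (extended one bond shell
when fewer than three frame atoms exist) and the reference hydrogen
positions are transferred. The backbone amide H is special-cased onto the
bisector opposite CA and the preceding carbonyl carbon; a free N-terminus
receives an NH3+ triplet staggered about the N–CA bond and is flagged
terminal. At the 0.5 Å map spacing, sub-0.1 Å differences from a minimized
placement are irrelevant to map features; determinism is worth more.

Candidate residues are the requested types (ALA/ILE/LEU/PRO/VAL) with
complete backbone (N, CA, C, O) and complete heavy sidechain, excluding
chain-terminal residues (their φ or ψ is undefined). Every candidate is
guaranteed to carry the CA/CB/HA atoms the canonical frame needs.

## Conformation binning

Dihedrals follow the standard atan2 torsion formulation (validated against
an independent oracle and biotite to 1e-6°). The parse torsion for
ILE/LEU/PRO is the CA–CB–CG–CD* angle — the rotamer-defining torsion about
the CB–CG bond — reported in [0°, 360°); valine's χ1 is computed and stored
but never used for parsing; alanine has none.

The chessboard is an 8×8 grid of 45°×45° half-open cells over (φ, ψ),
shifted by (−20°, −25°) for ALA/ILE/LEU/VAL and (−35°, −5°) for PRO. The
orientation convention — columns a→h along increasing φ with origin at
−180° − shift_φ, rows 1→8 along increasing ψ with origin at 90° − shift_ψ —
is the unique placement on the 45° lattice for which the ideal α-helix
(−63°, −43°) lands in `c5` and the ideal β-strand (−110°, +130°) in `b1`.
It is encoded in one function (`conformation.chess_square`) and pinned by
two anchor tests; changing the convention is a one-line edit. χ1 parses use
half-open intervals with the lower edge inclusive ([0,120) → `.60`,
[120,240) → `.180`, [240,360) → `.300`; PRO [180,360) → `.30m`, else
`.30p`).

The canonical frame is built directly from the residue: CA at the origin,
CA→CB normalized to +z, the HA component orthogonal to z defining +y. This
is equivalent to least-squares fitting the three atoms onto a canonical
model residue, is exactly rigid (determinant +1, pairwise distances
preserved to 1e-9 Å), and fails loudly on degenerate geometry
(CA–CB < 0.5 Å).

## HINT scoring

The score is `b = a_i S_i a_j S_j T e^(−r) + L` with r in Å and unit decay
constant.

* **Atom constants `a`.** True HINT constants are derived from Hansch–Leo
  fragment analysis and are not shipped here. The default table is
  rule-based and sign/class-faithful: aliphatic C +0.8, hetero-substituted
  sp3 C +0.1, aromatic C +0.3, carbonyl-like C −0.3 (polar-neutral), H on C
  +0.23, polar H −0.2, donor N −1.0, acceptor N −0.9, carbonyl/carboxylate
  O −1.2, hydroxyl O −1.0, S +0.5. Chemotypes are derived from the CCD bond
  graph (bond orders identify carbonyls and aromatics). The table is
  overridable from a TSV so externally parameterized constants can be
  substituted; all package tests assert only signs and classes, never
  specific magnitudes.
* **S terms.** `S_i` defaults to the atom's Shrake–Rupley area with only
  its own residue as occluder ("local geometry"). Using in-context protein
  SASA instead would zero the interaction strength of buried atoms and
  leave buried residues with empty maps, contradicting the observation that
  deeply buried β-sheet alanines carry the richest hydrophobic maps.
  In-context (`structure`) and unit (`unit`) modes remain config options.
* **T resolution.** Acid–base pairs take +1 applied to |a_i S_i a_j S_j|
  (favorable polar), acid–acid and base–base −1 (unfavorable polar); any
  pair involving a hydrophobic atom takes T = +1 with the sign carried by
  the product of signed constants, so hydrophobic–polar pairs come out
  negative (unfavorable hydrophobic). Polar-neutral atoms (hydroxyls,
  amide-like carbons) pair favorably with any polar partner.
* **L term.** A clamped 6-12 clash penalty, −ε((r0/r)⁶ − 1)² for r below
  the vdW contact sum r0 and exactly 0 at and beyond it (ε = 0.1,
  configurable off). It is a stand-in for the original Lennard-Jones
  formulation, whose exact parameters are not published with the score
  definition; it only suppresses scores at physically impossible overlaps.
* **Pair cutoff.** 8.0 Å. With unit exponential decay, a pair at 8 Å
  contributes e^(−8) ≈ 3×10⁻⁴ of its contact strength, far below the
  F = 1.0 map floor for realistic |a S| products.

The environment of a target residue is every atom outside that residue —
protein, water, lipid — with lipids switchable off to produce the
`no_lipids` (mN) score variant for the same residues. The lipid score ratio
Σ|b|(lipid) / Σ|b|(all) feeds the LASA rule.

## Maps, similarity, clustering

Deposition uses the printed form exp(−d²/σ) with σ = 0.5 (the quotient
taken in Å²), evaluated on a subgrid around each midpoint and truncated
where the Gaussian factor drops below 1e-8 (≈ 3.0 Å); the search slab is
padded by one cell so the truncation is decided by the floor test alone and
deposition is exactly translation-equivariant up to coordinate precision.
Box endpoint ranges are grid points (inclusive), which reproduces the
published point counts exactly.

The log transform A = sign(G)·log10(|G|/F), F = 1.0, keeps strong
unfavorable (negative) regions — the condition is on |G|/F, otherwise all
unfavorable structure would vanish. The similarity D is the Hodgkin index
over the four class grids concatenated with equal weights (configurable):
it is exactly 1.0000 for identical maps, bounded by |D| ≤ 1, symmetric, and
sensitive to both shape and magnitude. Two all-zero maps compare as 1.0
with a warning; zero vs nonzero is 0.0. The index lives in one function so
an alternative correlation metric can be substituted.

k-means clusters each bin's maps on the rows of the bin's similarity matrix
(the only feature space in which the published procedure's centroids are
defined), with k-means++ initialization, 50 restarts, and a caller-supplied
seed; empty clusters are dropped, so `k_used` may be below the per-type
maximum {ALA 4, ILE 9, LEU 9, PRO 6, VAL 9}. Bins with ≤ 4 maps are
averaged as a single cluster. Optional singleton recovery (off by default)
splits members beyond mean + 3·sd of within-cluster centroid distance into
singletons and reassigns the rest — the published recovery protocol is not
specified in detail, so this threshold rule is a documented stand-in.

Weighted averages use w = exp(−d²/σ²) with σ = d_max/8, d_max being the
mean over the bin's clusters of each cluster's maximum centroid distance;
σ = 0 (all members coincident) falls back to flat weights. Average residue
structures use the same weights on canonical-frame atomic positions over
the atom set shared by all members, and cluster RMSDs (heavy-atom and
all-atom) are pooled over members and atoms against that average with no
refitting — members are already in a common frame.

## Membrane domains and accessibility

Phosphate-bead planes are split at the median z; each plane needs ≥ 3
beads and reports mean ± sd. The membrane interval is closed: a residue
with backbone z exactly at a bound counts as membrane (pinned by a test).
Residues missing from the pore-lining CSV default to not-pore-lining, hence
mL when in membrane.

Sidechain SASA uses biotite's Shrake–Rupley (probe 1.4 Å, 960 sphere
points, single-atom vdW radii) with protein atoms only as occluders —
lipids and waters are stripped first, matching submission of bare protein
coordinates to an accessibility server. In/Out thresholds are 20 % / 50 %
of the residue type's free reference area (computed once from the isolated
CCD residue, cached, overridable); between them a residue is indeterminate.
The thresholds mirror common accessibility-server conventions and are
config keys. LASA reclassification is all-or-nothing per residue at lipid
score ratio > 0.1; cluster tables report SASA statistics over non-LASA
members and LASA statistics over LASA members.

## Synthetic fixtures

* **Peptides** are grown by NeRF with exact target (φ, ψ) — (−63°, −43°)
  helix, (−110°, +130°) strand — ω = 180°, standard bond lengths/angles,
  CCD sidechains rotated to requested rotamer torsions (proline puckers by
  rotating CG about the CB–CD axis), optional Gaussian coordinate noise.
  They are seed-deterministic and exercise protonation (they ship without
  hydrogens).
* **Membrane systems** emulate a MemProtMD export in shape only: a 4-helix
  antiparallel bundle along z spanning ±(w+5) Å for bilayer half-width
  w = 15, pseudo-DPPC lipids (13-atom headgroup + two 4-carbon tails;
  residue name `DPP` because the PDB residue field is 3 characters) packed
  in two leaflets against the bundle, phosphate-bead planes at ±w with
  configurable z-noise (default studies use sd = 1 Å, matching the ≈ 1 Å
  plane spread of real coarse-grained snapshots), and a pore-lining CSV
  marking inward-facing membrane residues. They are *not* physically
  packed lipid bilayers: lipid density, tilt and headgroup chemistry are
  schematic, so passing tests demonstrate pipeline correctness (geometry,
  bookkeeping, variant pairing), not lipid-physics realism.
* **Archetype maps** are sums of sign-consistent Gaussian blobs per
  interaction class; noisy copies jitter blob centers (sd = `noise` Å) and
  amplitudes (multiplicative, sd = 0.2·noise). They provide planted ground
  truth for clustering recovery; real map ensembles are less cleanly
  separated.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on the fixtures
above: an 18-residue helix (16 candidates), a 4-helix membrane bundle
(108 residues, 100 candidates, 20 lipids, 200 beads), and 4×25 planted
archetype maps. These sizes keep a full run within a couple of minutes
while leaving every pipeline stage non-trivially populated (multi-cluster
bins, all three membrane domains, both LASA and non-LASA residues). All
randomness — fixture noise, k-means initialization — derives from explicit
seeds, and the whole pipeline is bitwise repeatable for a fixed config and
seed.

## Known limitations

* The shipped atom constants are rule-based chemotype values, not fitted
  Hansch–Leo fragment constants; absolute map magnitudes are therefore
  package-specific, though signs, classes and all similarity/clustering
  structure are meaningful.
* Protonation is idealized-geometry only; rotatable polar hydrogens
  (hydroxyls) take CCD orientations rather than H-bond-optimized ones.
* mmCIF input, ligand/cofactor typing beyond water and lipid, χ2+ parsing,
  DSSP-style secondary structure, and membrane re-orientation are out of
  scope; membrane systems must arrive z-oriented.
* The exact published chessboard row/column labelling and the singleton
  recovery protocol are not fully specified by their sources; both are
  pinned here by explicit conventions and tests, and both are isolated for
  one-line substitution.
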