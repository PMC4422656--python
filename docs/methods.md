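# Methods

## Scope and model

`galkit` quantifies how galectin carbohydrate-recognition domains (CRDs)
discriminate type-1 (Galβ1-3GlcNAc) from type-2 (Galβ1-4GlcNAc)
N-acetyllactosamine. The analysis treats a crystal structure as a static
set of heavy atoms: torsion geometry, distance-based polar contacts,
salt-bridge geometry classes and rigid-body superpositions. No
energetics, protonation inference, or dynamics are modelled; crystal
snapshots need not reflect solution behaviour, and conclusions drawn
from single conformers should be read accordingly.

## Coordinate handling

Files are parsed with gemmi (PDB and PDBx/mmCIF). Hydrogens are dropped
throughout: every criterion in the package is heavy-atom based, matching
~2 Å crystallography where hydrogens are not observed. Alternate
locations are collapsed to one conformer per atom — highest occupancy
wins, ties break to the alphabetically first altloc — because the
distance tables report a single value per contact. Residue numbers are
taken verbatim from the file; a sequence-offset argument on the pairing
routines reconciles construct numbering differences when needed.
Protomer selection keeps one chain's protein atoms and assigns each
hetero/water residue to the chain owning its nearest protein atom (the
crystal dimers carry one ligand per protomer).

The bound disaccharide is identified by residue name (galactose: GAL,
GLA; GlcNAc: NAG, NDG; both sets overridable, since component naming
varies across deposition eras) and by connectivity: a C1^Gal–O
separation under 1.8 Å marks the glycosidic bond, and whether the bonded
oxygen is O3 or O4 of the GlcNAc decides β1-3 vs β1-4. Finding both
within bonding distance is reported as an error, never guessed around.

## Torsions, puckering, superposition

Dihedrals use the standard atan2 formulation under the IUPAC sign
convention, values in (−180°, 180°]; a second, independently coded
cross-product formulation serves as the test oracle. Note that a torsion
is invariant under chain reversal (τ(A,B,C,D) = τ(D,C,B,A)) and changes
sign only under mirror reflection; the property tests assert exactly
that. Averages over ligand copies are circular means (atan2 of mean
sine/cosine), since the ψ values straddle the ±180° seam. Both a
chain-A-only and an all-copies averaging mode exist because deposited
dimers carry two ligand copies and the choice is a user decision.

Ring conformations come from Cremer–Pople puckering coordinates computed
over the six ring atoms in O5→C5 order. A ring is a chair when the polar
angle θ is within 45° of a pole (threshold configurable) and the
amplitude Q exceeds 0.1 Å; smaller amplitudes are reported as
planar/non-chair rather than assigned a meaningless phase.

Superposition solves the Kabsch least-squares problem through
scipy's `Rotation.align_vectors` (proper rotations only; an
independent quaternion-eigenvalue implementation is the test oracle).
Cross-structure fits default to Cα atoms paired by residue number.
Subset RMSDs (Cα or all-heavy) are evaluated *after* a transform
obtained from the larger fitting set, so they measure how far the
selected residues deviate inside a common frame rather than refitting
each selection.

## Contacts, water bridges, salt bridges

The hydrogen-bond criterion is distance-only: ligand N/O to protein N/O
within 3.5 Å, no angular term and no donor/acceptor typing by default.
This mirrors the viewer-style distance tables the analysis is designed
to reproduce; the largest tabulated contact there is 3.47 Å, so 3.5 Å
is the natural default, exposed as a knob with a sanity range of
(2.2, 4.5]. A strict mode that rejects chemically implausible
carbonyl–carbonyl pairs exists but is off by default. Distances are
rounded half-up to 0.01 Å; per-moiety averages are arithmetic means of
the direct (non-water) contacts.

A water bridge requires the water oxygen within the hydrogen-bond
cutoff of at least one ligand polar atom and at least one protein polar
atom simultaneously. Steric-clash distances (e.g. the superposed LN1
C6-hydroxymethyl oxygen against the LN2-complex's ordered water) are
plain minimum heavy-atom distances after superposition. Trp–galactose
stacking is recorded as present when the ring-centroid separation is at
most 5.5 Å, with the interplanar angle from best-fit plane normals
reported alongside.

Salt bridges are Arg/Lys–Asp/Glu pairs with any sidechain N–O distance
(Arg NE/NH1/NH2, Lys NZ vs Asp OD1/2, Glu OE1/2) at or below 4.0 Å. The
class is *bidentate* only for the two-pronged fork–fork arrangement: two
contacts using distinct nitrogens **and** distinct oxygens. Multiple
contacts sharing a single atom remain monodentate. The 4.0 Å cutoff and
the fork–fork rule follow the standard geometric taxonomy of salt-bridge
motifs; the cutoff is a parameter since the taxonomy itself is
convention.

When diffing contact tables across a β1-3/β1-4 pair, GlcNAc atoms map by
position rather than name — the free 4-OH of the type-1 ligand occupies
the position of the free 3-OH of the type-2 ligand (O4↔O3), with N2 and
O6 conserved — and protein residues map through the built-in
hGal1/hGal3/hGal7 correspondence table.

## L4-loop classification

The acidic member of the Arg–Asp/Glu–Glu–Arg quartet sits on the loop
(L4) between β-strands S4 and S5. Its position class is *terminal* when
it occupies the last loop position or the first S5 position, *internal*
otherwise; combined with a loop-length class (short: ≤ 6 residues) this
yields three architecture groups: terminal acid → hGal7-group
(LN1-preferring short-loop architecture), internal acid in a short
loop → hGal7-like/Gal2-like, internal acid in a long loop →
hGal1/3-like. Strand boundaries are annotations, not computed: built-in
values (hGal1 L4 = 49–58 with Asp54 internal; hGal3 L4 = 163–171 with
Glu165 internal; hGal7 L4 = 54–58 with Glu58 terminal) were fixed from
the strand spans implied by the conserved contact residues, and callers
may override them. No automated secondary-structure assignment is
attempted.

## Binding equilibria

Direct titrations are fitted to A = A₀ + A_max·[L]/(K_d+[L]) by
Levenberg–Marquardt least squares with the analytic Jacobian,
multistarted from K_d equal to the smallest, geometric-mean and largest
concentration to avoid local minima. BLI mode fixes A₀ = 0
(baseline-subtracted responses); FP mode floats it. The fit demands a
≥ 10-fold concentration span and flags responses that drop by more than
a fifth of the dynamic range as non-monotone. The reported uncertainty
is the asymptotic covariance-based standard error.

The competition calculation applies the five mass-action steps exactly
as written in the assay's algebra (probe-bound fraction → free probe →
free galectin → competitor-bound galectin → free competitor → K_d). It
fails loudly when the deduced [CG] ≤ 0 (no detectable competition) or
[C] ≤ 0 (inconsistent inputs); both mass balances are asserted on every
call. Its independent oracle, `simulate_equilibrium_competition`, solves
the coupled equilibria for one receptor and two ligands by root-finding
the free-receptor concentration (the balance function is monotone, so
brentq on [0, G_total] at near-machine tolerance finds the unique root)
— the closed form inverts the simulator exactly in the noiseless case.

Preference ratios are computed as K_d^LN2 / K_d^LN1, so values above 1
mean LN1-preferred. The published summary of these ratios labels its
column K_d^LN1/K_d^LN2, but every printed value follows the LN2/LN1
arithmetic; the implementation reproduces the printed values and carries
the discrepancy note in its output metadata rather than guessing intent.
The published dissociation constants themselves (hGal1 340/150, hGal3
93/33, hGal7 270/410, hGal3-E165A 230/280 μM by BLI; 6.74/3.59,
1.44/0.33, 6.63/19.69 μM by FP) are measured inputs shipped as a data
table — the raw assay data are not deposited, so these values are used,
never recomputed.

## Synthetic data

The fixture generator emulates the binding-site geometry only, not its
physics. The disaccharide is grown by internal-coordinate (NeRF)
placement from an ideal chair template (C–C 1.52 Å, C–O 1.43 Å, puckered
hexagon of radius 1.46 Å and amplitude ±0.25 Å; all constants recorded
in the manifest), so requested φ/ψ are achieved to numerical precision
and the GlcNAc ring closes exactly by construction. Protein residues are
sidechain tips (imidazole, guanidinium, carboxylate, amide, indole)
anchored at requested distances and re-spun under a seeded generator
until no unintended polar pair falls inside the contact cutoff;
salt-bridge pairs are built in isolated zones 18 Å from the ligand with
head-on (monodentate) or fork-facing (bidentate) geometry verified at
build time. A seeded random rigid transform is applied last and recorded
in the manifest, making every fixture a rigid-motion-invariance test for
free. What fixtures do **not** have: backbone atoms, crystallographic
packing, coordinate noise, occupancy/altloc complexity, or realistic
water networks — passing on fixtures demonstrates the arithmetic and
bookkeeping are right, not that real electron density was interpreted
correctly.

Binding fixtures mirror the assay layout: eight-point 3-fold dilution
series from 3 mM (BLI) and single-point competition at the probe 0.1 μM /
galectin 120, 3, 120 μM / competitor 300, 6, 300 μM stoichiometries of
the hGal1/hGal3/hGal7 assays, with additive Gaussian noise at a stated
standard deviation (2 % of amplitude in the recovery tests).

## Numerical choices and sizes

Angles are reported to 0.1°, distances and RMSDs to 0.01 Å; comparisons
against tabulated reference values use ±5° for torsions, ±0.15–0.2 Å for
RMSDs and ±0.05 Å for single contacts, reflecting rounding and unstated
fitting-set choices upstream. Oracle-equivalence tests run 1000 random
cases per primitive (dihedral, superposition, contact enumeration,
salt-bridge detection); K_d recovery uses 200 noisy replicate titrations
— sizes chosen so the whole suite completes in well under a minute while
keeping binomial fluctuation in the median negligible. The two-ligand
equilibrium solver runs brentq at xtol 1e-15/rtol 9e-16, conserving mass
to better than 1e-10 relative.

## Known limitations

* Distance-only hydrogen bonds will count close non-bonding N/O pairs;
  the strict mode mitigates but does not resolve this without hydrogens.
* The comparative module needs the deposited wwPDB entries locally; it
  performs no downloads, and without those files the deposited-structure
  checks cannot run.
* Construct-numbering reconciliation is manual (offset argument); no
  sequence alignment is performed.
* Single-point competition inherits the assay's assumptions (1:1
  binding at both sites, anisotropy linear in bound-probe fraction); the
  multi-point extension averages per-point estimates but does not fit
  them jointly.
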