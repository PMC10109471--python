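# Methods

`bmcshell` analyzes how bacterial microcompartment shell hexamers (BMC-H,
Pfam 00936 fold) tile into 2D layers and how those layers bend. The package
covers the full chain from deposited crystal structures to derived
quantities: reconstruction of the hexamer layer from cell + symmetry
operators, classification of inter-hexamer arrangements (Arr-A/B/C/D),
construction of the tri-hexamer analysis unit, signed bending/tilting
dihedrals over snapshot ensembles, per-residue interface analytics,
alanine-scan model editing, regrafting of arbitrary hexamers onto the
Arr-A template, and WHAM reconstruction of potentials of mean force from
umbrella-sampling windows. Molecular dynamics itself is out of scope: the
package consumes coordinates (multi-MODEL PDB) and per-residue energy
tables produced by external engines, and ships a synthetic-data module that
generates every test fixture from scratch.

## Landmarks and portability

All geometric operators are parameterized by a *landmark map*, an explicit
role → residue-number table (PduA numbering by default): the edge lysine
K26, the bending probes S27/I38, the tilting probes M24/I18, the plane
probe (V54 by default; A53 is equally common and configurable — the source
analyses use both), the arginine R79 and its acidic pocket partner D/E83,
and the R28–D49 salt-bridge pair (CcmK numbering). Transfer to homologs is
by explicit user renumbering, never by sequence alignment. The map also
declares residues on the *concave* face; this anchors the sign convention
(below). Shipped defaults assume PduA author numbering; for other proteins
the defaults are a starting point the user must verify.

## Layer reconstruction and arrangement taxonomy

Symmetry operators are taken from REMARK 290 SMTRY records when present
(authoritative for the deposited setting) and otherwise from the
space-group name via gemmi's tables. `expand_layer` enumerates all
operator × integer-translation images whose center of mass falls within a
radius; for piled crystals the sheet containing the first deposited chain
is selected by filtering image COMs against the plane normal to the
thinnest principal axis of the reference content (half-thickness 6 Å).
Chains are grouped into C6 hexamers by pairwise superposition voting: two
chains belong to the same hexamer when their optimal superposition is a
pure rotation by a multiple of 60° (±8°, screw component < 2 Å) about an
axis shared, within 5 Å, with the other members. Hexamer COMs are the
unweighted mean of backbone (N, Cα, C, O) positions of core residues 1–90
over the six chains.

Interfaces are hexamer pairs with any heavy-atom contact below a cutoff
(default 5 Å; the underlying crystallographic analyses imply but never
state one, so it is a parameter everywhere). The classifier turns the
published exemplar ranges into explicit breakpoints on the minimal
inter-lysine Cα–Cα distance: ≤ 9 Å → Arr-A, (9, 12] Å → Arr-C, ≥ 13.5 Å →
Arr-B, with the 12–13.5 Å gap resolved by nearest prototype in
(d_lys, spacing) space using prototypes (8.0, 68.5), (10, 69.5), (16,
70.5). Arr-D is known from a single crystal form; without shippable
coordinates for it no numeric signature can be derived, so Arr-D is only
assigned against a user-supplied prototype and is otherwise never emitted.
Two side-chain flags accompany the label: Arg-insertion (any guanidinium N
of R79 within 4.5 Å of a carboxylate O of D/E83 on the facing hexamer, the
Arr-A signature) and the R28–D49 salt bridge (same 4.5 Å N–O criterion,
the Arr-B signature). The 4.5 Å value is this package's choice; the
interactions are described qualitatively in the source material.

## Signed bending and tilting

Bending is the signed dihedral over the Cα quadruple
I38(A)–S27(A)–S27(B)–I38(B), taken from one interfacial monomer of hexamer
A and the symmetric monomer of hexamer B; the facing monomer pair is the
one whose key-lysine Cαs are mutually closest (this selection is separated
from its runner-up by tens of Å and is therefore robust to coordinate
noise, unlike an S27-based selection, whose alternatives are nearly
degenerate). Tilting uses the midpoints of the M24 and I18 Cα pairs of the
two interfacial monomers of each hexamer. A flat layer is *trans* (raw
dihedral 180°), so the reported angle is the deviation from 180°, signed
so that negative = displacement toward the convex face — the orientation a
closed shell adopts, with the convex side facing the lumen. The convex
side is inferred per snapshot from the concave-face residues of the
landmark map, making both operators exactly invariant under rigid-body
motion of the snapshot and symmetric under swapping the two hexamers.
Degenerate (colinear) quadruples raise rather than return a value; in
ensemble sweeps such rows are marked invalid, and values more than 3 SD
from their interface's run mean are flagged as outliers but never
corrected.

Ensemble utilities follow the standard conventions: the average structure
superposes every snapshot on the first by the backbone of one hexamer
before coordinate-wise averaging; RMSD series are backbone RMSDs against a
reference after superposition; COM-deviation reports the change of each
pairwise hexamer separation between an average structure and the crystal
(negative = contraction). Plane representations pass an exact plane
through the plane-probe Cα of the three interface-proximal monomers of
each hexamer, plus the plane of the three hexamer COMs.

## Interface analytics

Three per-residue signals identify clamping residues over the 18 monomers
of a tri-hexamer: (i) side-chain RMSD against the average structure,
computed after local superposition of each residue's own backbone so the
profile reads conformational freezing rather than rigid drift (the first 8
snapshots are excluded by default as equilibration); (ii) the spread
(max − min) of the residue's per-monomer interaction energy; (iii) the
interface enrichment Δ = mean(interface copies) − mean(exposed copies),
negative = stabilizing at the interface. Energies are accepted as plain
(residue, monomer, value) TSV from any engine. For tests and ranking the
package also provides its own deterministic residue scorer: a screened
Coulomb term (1389.35·q_iq_j / 4r², formal charges on Lys/Arg/Asp/Glu and
optionally His side chains) plus a Lennard-Jones-like steric term with
embedded vdW radii, summed over inter-hexamer atom pairs within 12 Å. It
is a documented scoring function for ranking, not a physical energy. The
combined ranking is lexicographic — criteria met, then energy interval,
then enrichment — with every criterion's value retained so the
combination is auditable; an all-flat input is flagged `no_signal`.

## Regrafting and alanine scans

`superpose` is a plain Kabsch least-squares fit (SVD); `regraft_arrA`
superposes each donor hexamer individually on one template hexamer using
Cα of the core range and the best of the six cyclic chain
correspondences, rejects donors above 3 Å RMSD, and reports residue pairs
of different hexamers closer than 2.6 Å (≈ vdW overlap; the source
protocol relieved such clashes manually, without stating a threshold).
Side-chain rebuilding is deliberately out of scope — the clash report is
the hand-off point. `mutate_alanine` truncates a residue to Cβ and renames
it, in the interfacial copies (6 or 9 in a tri-hexamer, depending on
whether the residue sits near the interface center or edge — determined
from the contact mask, never hand-set), in all copies, or in an explicit
chain list; backbone and Cβ coordinates are untouched bitwise.

## WHAM

Umbrella windows carry a center, a spring constant in kJ/mol/nm² (the
engine convention; 1000 kJ/mol/nm² = 10 kJ/mol/Å² internally) and the
sampled order-parameter series. `Wham(windows, temperature).fit()` solves
the self-consistent equations for the window offsets f_i in log space
(logsumexp throughout), histogram bin width = window spacing / 5 (0.2 Å
for the reference 1 Å spacing), convergence at max|Δf_i| < 10⁻⁶ kJ/mol,
at most 10⁵ iterations; gapped windows and non-convergence raise with
diagnostics. G(ξ) = −k_BT ln ρ(ξ) is shifted so its minimum is zero.
Errors come from bootstrap resampling of samples within windows (seeded,
deterministic). A direct maximum-likelihood solution of the same
equations via scipy.optimize serves as an independent cross-check route
in the tests. The binding energy is read as G at the farthest restrained
window — bins beyond the last window center are sampled only by one
restraint's Gaussian tail and carry edge artifacts, so the readout
averages the bins belonging to the last window and checks a plateau over
the last three windows (tolerance max(1 kJ/mol, 2× tail bootstrap SE)).
Lateral-displacement profiles are reconstructed identically and annotated
with the canonical arrangement offsets (Arr-A at 0, Arr-C near 4.5 Å,
Arr-B near 9 Å).

## The synthetic-data module

The toy hexamer is a pseudo-protein: six C6-related chains of 95
backbone+Cβ residues on a ~33 Å disk, with full side chains only where a
landmark needs one. It is *not* a model of PduA's structure; it is a
geometric instrument whose construction constants are chosen so that every
downstream operator has an exact oracle:

- K26 sits on the wedge boundary at radius 30.25 Å, so a head-on lattice
  at spacing *s* has d_lys = s − 60.5 exactly; offsets enter through a
  sheared lattice vector (hexamers stay translationally related, all
  interfaces equivalent), giving d_lys = √((√(s²−o²) − 60.5)² + o²).
- S27/I38 share their y-offset, making the bending "wing" parallel to the
  tilting hinge: bending reads exactly 0 under a pure imposed tilt. The
  M24/I18 midpoints share their x, putting the tilting hinge exactly along
  the COM axis. Imposed rotations about each dihedral's own hinge are
  recovered exactly by construction; tilting picks up a bounded (< 12 %)
  cross-talk under a pure bend — the two dihedrals are not orthogonal
  observables, here or on real coordinates.
- Residues 91–93 mark the concave (+z) face; the convex face is −z.
- Interface chemistry is engineered in the C2-image algebra of the layer:
  R79/E83 tips meet (≈3.5 Å) only across head-on Arr-A interfaces, the
  R28/D49 tips only across Arr-B-like shear offsets (≈11–15 Å), and rim
  bands keep facing hexamers in heavy-atom contact (3–5 Å) without vdW
  overlap across the whole supported window (spacings ≈ 67.7–71 Å,
  offsets up to ≈ 15.5 Å).

Trajectories impose scheduled hinge rotations (constant, linear, or
rapid-rise-then-plateau — the statistical shape of the real bending
time-courses) on two of the three tri-hexamer interfaces, plus isotropic
Gaussian coordinate noise; the third interface's angles are geometrically
induced and marked as such in the emitted truth table. Umbrella samples
come from seeded Metropolis chains on named 1-D potentials (harmonic,
double-well, Morse-like); the default step (~2 bias widths) and 10×
thinning leave recorded samples essentially uncorrelated, emulating the
decorrelated sampling interval of production umbrella runs and keeping the
i.i.d. bootstrap calibrated.

What the generator does *not* emulate: real side-chain packing and
rotamer dynamics, solvent, correlated backbone motions, asymmetric-unit
contents smaller than a hexamer, and crystallographic disorder. Passing
recovery tests therefore demonstrate that the *operators* are correct and
robust at realistic noise levels, not that any particular protein bends.

## Numerical choices and limitations

- Coordinates ride in biotite AtomArrays (single precision). Angle
  operators and superpositions compute in float64; rigid-transform
  identities hold to 10⁻⁹–10⁻¹⁵ at the transform level, while stored
  model coordinates round-trip at the PDB field precision (10⁻³ Å).
- Alt-locs reduce to the highest-occupancy conformer (ties: first);
  hydrogens are ignored by all geometric operators; waters/ligands are
  flagged on reading and removed before lattice expansion.
- The coordinate-wise average of two configurations rotated by ±θ shrinks
  chords by (1 − cos θ); the average structure of a symmetric ensemble
  therefore *measures* the mid-pose angle but is not the mid-pose
  geometry. Tests assert the angle, not coordinates.
- Supported lattice window of the toy geometry: spacings ≈ 67.7–71 Å and
  shear offsets up to ≈ 15.5 Å (inter-lysine 7.2–17.6 Å, the full
  crystallographic range). Outside it, facing atoms may lose contact or
  overlap; `make_lattice` emits the true minimal contact distance so
  callers can pick contact cutoffs from ground truth.
- The hexamer detector assumes near-ideal C6 units (backbone RMSD < 1.5 Å
  between chains after rotation); heavily distorted or partially occupied
  hexamers are reported as ungrouped chains rather than force-grouped.
- Problem sizes in the shipped tests and the acceptance script (≤ 100
  snapshots, 400 samples per umbrella window, 40 bootstrap replicates)
  were chosen as the smallest ensembles at which the statistical
  tolerances are stable; all scale linearly if increased.
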