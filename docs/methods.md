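# Methods

This note documents the models, conventions and numerical choices behind
`trifil`, and what the synthetic data generator does and does not
emulate.

## Units and geometric conventions

Coordinates are held in nanometres throughout; RMSD values and filament
rises are *reported* in angstroms, the units customary for structural
comparisons and cross-β spacings.  Angles are degrees.  Torsions follow
the IUPAC sign convention (positive clockwise looking from the second to
the third defining atom) on the half-open interval (−180, 180], so a
perfectly trans arrangement reports +180, never −180.  Vectors shorter
than 1e−9 nm are treated as degenerate and raise `GeometryError` rather
than returning a number.  Periodic systems are restricted to
orthorhombic boxes; triclinic cells are rejected with a clear error.
Superposition uses the SVD form of the Kabsch algorithm with the
determinant correction that excludes reflections; the test suite
cross-checks it against an independently implemented quaternion
eigenvalue (Horn) oracle.

## Data model

A system is a set of capped tripeptides — acetyl cap (residue index 0),
three amino acids over {Phe, Ile} (indices 1–3), amide cap (index 4) —
plus optional coarse water beads (`W`, peptide id −1).  Each amino acid
must carry N, CA, C, O and CB; the amide hydrogen is optional.  When H
is absent it is rebuilt in the amide plane at 0.1 nm from N with the
standard trans-amide geometry (C(prev)–N–H = 119°, H anti to the
following CA), the same convention the structure builder uses, so
detection of hydrogen bonds is insensitive to whether the input file
stored hydrogens.  File I/O (PDB with multi-model support, GRO, XTC/DCD)
goes through biotite and MDAnalysis; peptide bookkeeping is
reconstructed from residue names (each `ACE` starts a peptide), which
keeps the reader independent of chain-id conventions that GRO lacks.

## Rotamer-state classification

The (φ, ψ) torus is partitioned into four rectangles (lower edges
closed, upper edges open; an upper bound of exactly 180 is closed):

| state | φ | ψ |
|---|---|---|
| α_R | [−180, 0) | [−120, 50) |
| α_L | [0, 180] | any |
| β   | [−180, −100) | [50, 180] ∪ [−180, −120) |
| PP_II | [−100, 0) | [50, 180] ∪ [−180, −120) |

The partition is total and disjoint by construction (verified on a grid
and by property tests), so classification is a total function and
boundary points are owned deterministically by the lower-closed edge.
A tripeptide code is the ordered triple of per-residue states.  By
default the β and PP_II basins — geometrically the closest pair — are
merged at the C-terminal position, giving 4 × 4 × 3 = 48 uniquely
defined codes; the merge is a config switch (off → 64) and is surfaced
in reports.

Each state also carries a *realization centre*, the (φ, ψ) target used
when building an ideal fixture for that state: β (−120, 130), PP_II
(−75, 150), α_R (−80, −50), α_L (80, 50).  The helical centres sit
deeper in their basins than the textbook α-helix point (−60, −45)
because the sidechain rotation angle of an adjacent helical-helical pair
at the textbook point is ≈70°, inside the excluded 60–115° band, whereas
helical-turn conformations in fibril interiors are canonically all-syn.
At (−80, −50) the α_R–α_R pair sits at θ ≈ 43° with a comfortable margin
to the syn cut.  Centres are config-overridable.

## Sidechain rotation angle and topology groups

θ is operationalized as the four-point torsion
C_β(i)–C_α(i)–C_α(i+1)–C_β(i+1), i.e. the rotation of the two C_α→C_β
vectors about the C_α–C_α axis; this reduces to the syn/anti semantics
(same side / opposite sides of the backbone).  Grouping uses |θ| with
strict cuts: both > 115° → all-anti; both < 60° → all-syn; mixed →
N-syn or C-syn depending on which terminal sidechain points with the
middle one; any |θ| in the closed band [60, 115] → other.  Signed θ
values are reported; only the grouping takes magnitudes.  CB placement
uses L-amino-acid chirality (improper torsion C–N–CA–CB = −120°,
N–CA–CB = 109.5°, matching ideal alanine geometry), under which the
extended strand `b-b-b` is all-anti (θ ≈ −167°) and the helical turn
`aR-aR-b` is all-syn (θ ≈ 43°, 0°).

## Interaction accounting

All thresholds are the conventional printed values and are held in one
dataclass: contact cutoff 0.65 nm, hydrogen-bond donor–acceptor cutoff
0.35 nm with donor–H–acceptor angle > 120° (both strict), fiber-core
radius 1.0 nm.  Contact families operate on sidechain particles only
(CB and beyond); backbone atoms and cap groups are excluded from the
contact families but cap amides do participate as hydrogen-bond donors
and acceptors (they are backbone amides; switchable).  Pairs within one
residue are never counted, and unordered pairs are counted once.
Distances are minimum-image whenever a box is present (via a periodic
k-d tree, brute force without a box); the test suite checks equality
with an O(n²) oracle and invariance under lattice translations.

Per-residue normalization divides each family count by the number of
residues of the relevant type in the peptide (Phe–Phe by the peptide's
Phe count, Phe–Ile by Phe+Ile = 3, water exposure by the respective
residue count); hydrogen bonds are reported per peptide unnormalized.
The divisor choice makes bars comparable across sequences and is
switchable (`normalize=False`).  Families undefined for a sequence
(e.g. Ile–Ile for FFF) are reported as missing, not zero.  Sequences
without solvent simply report zero water contacts.

The core filter estimates the fiber axis as the first principal axis of
the largest aggregate's peptide-centroid cloud and keeps peptides whose
centroid lies within 1 nm of that axis; a point-centroid variant
(`mode="point"`) implements the literal distance-to-centroid reading,
which would empty the ends of long fibers and is therefore not the
default.  For single-peptide "aggregates" the axis degenerates to the
centroid point.  The axis estimate ignores periodic wrapping of the
aggregate; generated fibers are built unwrapped.

## Aggregates, filaments, rise

Aggregation reuses the 0.65 nm contact criterion over all peptide
particles: peptides are nodes, any interchain pair within the cutoff is
an edge, aggregates are connected components.  Filament detection then
looks for in-register parallel stacking *within* components: a stacking
link requires the residue-wise (i ↔ i) mean CA–CA distance inside
[0.40, 0.60] nm — bracketing the 4.6–4.9 Å cross-β range — and at least
one interchain backbone hydrogen bond.  Link components of ≥ 2 peptides
are filaments, ordered along their principal axis; the rise is the mean
(± sd) in-register CA–CA spacing of adjacent pairs, in Å.  Antiparallel
registration is out of scope.  Reference comparison extracts backbone +
CB atoms of residues 1–3 in a canonical order from every sampled
conformer, Kabsch-superposes onto the reference, and reports the single
smallest RMSD (ties → first occurrence) together with the best
conformer's code; the atom selection is configurable since crystal
comparisons sometimes include caps.

## Synthetic structure generator

The generator stands in for self-assembly trajectory data and mirrors
the study conditions such data would have: 30 peptides in a 6 × 6 × 6 nm
periodic box, three independent runs, filament rises drawn from
4.6–4.9 Å when unspecified, MARTINI-like coarse water at 8.35 beads/nm³
(bulk water density over the 4:1 mapping).

Tripeptides are built by sequential internal-coordinate placement
(NeRF) with standard bond lengths (N–CA 1.46 Å, CA–C 1.52 Å, C–N
1.33 Å), standard angles, ω fixed at 180°, and sidechains represented by
CB only; measured backbone dihedrals reproduce the targets to better
than 1e−4° before noise.  Filaments are rigid z-stacked copies at the
requested rise and per-step twist.  Because a rigid stack only hydrogen
bonds at the right azimuthal orientation, the monomer is first aligned
strand-axis-to-x and then rotated about x by a deterministic 2° grid
search maximizing interchain hydrogen bonds between z-neighbours (ties
broken by closest donor–acceptor approach).  Bundles place filaments at
explicit lateral offsets/rotations; helper routines bisect the symmetric
bundle radius to a target surface gap (default 0.3 nm — between the
0.05 nm steric-warning limit and the 0.65 nm contact cutoff, so bundles
are contact-connected without collisions).  Solvent beads are placed by
Poisson sampling in the box with minimum-image rejection inside an
exclusion radius (default 0.45 nm) of any solute atom, so the accepted
count is Poisson in the free volume.

Mixture pseudo-trajectories draw each peptide's conformation code
independently from the mixture each frame and rebuild the peptide at the
code's realization centres with Gaussian coordinate noise, σ = 0.01 nm
by default.  On a tripeptide this σ corresponds to ≈10° of dihedral
jitter, which would occasionally carry a residue across a basin edge
(the β centre is 20° from the β/PP_II boundary); the generator therefore
*truncates* the noise by rejection, redrawing any sample whose realized
code or topology group differs from the drawn one.  Drawn label equals
realized label by construction, so mixture recovery is exactly binomial
in the number of peptide × frame observations — which is what the
recovery tests assert.  All randomness flows from explicit integer seeds
through per-run `SeedSequence` spawns; generation is bitwise
reproducible, and distinct runs are independent streams.

What the generator does **not** emulate: physical dynamics or kinetics
(frames are i.i.d., with no temporal correlation), force-field
energetics, sidechain rotamer detail beyond CB, fiber twist (available
but zero by default, with no handedness assertion), and the
conformational heterogeneity of real basins beyond small jitter.
Passing tests therefore demonstrate the *analysis* pipeline's
correctness on data with known ground truth, not the thermodynamics of
real peptide assembly.

## Statistics

Fractions (conformation codes, topology groups) are computed over
peptide × frame observations within each run; the across-run mean and
sample standard deviation (ddof = 1; zero for a single run) provide the
error bars, following the three-independent-runs convention.  Interaction
profiles average per-peptide values over core peptides and frames within
a run before the across-run summary.  Recovery tests use 3 binomial
standard errors of the target weight at the realized observation count.

## Pipeline and reproducibility

A run is fully described by a YAML-serializable config (forge recipe or
input files, region-map override, criteria, cuts, seed, output
directory).  Outputs are CSV/JSON tables plus a provenance record
(config hash, seed, package versions).  Numeric outputs are
byte-identical for identical config + seed; writers strip wall-clock
stamps for that reason.  Report validation re-checks the normalization
invariants (fractions summing to 1) on the written files.

## Problem sizes used in the test suite

Oracle-equivalence suites use ≥100 random instances per kernel.
Mixture-recovery runs use the full study geometry (3 runs × 30 peptides
× 200 frames ≈ 18,000 observations).  Morphology recovery uses a
3 × 6-peptide bundle with σ = 0.01 nm coordinate noise.  The whole suite
completes in well under a minute of CPU time thanks to template caching
in the generator and an atom-index cache in the data model.

## Known limitations

* Only orthorhombic boxes; no triclinic minimum image.
* Antiparallel or out-of-register stacking is not detected as filament.
* The fiber axis is a single straight principal axis; strongly curved
  or branched fibers would need a local-axis formulation.
* π-stacking is approximated by Phe-sidechain contact counts; no
  ring-orientation classifier (with CB-only sidechains none is possible).
* The 48-state count follows from the documented terminal β/PP_II merge;
  alternative reductions consistent with other counts are not provided.
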