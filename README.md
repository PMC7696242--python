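# trifil

Conformational fingerprinting and molecular-packing analysis for
self-assembling capped tripeptides of phenylalanine and isoleucine.

Short hydrophobic peptides such as FFF or FII assemble into nanofibers
built from laterally associated filaments, in which peptide chains stack
through in-register parallel backbone hydrogen bonds at the 4.6–4.9 Å
spacing characteristic of cross-β aggregates.  Understanding *which*
backbone conformation a peptide adopts inside such a fiber, and how its
sidechains arrange at the filament interfaces, is central to designing
peptide nanomaterials.  `trifil` provides the analysis toolchain for
this question, aimed at people who run (or emulate) self-assembly
simulations of capped tripeptides and need reproducible structural
statistics from multi-model PDB/GRO/XTC data.

## What it computes

**Backbone rotamer codes.**  Each residue's (φ, ψ) pair is assigned to
one of four Ramachandran basins — right-handed helical (α_R), left-handed
helical (α_L), extended β, and polyproline II (PP_II) — and a tripeptide
conformation is the ordered triple, e.g. `b-b-b` or `aR-aR-b`.  With the
default merge of the geometrically close β/PP_II basins at the
C-terminal residue the scheme defines 4 × 4 × 3 = **48** distinct codes
(4³ = 64 with the merge disabled).  Populations are reported per run
with mean ± sd across independent runs.

**Sidechain topology.**  The rotation angle θ between adjacent residues
is the torsion C_β(i)–C_α(i)–C_α(i+1)–C_β(i+1).  Two sidechains are
*anti* (opposite backbone faces) when |θ| > 115° and *syn* (same face)
when |θ| < 60°; the pair (θ₁, θ₂) classifies a tripeptide into one of
five groups: all-anti, all-syn, N-syn, C-syn, or "other" for any θ in
the excluded 60–115° band.

**Noncovalent interaction profile.**  Geometric contacts (two particles
within 0.65 nm), hydrogen bonds (donor–acceptor < 0.35 nm and
donor–H–acceptor angle > 120°), and sidechain–water exposure, restricted
to peptides within 1 nm of the fiber axis and normalized per residue
(except hydrogen bonds), over the six families PheSC–W, IleSC–W,
PheSC–PheSC, IleSC–IleSC, PheSC–IleSC, and interchain HB.

**Assembly morphology.**  Aggregates as connected components of the
peptide contact graph; filaments as chains of in-register stacked,
hydrogen-bonded peptides; the adjacent-chain rise in Å; and minimum
Kabsch-RMSD matching of sampled conformers against reference (crystal)
structures over backbone + C_β atoms.

**Synthetic structure generator.**  Because such analyses need inputs,
the package builds capped tripeptides at arbitrary (φ, ψ) targets by
internal-coordinate (NeRF) chain extension, stacks them into filaments
and multi-filament fibers, adds a coarse-water shell, and emits seeded
pseudo-trajectory ensembles whose per-peptide conformations are drawn
from a prescribed mixture — the test bed for every statistic above.

## Worked example

Build a three-filament fiber of extended-strand FFF peptides and recover
its architecture (`examples/04_filament_morphology.py`):

```text
aggregate sizes: [18]
filaments recovered: 3
  members [0, 1, 2, 3, 4, 5]: rise 4.80 +- 0.00 angstrom
  members [6, 7, 8, 9, 10, 11]: rise 4.80 +- 0.00 angstrom
  members [12, 13, 14, 15, 16, 17]: rise 4.80 +- 0.00 angstrom

per-peptide interaction profile (fiber core):
              mean   sd
phe_sc_water  0.78 0.00
ile_sc_water   NaN 0.00
phe_phe       4.11 0.00
ile_ile        NaN 0.00
phe_ile       0.00 0.00
hb            6.67 0.00
```

The 18 peptides form a single aggregate of exactly the three 6-peptide
filaments that were built, at the constructed 4.8 Å rise.  Each core
peptide is involved in ~6.7 interchain hydrogen bonds and ~4.1
Phe–Phe sidechain contacts per Phe residue, while only ~0.8 water beads
touch each Phe sidechain — buried hydrophobic packing.  Ile families are
absent (`NaN`) because the sequence contains no isoleucine.

Recover a 70/30 conformational mixture from a 3-run synthetic ensemble
(`examples/03_mixture_recovery.py`):

```text
         mean_fraction  sd_fraction  n_obs
aR-aR-b         0.3042       0.0057   1369
b-b-b           0.6958       0.0057   3131

most populated conformation: b-b-b at 0.696
```

The other examples cover classification (`01`), the θ taxonomy over all
48 codes (`02`), and reference-structure comparison (`05`).

## Command line

A thin CLI wraps the pipeline for shell use:

```bash
trifil forge --seed 1 --out fixtures/        # synthetic GRO/PDB fixtures
trifil all --config run.yaml                 # full analysis bundle
```

Subcommands `classify`, `topology`, `interactions`, `morphology` and
`report` run individual stages; outputs are CSV/JSON plus a provenance
record, byte-identical under a fixed config and seed.

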