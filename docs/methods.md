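# Methods

## Problem setting

A ligand binds its protein target in one (or a few) *bioactive* conformations.
Conformer generators enumerate low-energy structures without knowledge of the
target, so the bioactive-like members of an ensemble are hidden among up to
250 geometries. The package's goal is to order an ensemble so bioactive-like
conformers (and as few non-bioactive ones as possible) appear in the earliest
ranks, where rigid docking or pharmacophore screening can afford to look.

## Labels: symmetry-aware ARMSD

For two conformations of the same molecule, ARMSD is the heavy-atom RMSD after
the optimal rigid superposition. Two choices matter:

- **Proper rotations only.** The Kabsch fit excludes reflections, so a
  molecule can never be superposed onto its mirror image; chirality is
  preserved. This is asserted in the tests with a chiral tetrahedron.
- **Graph-automorphism minimization.** Topologically equivalent atoms (the
  two oxygens of a nitro group, the two rings of a symmetric biphenyl) must
  not inflate the deviation, so ARMSD is the minimum of the Kabsch RMSD over
  all chirality-respecting automorphisms of the heavy-atom graph. Enumeration
  is capped at 10,000 automorphisms; beyond the cap the minimum over the
  enumerated subset is a best-effort fallback. Automorphisms are enumerated
  as self-substructure matches; the implementation is cross-checked against
  an independent RDKit best-RMS oracle (with terminal-group symmetrization
  disabled, since e.g. carboxyl O/OH are *not* graph-automorphic).

ARMSD_bio is the minimum ARMSD to any known bioactive conformation of the
molecule. Labels use strict thresholds: < 1 Å bioactive-like, > 2.5 Å
non-bioactive, otherwise intermediate; the boundary values are intermediate.

Hydrogens are never read or compared: generators add them for embedding, the
stored geometry and every metric use heavy atoms only.

## Conformer generation

Ensembles come from RDKit's ETKDG (distance geometry with experimental
torsion-knowledge terms), hydrogens added for embedding and stripped after.
The generator's native output order is recorded as `gen_order` and serves as
the "generator order" baseline, standing in for a torsion-likelihood ordering
from knowledge-based generators. Similar conformers are pruned at 0.5 Å by
default; a fixed seed reproduces an ensemble bit for bit. Generated conformers
are not energy-minimized afterwards.

## The atomistic network

The regressor is a SchNet-class, distance-only network:

- learnable embedding per element (vocabulary built from the training set;
  unseen elements raise an error rather than silently extrapolating);
- radial neighbourhood graph: all ordered atom pairs within a cutoff;
- Gaussian radial basis expansion of each edge distance, centres evenly
  spaced on [0, cutoff], width tied to the centre spacing;
- interaction blocks: a two-layer filter network (shifted softplus) maps the
  basis vector to per-edge filters, multiplied by a cosine cutoff envelope;
  filters gate linearly transformed neighbour features, messages are summed
  per atom, passed through an atom-wise two-layer head, and added residually;
- readout: atom-wise two-layer head to one scalar per atom, summed over the
  conformation.

Because only interatomic distances enter, the output is invariant to
translations, rotations, reflections and atom permutations by construction
(asserted to 1e-5), and sum pooling makes disconnected duplicates exactly
additive.

Forward and backward passes are explicit numpy; gradients are verified against
central finite differences to 1e-4 relative on a toy graph. Batched training
concatenates molecules into one disconnected union graph (message passing
cannot cross components, so batching is exact) with sparse-matrix scatter.

**Defaults.** Full preset: 128 features, 6 interaction blocks, 50 basis
functions, 10 Å cutoff, readout hidden 64, Adam with learning rate 1e-5,
batch 32, early stopping patience 5 on validation loss, best-epoch weights
restored. The **desk preset** (used by the reference experiment and the test
suite) shrinks this to 64 features, 3 blocks, 20 basis functions, 5 Å cutoff,
learning rate 1e-3, up to 45-60 epochs: the 5 Å cutoff keeps the edge count —
and with it CPU time — roughly quadratically smaller while still covering
1-4-neighbour geometry, and the larger learning rate suits the much smaller
datasets; with desk-scale epochs the validation loss is noisy, so the
reference experiment extends the patience to 15 epochs. Targets are used in Å;
an optional flag standardizes them during fitting (the desk experiment
enables it).

## Rankers

All rankers emit a permutation of the ensemble; ties are always broken by
generation order (stable), so every ranking is reproducible.

- **Random**: one standard-normal draw per conformer, ascending; seeded.
- **Generator order**: ascending `gen_order`.
- **Energy**: ascending single-point potential energy, hydrogens added at
  standard geometry first; MMFF94 with UFF fallback. Only the within-molecule
  ordering matters, so the force field is configurable; molecules that cannot
  be typed are skipped individually.
- **SASA**: descending solvent-accessible surface area (probe 1.4 Å, heavy
  atoms, standard radii).
- **RGyr**: descending mass-weighted radius of gyration.
- **TFD2SimRefMCS** (bioactivity-based): nearest reference by Tanimoto of
  chirality-aware Morgan fingerprints (radius 3, ties to the
  lexicographically first id) → chirality-respecting MCS (10 s time cap,
  best-so-far on timeout) → torsion fingerprint deviation computed only over
  torsions whose four atoms all lie in the MCS, against the reference's first
  bioactive conformation → ascending. Torsion definitions and centrality
  weights come from the whole test molecule and are then restricted to the
  MCS; per torsion the deviation is the minimum over symmetric quadruple
  representations of the wrapped angular difference, normalized by the
  torsion's maximal deviation, aggregated as a weight-normalized mean in
  [0, 1]. If no torsion lies in the MCS, the ranker falls back to generator
  order and flags the molecule.
- **Oracle**: ascending true ARMSD_bio; per molecule this maximizes
  BEDROC_bio-like and minimizes BEDROC_non-bio over all permutations, so it is
  the attainable ceiling for any ranking method.
- **AtNN**: ascending predicted ARMSD_bio from the trained network.

## Evaluation

BEDROC (discrete Truchon–Bayly formulation) with α = 20: the top 8% of ranks
carry 80% of the exponential weight mass. BEDROC_bio-like treats
bioactive-like conformers as positives; BEDROC_non-bio treats non-bioactive
conformers as positives (low values mean early *impoverishment*, which is
desirable). Intermediate conformers count as negatives on both sides. A side
with no positives or no negatives is undefined and recorded as missing, never
as zero, to keep medians unbiased. Values are clipped to [0, 1] against
floating-point overshoot.

Molecules enter the ranking evaluation only when ranking can help: at least
one but not only bioactive-like conformers. Ranks are 1-based and scaled by
the ensemble size into (0, 1]. The *hard subset* flags molecules with a full
ensemble (250 by default) and under 5% bioactive-like conformers. Medians are
taken per split over eligible molecules, then mean ± sd across split
replicates. Top-fraction selection takes ceil(fraction × n), at least one.

## Splitting

Random split: shuffle unique molecules, slice 80/10/10 (floors, remainder to
test). Scaffold split: Bemis–Murcko scaffold (whole molecule for acyclic
compounds, avoiding a degenerate empty-scaffold cluster), Morgan fingerprint
radius 3 of the scaffold, complete-linkage agglomerative clustering on
Tanimoto distance cut at 0.5 — complete linkage is the linkage under which
that cut provably guarantees ≥ 50% similarity within every cluster — and
whole clusters are poured into train until the cumulative conformation count
reaches 80%, then val to 90%, remainder test. Five replicate seeds per split
type by default.

## Synthetic benchmark design

The generator emulates a curated structure dataset without any external data.
Every molecule gets an ETKDG ensemble; its "bioactive" reference is a
torsion-jittered copy of a generated conformer (small jitter ≈ 3° per
rotatable torsion plus 0.02 Å Cartesian noise), so the reference provably sits
within jitter range of the ensemble. With probability 1 −
`target_frac_with_bio_like` (default 0.8) the jitter is large (120°), pushing
the reference away from the whole ensemble and yielding a molecule without
bioactive-like conformers — emulating the ~80% retrieval rate of real
generators. A molecule can carry one or two references (70/30 by default),
and ARMSD_bio is the minimum over them.

**Family mode** builds series of molecules sharing a ≥ 20-heavy-atom
flexible-linker core, decorated with varied peripheral substituents. The
first member's reference fixes the family's core torsion pattern; every other
member's reference starts from its ensemble conformer closest to that pattern
and has its core torsions snapped exactly onto it, so bioactive core geometry
is consistent family-wide — the property that gives substructure-based
methods (MCS/TFD) and trained networks their signal, mirroring congeneric
series in curated datasets. Because the snapped reference leaves the sampled
manifold, the generator's retrieval of the bioactive conformation is emulated
by replacing a few ensemble slots with jittered copies of the reference at
increasing amplitudes (3°-90°), which restores a continuum of ARMSD_bio
values from the bioactive-like regime through intermediate to non-bioactive.
Molecules that still end up without the requested label mix are regenerated up
to three times, then flagged.

What the synthetic data does **not** emulate: docked poses, protein pockets,
binding-induced strain, crystallographic noise, or any relationship between
chemistry and target class beyond family membership. Passing tests therefore
demonstrate that the machinery ranks correctly when a consistent bioactive
geometry exists within a series — not that any particular enrichment level
transfers to real protein–ligand data.

## The reference experiment

`confrank.experiments.family_ranking_experiment` runs the full pipeline at
desk scale: 56 molecules in 4 families, ensembles of up to 40 conformers,
random 80/10/10 split, desk-preset network (≤ 45 epochs, patience 15,
standardized targets), all rankers on eligible held-out molecules. These sizes
keep the complete run within minutes on a single CPU while leaving every
family with held-out members that share their core with training molecules.
Expected qualitative ordering: oracle ≥ TFD2SimRefMCS > trained network >
bioactivity-unaware baselines on median BEDROC_bio-like, with the oracle
lowest on BEDROC_non-bio.

## Numerical choices and edge cases

- Kabsch via SVD with determinant correction; RMSD differences below 1e-9 Å
  are treated as exact in tests.
- Degenerate geometries: single-atom graphs are valid (zero edges); a
  single-conformer ensemble ranks trivially.
- BEDROC requires at least one positive and one negative; otherwise an
  undefined-metric signal is raised and recorded as missing.
- R² is undefined for zero-variance truths and raises.
- Dihedrals use the standard praxeolitic formula and match RDKit's sign
  convention; angular differences are wrapped to [0°, 180°].
- All randomness flows from explicit integer seeds (numpy Generators; RDKit
  embedding seeds); the CLI fans one master seed out per stage by hashing the
  stage name.

## Known limitations

- Only the distance-based architecture is implemented; the model interface
  (graph in, scalar out) admits angle- and torsion-aware backbones later.
- The automorphism cap makes ARMSD a best-effort bound on pathologically
  symmetric graphs.
- The TFD restriction uses whole-molecule torsion weights limited to MCS
  torsions; recomputing weights on the MCS subgraph would be an alternative
  reading.
- Training is single-device, full numpy; it is intended for desk-scale
  benchmarks, not for datasets of millions of conformers.
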