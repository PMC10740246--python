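# confrank

Rank generated conformer ensembles towards bioactive-like conformations.

Conformer generators produce up to hundreds of low-energy 3D structures per
ligand, but virtual-screening workflows (rigid docking, pharmacophore
searching) can only afford a handful — ideally the ones resembling the
conformation the ligand adopts when bound to its protein target. `confrank`
implements a complete benchmark-and-ranking framework for this problem, aimed
at computational chemists evaluating conformer selection strategies:

- **Labelling.** Every generated conformer gets an ARMSD_bio value: the
  heavy-atom RMSD, after optimal rigid superposition (Kabsch, proper rotations
  only) minimized over chirality-respecting graph automorphisms, to the
  closest known bioactive conformation of its molecule. Conformers with
  ARMSD_bio < 1 Å are *bioactive-like*, > 2.5 Å *non-bioactive*, in between
  *intermediate*.
- **Model.** A distance-only atomistic neural network (SchNet-class: element
  embedding, radial-basis distance encoding, continuous-filter convolution
  interaction blocks, atom-wise readout summed per conformation) regresses
  ARMSD_bio from the raw heavy-atom point cloud — no bond information. The
  network and its analytic backpropagation are implemented in numpy and
  exposed as a scikit-learn style estimator (`SchNetRegressor`, with
  `fit`/`predict`/`get_params`).
- **Baselines.** Five bioactivity-unaware rankers (random scores, generator
  output order, ascending force-field energy, descending SASA, descending
  radius of gyration) and a bioactivity-based ranker, **TFD2SimRefMCS**:
  nearest reference molecule by Tanimoto of chirality-aware Morgan
  fingerprints (radius 3), maximum common substructure with chirality
  matching, then torsion fingerprint deviation over MCS torsions to the
  reference's bioactive conformation.
- **Evaluation.** Early enrichment via BEDROC (Truchon–Bayly, α = 20, so the
  top 8% of ranks carry 80% of the score), scaled first ranks, eligibility
  and hard-subset filters, per-split medians, random and Bemis–Murcko
  scaffold-cluster splits (80/10/10).
- **Synthetic benchmarks.** A generator of fully self-contained datasets:
  drug-like molecules with ETKDG ensembles and designated "bioactive"
  references, including family mode (groups sharing a ≥ 20-heavy-atom core),
  so the whole pipeline is testable without any proprietary data.

## Worked example

```python
from confrank import (SyntheticSpec, make_benchmark, bedroc_pair,
                      eligible_for_ranking)
from confrank.baselines import TFD2SimRefMCSRanker

data = make_benchmark(SyntheticSpec(n_molecules=8, max_conformers=20,
                                    family_structure=True,
                                    members_per_family=4, seed=7))
ens = next(e for e in data.ensembles.values() if eligible_for_ranking(e))
print(ens.mol_id, ens.n_conformers, ens.n_bio_like, round(float(ens.armsd_bio.min()), 2))
```

prints

```
fam0_m1 19 4 0.17
```

— this family member has a 19-conformer ensemble whose closest conformer sits
0.17 Å from the bioactive reference; four conformers are bioactive-like, so
the molecule is eligible for ranking. Ranking it with the bioactivity-based
baseline fitted on the other family members:

```python
refs = [e for e in data.ensembles.values() if e.mol_id != ens.mol_id]
result = TFD2SimRefMCSRanker().fit(refs).rank(ens)
print(result.order[:5], [round(float(s), 3) for s in result.scores[:5]])
print(bedroc_pair(result, ens))
```

```
[12, 8, 17, 7, 14] [0.015, 0.026, 0.034, 0.085, 0.112]
(0.982, 0.001)
```

The conformers with the lowest torsion deviation to the reference's bioactive
conformation (scores 0.015-0.112) fill the early ranks and are the
bioactive-like ones: BEDROC_bio-like is 0.98 (near-perfect early enrichment)
and BEDROC_non-bio is 0.001 (non-bioactive conformers pushed to late ranks).

A full comparison of all rankers — including a desk-scale trained network — is
one call:

```python
from confrank.experiments import family_ranking_experiment
result = family_ranking_experiment(seed=7)   # ~10 min on one CPU
print(result.median_bedroc_bio)
```

Output with seed 7 (56 molecules, 4 families, held-out test members; median
BEDROC_bio-like): oracle 1.00, TFD2SimRefMCS 0.97, trained network 0.22,
generator order 0.22, random 0.01, energy/SASA/RGyr 0.00 — bioactivity-based
ranking far ahead of bioactivity-unaware baselines, with the true-label oracle
as the ceiling; on BEDROC_non-bio the oracle (0.00) and TFD2SimRefMCS (0.02)
also push undesirable conformers latest.

## Command-line pipeline

```bash
confrank synth --seed 1 --out run/        # synthetic benchmark -> SDF/TSV
confrank split --out run/                 # random or scaffold splits
confrank train --out run/ --preset desk   # train the network, save checkpoint
confrank rank  --out run/                 # all rankers on test ensembles
confrank evaluate --out run/              # per-molecule report + split summary
```

Stages for curating real data (`curate`, `generate`, `label`) read SDF
structures plus a TSV of reference SMILES and reproduce the standardization /
chirality-aware reference-matching logic, dropping unmatched ligands
per-molecule.

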