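"""Train/validation/test partitioning of molecules.

Two strategies are provided.  The random split shuffles unique molecules and
slices them 80/10/10.  The scaffold split groups molecules by Bemis–Murcko
scaffold similarity — circular fingerprints of radius 3 on the scaffold,
complete-linkage agglomerative clustering on Tanimoto distance cut at 0.5, so
every within-cluster pair is at least 50% similar — and assigns whole clusters
to subsets, weighting each cluster by its conformation count so that the train
subset covers about 80% of all conformations.  Scaffold splits probe
generalization to unseen chemotypes: no cluster ever spans two subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.DataStructs import TanimotoSimilarity
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structures import MoleculeRecord

__all__ = ["SplitAssignment", "random_split", "scaffold_split", "write_split_table"]

_SUBSETS = ("train", "val", "test")


@dataclass
class SplitAssignment:
    split_type: str  # "random" | "scaffold"
    seed: int
    assignment: dict[str, str]  # mol_id -> subset

    def subset(self, name: str) -> list[str]:
        return [m for m, s in self.assignment.items() if s == name]


def random_split(
    mol_ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Shuffle molecules and slice by cumulative ratio (remainder to test)."""
    if len(mol_ids) < 3:
        raise ValueError("need at least 3 molecules to split")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    order = list(mol_ids)
    rng.shuffle(order)
    n = len(order)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    assignment = {}
    for i, mol_id in enumerate(order):
        if i < n_train:
            assignment[mol_id] = "train"
        elif i < n_train + n_val:
            assignment[mol_id] = "val"
        else:
            assignment[mol_id] = "test"
    return SplitAssignment(split_type="random", seed=seed, assignment=assignment)


_fp_generator = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)


def murcko_scaffold(mol: Chem.Mol) -> Chem.Mol:
    """Bemis–Murcko scaffold; acyclic molecules fall back to the whole molecule."""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return mol
    return scaffold


def scaffold_clusters(mols: Sequence[MoleculeRecord], max_distance: float = 0.5) -> list[int]:
    """Cluster molecules on scaffold-fingerprint Tanimoto similarity.

    Complete linkage cut at ``max_distance`` guarantees all within-cluster
    pairwise similarities are >= 1 - max_distance.
    """
    fps = [_fp_generator.GetFingerprint(murcko_scaffold(rec.mol)) for rec in mols]
    n = len(fps)
    if n == 1:
        return [0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - TanimotoSimilarity(fps[i], fps[j])
            dist[i, j] = dist[j, i] = d
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=max_distance, criterion="distance")
    return [int(x) - 1 for x in labels]


def scaffold_split(
    mols: Sequence[MoleculeRecord],
    weights: Mapping[str, int],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Whole-cluster assignment weighted by per-molecule conformation counts.

    Clusters are shuffled by seed and poured into train until the cumulative
    conformation count reaches ``ratios[0]`` of the total, then into val until
    ``ratios[0] + ratios[1]``, remainder to test.
    """
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    labels = scaffold_clusters(mols)
    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(idx)
    cluster_ids = sorted(clusters)
    rng = np.random.default_rng(seed)
    rng.shuffle(cluster_ids)
    total = float(sum(weights[rec.mol_id] for rec in mols))
    assignment: dict[str, str] = {}
    cum = 0.0
    stage = 0  # 0 -> train, 1 -> val, 2 -> test
    boundaries = (ratios[0] * total, (ratios[0] + ratios[1]) * total)
    for cid in cluster_ids:
        if stage < 2 and cum >= boundaries[stage]:
            stage += 1
        subset = _SUBSETS[stage]
        for idx in clusters[cid]:
            assignment[mols[idx].mol_id] = subset
            cum += weights[mols[idx].mol_id]
    return SplitAssignment(split_type="scaffold", seed=seed, assignment=assignment)


def write_split_table(splits: Sequence[SplitAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mol_id\tsplit_type\tseed\tsubset\n")
        for split in splits:
            for mol_id, subset in split.assignment.items():
                fh.write(f"{mol_id}\t{split.split_type}\t{split.seed}\t{subset}\n")
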