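"""Conformer generation, symmetry-aware ARMSD, and ensemble labelling.

The central quantity is ARMSD_bio: a generated conformer's heavy-atom RMSD,
after optimal rigid superposition, to the closest known bioactive conformation
of its molecule.  The superposition uses the Kabsch algorithm restricted to
proper rotations (no reflections, so chirality is preserved) and the RMSD is
minimized over the chirality-respecting automorphisms of the heavy-atom graph,
so that topologically equivalent atoms (e.g. the two oxygens of a carboxylate)
do not inflate the deviation.

Conformers with ARMSD_bio below 1 Å are labelled bioactive-like, above 2.5 Å
non-bioactive, and in between intermediate (both thresholds strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import ConfrankError, DimensionError, GenerationError
from .structures import MoleculeRecord

__all__ = [
    "ConformerRecord",
    "LabelledEnsemble",
    "BIO_LIKE_THRESHOLD",
    "NON_BIO_THRESHOLD",
    "generate_conformers",
    "kabsch_rmsd",
    "graph_automorphisms",
    "armsd",
    "armsd_bio",
    "classify_conformer",
    "build_labelled_ensemble",
    "write_ensemble_sdf",
    "read_ensemble_sdf",
    "write_label_table",
]

#: Strict upper bound (Å) for the bioactive-like label.
BIO_LIKE_THRESHOLD = 1.0
#: Strict lower bound (Å) for the non-bioactive label.
NON_BIO_THRESHOLD = 2.5

#: Cap on enumerated graph automorphisms before falling back to the best match
#: found so far.
MAX_AUTOMORPHISMS = 10_000


@dataclass
class ConformerRecord:
    """One 3D heavy-atom geometry of a molecule with its provenance."""

    mol_id: str
    conf_id: int
    coords: np.ndarray  # (N, 3) Å, heavy atoms only
    source: str = "generated"  # or "bioactive"
    gen_order: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DimensionError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ConfrankError(f"{self.mol_id}/{self.conf_id}: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


def generate_conformers(
    record: MoleculeRecord,
    max_n: int = 250,
    seed: int = 0,
    prune_rms_thresh: float = 0.5,
) -> list[ConformerRecord]:
    """Generate up to ``max_n`` conformers with a knowledge-based DG embedder.

    Uses ETKDG (distance geometry with experimental-torsion terms).  Hydrogens
    are added for embedding and stripped from the stored coordinates.  The
    generator's native output order is recorded as ``gen_order`` and stands in
    for a torsion-likelihood ordering.  Similar conformers are pruned at
    ``prune_rms_thresh`` Å, so rigid molecules yield small ensembles.  The same
    seed reproduces the same ensemble bit for bit.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    n_heavy = record.mol.GetNumAtoms()
    molh = Chem.AddHs(Chem.Mol(record.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = float(prune_rms_thresh)
    params.numThreads = 1
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=int(max_n), params=params)
    if len(conf_ids) == 0:
        raise GenerationError(f"{record.mol_id}: embedding failed for all attempts")
    out: list[ConformerRecord] = []
    for order, cid in enumerate(conf_ids):
        pos = molh.GetConformer(cid).GetPositions()[:n_heavy]  # AddHs appends H last
        out.append(
            ConformerRecord(
                mol_id=record.mol_id,
                conf_id=order,
                coords=np.array(pos, dtype=float),
                source="generated",
                gen_order=order,
            )
        )
    return out


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Heavy-atom RMSD of ``p`` onto ``q`` after optimal proper-rotation fit.

    Both inputs are (N, 3); reflections are excluded so the fit cannot turn a
    molecule into its mirror image.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise DimensionError(f"shape mismatch {p.shape} vs {q.shape}")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # enforce det(R) = +1
    e = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(e) @ u.T
    diff = pc @ rot.T - qc
    return float(np.sqrt((diff**2).sum() / p.shape[0]))


def graph_automorphisms(
    mol: Chem.Mol, max_automorphisms: int = MAX_AUTOMORPHISMS
) -> list[tuple[int, ...]]:
    """Chirality-respecting automorphisms of the heavy-atom graph.

    Enumeration is capped; pathological highly symmetric graphs return the
    first ``max_automorphisms`` permutations found (a heuristic best-match
    fallback rather than an exhaustive search).
    """
    matches = mol.GetSubstructMatches(
        mol, uniquify=False, useChirality=True, maxMatches=max_automorphisms
    )
    if not matches:
        return [tuple(range(mol.GetNumAtoms()))]
    return list(matches)


def armsd(
    a: ConformerRecord,
    b: ConformerRecord,
    mol: Chem.Mol | None = None,
    automorphisms: Sequence[tuple[int, ...]] | None = None,
) -> float:
    """Symmetry-aware overlaid heavy-atom RMSD between two conformations.

    Minimum over graph automorphisms sigma of the Kabsch RMSD between ``a``
    and ``b`` re-indexed by sigma.  Pass ``mol`` (or a precomputed
    ``automorphisms`` list) to enable the symmetry correction; otherwise only
    the identity mapping is used.
    """
    if a.n_atoms != b.n_atoms:
        raise DimensionError(
            f"atom count mismatch: {a.n_atoms} vs {b.n_atoms}"
        )
    if automorphisms is None:
        automorphisms = graph_automorphisms(mol) if mol is not None else [tuple(range(a.n_atoms))]
    best = np.inf
    for perm in automorphisms:
        val = kabsch_rmsd(a.coords, b.coords[list(perm)])
        if val < best:
            best = val
    return float(best)


def armsd_bio(
    conf: ConformerRecord,
    bioactive: Sequence[ConformerRecord],
    mol: Chem.Mol | None = None,
    automorphisms: Sequence[tuple[int, ...]] | None = None,
) -> float:
    """ARMSD to the closest bioactive conformation."""
    if not bioactive:
        raise ValueError("bioactive list must be non-empty")
    return min(armsd(conf, b, mol=mol, automorphisms=automorphisms) for b in bioactive)


def classify_conformer(
    value: float,
    bio_like_threshold: float = BIO_LIKE_THRESHOLD,
    non_bio_threshold: float = NON_BIO_THRESHOLD,
) -> str:
    """Label an ARMSD_bio value: bio_like (< 1 Å), non_bio (> 2.5 Å), else intermediate."""
    if value < 0:
        raise ValueError(f"ARMSD_bio must be non-negative, got {value}")
    if value < bio_like_threshold:
        return "bio_like"
    if value > non_bio_threshold:
        return "non_bio"
    return "intermediate"


@dataclass
class LabelledEnsemble:
    """A molecule's generated conformers with ARMSD_bio values and labels."""

    mol_id: str
    mol: Chem.Mol
    conformers: list[ConformerRecord]
    bioactive: list[ConformerRecord]
    armsd_bio: np.ndarray = field(default_factory=lambda: np.empty(0))
    labels: list[str] = field(default_factory=list)

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    @property
    def n_bio_like(self) -> int:
        return sum(1 for lab in self.labels if lab == "bio_like")

    @property
    def n_non_bio(self) -> int:
        return sum(1 for lab in self.labels if lab == "non_bio")

    @property
    def frac_bio_like(self) -> float:
        return self.n_bio_like / self.n_conformers if self.n_conformers else 0.0

    @property
    def bioactive_retrieved(self) -> bool:
        """True when at least one generated conformer is within 1 Å of a reference."""
        return bool(self.armsd_bio.size) and float(self.armsd_bio.min()) < BIO_LIKE_THRESHOLD

    @property
    def gen_orders(self) -> np.ndarray:
        return np.array(
            [c.gen_order if c.gen_order is not None else i for i, c in enumerate(self.conformers)]
        )


def build_labelled_ensemble(
    record: MoleculeRecord,
    generated: Sequence[ConformerRecord],
    bioactive: Sequence[ConformerRecord],
    bio_like_threshold: float = BIO_LIKE_THRESHOLD,
    non_bio_threshold: float = NON_BIO_THRESHOLD,
) -> LabelledEnsemble:
    """Compute ARMSD_bio and class labels for every generated conformer."""
    if not generated:
        raise ValueError(f"{record.mol_id}: generated list must be non-empty")
    if not bioactive:
        raise ValueError(f"{record.mol_id}: bioactive list must be non-empty")
    autos = graph_automorphisms(record.mol)
    values = np.array(
        [armsd_bio(c, bioactive, automorphisms=autos) for c in generated], dtype=float
    )
    labels = [
        classify_conformer(v, bio_like_threshold, non_bio_threshold) for v in values
    ]
    return LabelledEnsemble(
        mol_id=record.mol_id,
        mol=record.mol,
        conformers=list(generated),
        bioactive=list(bioactive),
        armsd_bio=values,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# SDF / TSV interchange


def _mol_with_coords(mol: Chem.Mol, coords: np.ndarray) -> Chem.Mol:
    out = Chem.Mol(mol)
    conf = Chem.Conformer(out.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    out.RemoveAllConformers()
    out.AddConformer(conf, assignId=True)
    return out


def write_ensemble_sdf(ensembles: Iterable[LabelledEnsemble], path: str | Path) -> None:
    """One SDF record per conformer, with provenance and labels as properties."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for ens in ensembles:
        have_labels = len(ens.labels) == len(ens.conformers)
        for k, conf in enumerate(list(ens.conformers) + list(ens.bioactive)):
            mol = _mol_with_coords(ens.mol, conf.coords)
            mol.SetProp("_Name", f"{ens.mol_id}_{conf.source}_{conf.conf_id}")
            mol.SetProp("mol_id", ens.mol_id)
            mol.SetIntProp("conf_id", int(conf.conf_id))
            mol.SetProp("source", conf.source)
            if conf.gen_order is not None:
                mol.SetIntProp("gen_order", int(conf.gen_order))
            if conf.source == "generated" and have_labels and k < len(ens.conformers):
                mol.SetDoubleProp("armsd_bio", float(ens.armsd_bio[k]))
                mol.SetProp("label", ens.labels[k])
            writer.write(mol)
    writer.close()


def read_ensemble_sdf(path: str | Path) -> list[LabelledEnsemble]:
    """Read ensembles written by :func:`write_ensemble_sdf` (labels optional)."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    by_mol: dict[str, dict] = {}
    for mol in supplier:
        if mol is None:
            continue
        mol_id = mol.GetProp("mol_id")
        entry = by_mol.setdefault(
            mol_id, {"mol": None, "generated": [], "bioactive": [], "armsd": {}, "label": {}}
        )
        if entry["mol"] is None:
            template = Chem.Mol(mol)
            template.RemoveAllConformers()
            entry["mol"] = template
        conf = ConformerRecord(
            mol_id=mol_id,
            conf_id=mol.GetIntProp("conf_id"),
            coords=np.array(mol.GetConformer().GetPositions(), dtype=float),
            source=mol.GetProp("source"),
            gen_order=mol.GetIntProp("gen_order") if mol.HasProp("gen_order") else None,
        )
        if conf.source == "bioactive":
            entry["bioactive"].append(conf)
        else:
            entry["generated"].append(conf)
            if mol.HasProp("armsd_bio"):
                entry["armsd"][conf.conf_id] = mol.GetDoubleProp("armsd_bio")
                entry["label"][conf.conf_id] = mol.GetProp("label")
    out = []
    for mol_id, entry in by_mol.items():
        gen = entry["generated"]
        values = np.array([entry["armsd"].get(c.conf_id, np.nan) for c in gen])
        labels = [entry["label"].get(c.conf_id, "") for c in gen]
        if any(not lab for lab in labels):
            values, labels = np.empty(0), []
        out.append(
            LabelledEnsemble(
                mol_id=mol_id,
                mol=entry["mol"],
                conformers=gen,
                bioactive=entry["bioactive"],
                armsd_bio=values,
                labels=labels,
            )
        )
    return out


def write_label_table(ensembles: Iterable[LabelledEnsemble], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mol_id\tconf_id\tgen_order\tarmsd_bio\tlabel\n")
        for ens in ensembles:
            for conf, val, lab in zip(ens.conformers, ens.armsd_bio, ens.labels):
                fh.write(
                    f"{ens.mol_id}\t{conf.conf_id}\t{conf.gen_order}\t{val:.6f}\t{lab}\n"
                )
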