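"""Conformer ranking baselines.

Five bioactivity-unaware rankers — random scores, generator output order,
ascending force-field energy, descending solvent-accessible surface area,
descending radius of gyration — and one bioactivity-based ranker,
TFD2SimRefMCS, which finds the most similar molecule in a reference set
(Tanimoto on chirality-aware circular fingerprints, radius 3), computes the
chirality-respecting maximum common substructure, and ranks conformers by the
torsion fingerprint deviation over MCS torsions to the reference's bioactive
conformation.  The oracle ranker (true ARMSD_bio, ascending) bounds what any
ranking method can achieve and is used for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, TorsionFingerprints, rdFingerprintGenerator, rdFMCS, rdFreeSASA
from rdkit.DataStructs import TanimotoSimilarity

from .conformers import ConformerRecord, LabelledEnsemble
from .errors import ConfrankError
from .ranking import ConformerRanker, RankingResult, order_by_scores

__all__ = [
    "RankingSkip",
    "McsMatch",
    "RandomRanker",
    "GeneratorOrderRanker",
    "EnergyRanker",
    "SasaRanker",
    "RGyrRanker",
    "TFD2SimRefMCSRanker",
    "AtNNRanker",
    "OracleRanker",
    "find_nearest_reference",
    "mcs",
    "tfd_mcs",
    "match_conformers_by_mcs_torsions",
    "thermal_energy_window",
    "default_rankers",
    "write_ranking_table",
]

BOLTZMANN_KCAL = 1.987e-3  # kcal / (mol K)


class RankingSkip(ConfrankError):
    """A ranker cannot handle this molecule (e.g. force-field typing failure)."""


# ---------------------------------------------------------------------------
# Bioactivity-unaware rankers


class RandomRanker(ConformerRanker):
    """Standard-normal score per conformer, ascending; seeded."""

    name = "random"

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def score(self, ensemble: LabelledEnsemble) -> np.ndarray:
        return self.rng.standard_normal(ensemble.n_conformers)


class GeneratorOrderRanker(ConformerRanker):
    """Keep the conformer generator's native output order."""

    name = "generator_order"

    def score(self, ensemble: LabelledEnsemble) -> np.ndarray:
        orders = [c.gen_order for c in ensemble.conformers]
        if any(o is None for o in orders):
            raise ValueError(f"{ensemble.mol_id}: conformers lack gen_order")
        return np.asarray(orders, dtype=float)


def _mol_with_conformer(mol: Chem.Mol, record: ConformerRecord) -> Chem.Mol:
    out = Chem.Mol(mol)
    conf = Chem.Conformer(out.GetNumAtoms())
    for i, xyz in enumerate(record.coords):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    out.RemoveAllConformers()
    out.AddConformer(conf, assignId=True)
    return out


class EnergyRanker(ConformerRanker):
    """Ascending single-point potential energy (MMFF94, UFF fallback).

    Hydrogens are added at standard geometry before the evaluation; the score
    only has to order conformers of the same molecule, so the force-field
    choice is configurable rather than fixed.
    """

    name = "energy"

    def __init__(self, forcefield: str = "mmff"):
        self.forcefield = forcefield

    def _energy(self, mol: Chem.Mol, record: ConformerRecord) -> float:
        molh = Chem.AddHs(_mol_with_conformer(mol, record), addCoords=True)
        if self.forcefield == "mmff":
            props = AllChem.MMFFGetMoleculeProperties(molh)
            if props is not None:
                ff = AllChem.MMFFGetMoleculeForceField(molh, props)
                if ff is not None:
                    return float(ff.CalcEnergy())
        ff = AllChem.UFFGetMoleculeForceField(molh)
        if ff is None:
            raise RankingSkip(f"{record.mol_id}: force-field typing failed")
        return float(ff.CalcEnergy())

    def score(self, ensemble: LabelledEnsemble) -> np.ndarray:
        return np.array([self._energy(ensemble.mol, c) for c in ensemble.conformers])


class SasaRanker(ConformerRanker):
    """Descending solvent-accessible surface area (probe 1.4 Å, heavy atoms)."""

    name = "sasa"
    direction = "descending"

    def score(self, ensemble: LabelledEnsemble) -> np.ndarray:
        values = []
        for c in ensemble.conformers:
            mol = _mol_with_conformer(ensemble.mol, c)
            radii = rdFreeSASA.classifyAtoms(mol)
            values.append(float(rdFreeSASA.CalcSASA(mol, radii)))
        return np.array(values)


class RGyrRanker(ConformerRanker):
    """Descending mass-weighted radius of gyration over heavy atoms."""

    name = "rgyr"
    direction = "descending"

    def score(self, ensemble: LabelledEnsemble) -> np.ndarray:
        masses = np.array([a.GetMass() for a in ensemble.mol.GetAtoms()])
        values = []
        for c in ensemble.conformers:
            com = (masses[:, None] * c.coords).sum(0) / masses.sum()
            r2 = ((c.coords - com) ** 2).sum(1)
            values.append(float(np.sqrt((masses * r2).sum() / masses.sum())))
        return np.array(values)


# ---------------------------------------------------------------------------
# MCS / TFD machinery for the bioactivity-based ranker


@dataclass
class McsMatch:
    """Maximum common substructure between a test molecule and a reference."""

    reference_mol_id: str
    pairs: list[tuple[int, int]]  # (test_atom, ref_atom)
    n_heavy: int
    torsions: list[tuple[int, int, int, int]] = field(default_factory=list)
    timed_out: bool = False


_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=3, fpSize=2048, includeChirality=True
)


def morgan_fingerprint(mol: Chem.Mol):
    return _fp_generator.GetFingerprint(mol)


def find_nearest_reference(test_mol: Chem.Mol, reference_set: Sequence[tuple[str, Chem.Mol]]) -> str:
    """mol_id of the reference with the highest Tanimoto similarity.

    Ties (including all-zero overlap) go to the lexicographically first id.
    """
    if not reference_set:
        raise ValueError("reference set must be non-empty")
    fp = morgan_fingerprint(test_mol)
    best_id, best_sim = None, -1.0
    for mol_id, ref in sorted(reference_set, key=lambda pair: pair[0]):
        sim = TanimotoSimilarity(fp, morgan_fingerprint(ref))
        if sim > best_sim:
            best_id, best_sim = mol_id, sim
    return best_id


def mcs(
    test_mol: Chem.Mol,
    ref_mol: Chem.Mol,
    ref_mol_id: str = "",
    timeout: int = 10,
) -> McsMatch:
    """Element-, bond-order- and chirality-respecting MCS with atom mapping."""
    result = rdFMCS.FindMCS(
        [test_mol, ref_mol],
        matchChiralTag=True,
        timeout=timeout,
    )
    if result.numAtoms == 0 or not result.smartsString:
        return McsMatch(ref_mol_id, [], 0, timed_out=result.canceled)
    query = Chem.MolFromSmarts(result.smartsString)
    test_match = test_mol.GetSubstructMatch(query)
    ref_match = ref_mol.GetSubstructMatch(query)
    if not test_match or not ref_match:
        return McsMatch(ref_mol_id, [], 0, timed_out=result.canceled)
    pairs = sorted(zip(test_match, ref_match))
    match = McsMatch(ref_mol_id, pairs, len(pairs), timed_out=result.canceled)
    entries, _ = _mcs_torsion_entries(test_mol, match)
    match.torsions = [quad for quads, _ in entries for quad in quads]
    return match


def _mcs_torsion_entries(test_mol: Chem.Mol, match: McsMatch):
    """Test-side torsion entries fully contained in the MCS, with TFD weights.

    Torsion definitions and topological-centrality weights come from the whole
    test molecule (standard TFD); entries are then restricted to the
    alternative atom quadruples whose four atoms all lie in the MCS.
    """
    in_mcs = {t for t, _ in match.pairs}
    tl, tlr = TorsionFingerprints.CalculateTorsionLists(test_mol)
    try:
        weights = TorsionFingerprints.CalculateTorsionWeights(test_mol)
    except Exception:  # single-torsion molecules have no weights
        weights = [1.0] * (len(tl) + len(tlr))
    entries = []
    kept_weights = []
    for (quads, maxdev), w in zip(list(tl) + list(tlr), weights):
        kept = [q for q in quads if all(a in in_mcs for a in q)]
        if kept:
            maxdev_val = 180.0 if maxdev == 180.0 else float(maxdev)
            entries.append((kept, maxdev_val))
            kept_weights.append(float(w))
    return entries, np.array(kept_weights, dtype=float)


def dihedral_deg(coords: np.ndarray, quad: Sequence[int]) -> float:
    """Signed dihedral angle (degrees) of four atoms in a coordinate array."""
    p0, p1, p2, p3 = (coords[i] for i in quad)
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _angle_diff_deg(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def tfd_mcs(
    test_conf: ConformerRecord,
    ref_conf: ConformerRecord,
    match: McsMatch,
    test_mol: Chem.Mol,
) -> float:
    """Torsion fingerprint deviation restricted to MCS torsions, in [0, 1].

    Per torsion: minimum over symmetric atom-quadruple representations of the
    wrapped angular difference, normalized by the torsion's maximal deviation;
    aggregated as a weight-normalized sum.  Zero iff every MCS torsion agrees.
    """
    entries, weights = _mcs_torsion_entries(test_mol, match)
    if not entries:
        raise RankingSkip(f"{test_conf.mol_id}: no torsion lies inside the MCS")
    ref_index = dict(match.pairs)
    deviations = []
    kept_w = []
    for (quads, maxdev), w in zip(entries, weights):
        devs = []
        for quad in quads:
            ref_quad = [ref_index[a] for a in quad]
            da = dihedral_deg(test_conf.coords, quad)
            db = dihedral_deg(ref_conf.coords, ref_quad)
            devs.append(_angle_diff_deg(da, db) / maxdev)
        deviations.append(min(devs))
        kept_w.append(w)
    kept_w = np.asarray(kept_w)
    if kept_w.sum() == 0:
        kept_w = np.ones_like(kept_w)
    return float(np.clip(np.dot(deviations, kept_w) / kept_w.sum(), 0.0, 1.0))


def match_conformers_by_mcs_torsions(
    ensemble_a: LabelledEnsemble,
    ensemble_b: LabelledEnsemble,
    match: McsMatch,
    bin_width_deg: float = 10.0,
) -> list[tuple[int, int]]:
    """Pairs of (conf_a, conf_b) whose MCS torsions all fall in the same bin.

    Bins tile [-180, 180) with the given width; a pair of conformers (one from
    each ensemble) matches when every MCS torsion of both lands in the same
    angular bin, which is how predictions are compared across molecules that
    share a substructure.
    """
    entries, _ = _mcs_torsion_entries(ensemble_a.mol, match)
    ref_index = dict(match.pairs)

    def bins(coords: np.ndarray, side: str) -> tuple:
        out = []
        for quads, _ in entries:
            quad = quads[0]
            if side == "b":
                quad = [ref_index[a] for a in quad]
            angle = dihedral_deg(coords, quad)
            out.append(int(np.floor((angle + 180.0) / bin_width_deg)))
        return tuple(out)

    bins_a = [bins(c.coords, "a") for c in ensemble_a.conformers]
    bins_b = [bins(c.coords, "b") for c in ensemble_b.conformers]
    return [
        (ca.conf_id, cb.conf_id)
        for ca, ba in zip(ensemble_a.conformers, bins_a)
        for cb, bb in zip(ensemble_b.conformers, bins_b)
        if ba == bb
    ]


class TFD2SimRefMCSRanker(ConformerRanker):
    """Bioactivity-based ranker: TFD over the MCS to the nearest reference.

    Fitted on a reference set of molecules with bioactive conformations
    (typically the training split).  For a test ensemble it selects the most
    similar reference molecule, computes the MCS, and ranks conformers by
    ascending TFD to the reference's (first) bioactive conformation.  When no
    torsion lies in the MCS the ranker falls back to the generator order and
    flags it.
    """

    name = "tfd2simrefmcs"

    def __init__(self, timeout: int = 10):
        self.timeout = timeout
        self.references_: list[tuple[str, Chem.Mol, ConformerRecord]] = []

    def fit(self, references: Sequence[LabelledEnsemble] | None = None) -> "TFD2SimRefMCSRanker":
        if not references:
            raise ValueError("TFD2SimRefMCS requires a non-empty reference set")
        self.references_ = []
        for ens in references:
            if not ens.bioactive:
                raise ValueError(f"{ens.mol_id}: reference without bioactive conformation")
            self.references_.append((ens.mol_id, ens.mol, ens.bioactive[0]))
        return self

    def rank(self, ensemble: LabelledEnsemble) -> RankingResult:
        if not self.references_:
            raise ValueError("ranker must be fitted with a reference set first")
        ref_id = find_nearest_reference(
            ensemble.mol, [(mid, mol) for mid, mol, _ in self.references_]
        )
        ref_mol, ref_bio = next(
            (mol, bio) for mid, mol, bio in self.references_ if mid == ref_id
        )
        match = mcs(ensemble.mol, ref_mol, ref_mol_id=ref_id, timeout=self.timeout)
        try:
            scores = np.array(
                [tfd_mcs(c, ref_bio, match, ensemble.mol) for c in ensemble.conformers]
            )
        except RankingSkip:
            fallback = GeneratorOrderRanker().rank(ensemble)
            fallback.ranker_name = self.name
            fallback.flags["fallback"] = "generator_order"
            fallback.flags["reference_mol_id"] = ref_id
            return fallback
        return order_by_scores(
            ensemble,
            scores,
            self.name,
            flags={"reference_mol_id": ref_id, "mcs_n_heavy": match.n_heavy},
        )

    def score(self, ensemble: LabelledEnsemble) -> np.ndarray:
        return self.rank(ensemble).scores


# ---------------------------------------------------------------------------
# Model-based and oracle rankers


class AtNNRanker(ConformerRanker):
    """Rank by ascending predicted ARMSD_bio from a trained regressor."""

    name = "atnn"

    def __init__(self, model):
        self.model = model

    def score(self, ensemble: LabelledEnsemble) -> np.ndarray:
        z = np.array([a.GetAtomicNum() for a in ensemble.mol.GetAtoms()])
        return self.model.predict([(z, c.coords) for c in ensemble.conformers])


class OracleRanker(ConformerRanker):
    """Rank by the true ARMSD_bio (upper bound on ranking performance)."""

    name = "oracle"

    def score(self, ensemble: LabelledEnsemble) -> np.ndarray:
        if ensemble.armsd_bio.size != ensemble.n_conformers:
            raise ValueError("ensemble has no ARMSD_bio labels")
        return np.asarray(ensemble.armsd_bio, dtype=float)


def thermal_energy_window(multiple: float, temperature_k: float) -> float:
    """multiple x kB x T in kcal/mol (e.g. a 3 kBT strain-energy window)."""
    if multiple < 0 or temperature_k <= 0:
        raise ValueError("multiple must be >= 0 and temperature positive")
    return multiple * BOLTZMANN_KCAL * temperature_k


def default_rankers(seed: int = 0) -> list[ConformerRanker]:
    """The five bioactivity-unaware baselines with a shared seed."""
    return [
        RandomRanker(seed=seed),
        GeneratorOrderRanker(),
        EnergyRanker(),
        SasaRanker(),
        RGyrRanker(),
    ]


def write_ranking_table(rankings: Sequence[RankingResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("mol_id\tranker\trank\tconf_id\tscore\n")
        for res in rankings:
            for conf_rank, (cid, score) in enumerate(zip(res.order, res.scores), start=1):
                fh.write(
                    f"{res.mol_id}\t{res.ranker_name}\t{conf_rank}\t{cid}\t{score:.6f}\n"
                )
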