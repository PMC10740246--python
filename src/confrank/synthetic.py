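"""Self-contained synthetic benchmarks for the conformer-ranking pipeline.

Real studies of bioactive conformer ranking need curated protein–ligand
structures; this module replaces them with fully reproducible synthetic data.
Each synthetic molecule gets an ETKDG conformer ensemble, and its "bioactive"
reference is a torsion-jittered copy of one generated conformer: a small
jitter (a few degrees) leaves the source conformer bioactive-like (< 1 Å),
while a large jitter pushes the reference away from the whole ensemble, so the
ARMSD_bio distribution spans the bioactive-like and non-bioactive regimes in a
controllable way.  ``target_frac_with_bio_like`` sets the probability of the
small-jitter regime per molecule.

Family mode builds groups of molecules sharing a drug-like core of >= 20 heavy
atoms with varied peripheral substituents, and picks each member's bioactive
source conformer to be the one whose core torsions are closest to the family's
reference pattern.  That gives ranking methods which exploit shared
substructures (MCS/TFD matching, trained atomistic networks) a real signal to
find, mimicking the series structure of curated protein–ligand datasets.

What this does not emulate: docked poses, protein pockets, strain induced by
binding, or crystallographic noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import TorsionFingerprints, rdMolTransforms

from .conformers import (
    ConformerRecord,
    LabelledEnsemble,
    build_labelled_ensemble,
    generate_conformers,
)
from .structures import MoleculeRecord, molecule_from_smiles

__all__ = ["SyntheticSpec", "SyntheticDataset", "make_benchmark", "make_toy_geometries", "SMILES_POOL", "FAMILY_CORES"]

#: Drug-like molecules spanning roughly 1-12 rotatable bonds, biased towards
#: flexible linkers so that ensembles span the non-bioactive (> 2.5 Å) regime.
SMILES_POOL = [
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                          # ibuprofen
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",                        # naproxen
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",                          # lidocaine
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",                      # atenolol
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",                       # salbutamol
    "COc1ccc(CCN(C)CCCC(C#N)c2ccc(OC)c(OC)c2)cc1OC",       # verapamil-like
    "O=C(NCCCCN1CCN(c2ccccn2)CC1)c1ccc2ccccc2c1",          # naphthamide linker
    "c1ccc(-c2ccc(S(=O)(=O)NCCCCCCNC(=O)c3ccccc3)cc2)cc1", # biphenyl hexyl diamide
    "O=C(Nc1ccc(Cl)cc1)COCCOCCNC(=O)c1ccc(OC)cc1",         # PEG-linked diaryl
    "O=C(NCCCCCCNC(=O)c1ccc(F)cc1)c1ccc(OC)cc1",           # bis-amide chain
    "CCN(CC)CCCNC(=O)c1ccc(-c2ccccc2)cc1",                 # biphenyl amide amine
    "COc1ccc(OCCCCCN2CCN(c3ccccc3)CC2)cc1",                # aryloxy pentyl piperazine
    "O=S(=O)(N)c1ccc(CCNC(=O)c2ccccc2)cc1",                # sulfonamide amide
    "CCOC(=O)C1CCN(CC1)Cc1ccccc1",                         # ester piperidine
    "O=C(Nc1ccccc1)Nc1ccc(Cl)cc1",                         # diaryl urea
    "CCCCCCCCC(=O)OCCN(C)C",                               # flexible chain ester
]

#: Shared-core family templates (>= 20 heavy atoms each, flexible linkers so
#: ensembles span both label regimes); "{R}" marks the substitution site, and
#: the unsubstituted parent drops the branch.
FAMILY_CORES = [
    "c1ccc(-c2ccc(S(=O)(=O)NCCCCCCNC(=O)c3ccc({R})cc3)cc2)cc1",
    "O=C(NCCOCCOCCNC(=O)c1ccccn1)c1ccc2cc({R})ccc2c1",
    "COc1ccc(CCN(C)CCCCNC(=O)c2ccc(-c3ccc({R})cc3)cc2)cc1",
    "CC(=O)Nc1ccc(S(=O)(=O)NCCCCCOc2ccc(-c3ccc({R})cc3)cc2)cc1",
]

#: Peripheral substituents used to decorate a family core.
FAMILY_SUBSTITUENTS = [
    "F", "Cl", "Br", "C", "CC", "CCC", "OC", "OCC", "N(C)C",
    "C(F)(F)F", "C#N", "CO", "OC(C)C", "C(C)C",
]


@dataclass
class SyntheticSpec:
    """Study conditions of a synthetic benchmark."""

    n_molecules: int = 20
    max_conformers: int = 250
    n_bioactive_probs: dict[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.3})
    target_frac_with_bio_like: float = 0.8
    family_structure: bool = False
    members_per_family: int = 14
    small_jitter_deg: float = 3.0
    large_jitter_deg: float = 120.0
    #: torsion-jitter amplitudes of the conformers planted around the
    #: bioactive reference in family mode, emulating a generator sampling the
    #: basin of the bioactive conformation with decreasing fidelity
    basin_jitters_deg: tuple[float, ...] = (3.0, 5.0, 10.0, 15.0, 25.0, 40.0, 60.0, 90.0)
    cartesian_noise: float = 0.02
    retry_cap: int = 3
    seed: int = 0


@dataclass
class SyntheticDataset:
    molecules: list[MoleculeRecord]
    ensembles: dict[str, LabelledEnsemble]
    class_labels: dict[str, str] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)


def family_smiles(n_families: int, members_per_family: int) -> list[tuple[str, str, str]]:
    """(mol_id, family, smiles) tuples for shared-core families."""
    out = []
    for f in range(n_families):
        template = FAMILY_CORES[f % len(FAMILY_CORES)]
        members = [template.replace("({R})", "")]
        members += [template.replace("{R}", s) for s in FAMILY_SUBSTITUENTS]
        for m, smi in enumerate(members[:members_per_family]):
            out.append((f"fam{f}_m{m}", f"fam{f}", smi))
    return out


def _rotatable_torsions(mol: Chem.Mol) -> list[tuple[int, int, int, int]]:
    tl, _ = TorsionFingerprints.CalculateTorsionLists(mol)
    return [quads[0] for quads, _ in tl if quads]


def _jitter_conformer(
    record: MoleculeRecord,
    source: np.ndarray,
    rng: np.random.Generator,
    torsion_sigma_deg: float,
    cartesian_noise: float,
) -> np.ndarray:
    """Perturb a conformer by per-torsion jitter plus small Cartesian noise."""
    mol = Chem.Mol(record.mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(source):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    mol.RemoveAllConformers()
    cid = mol.AddConformer(conf, assignId=True)
    conf = mol.GetConformer(cid)
    for quad in _rotatable_torsions(mol):
        delta = float(rng.normal(0.0, torsion_sigma_deg))
        try:
            current = rdMolTransforms.GetDihedralDeg(conf, *quad)
            rdMolTransforms.SetDihedralDeg(conf, *quad, current + delta)
        except ValueError:
            continue  # torsion in a ring system the transform cannot rotate
    coords = np.array(conf.GetPositions(), dtype=float)
    coords += rng.normal(0.0, cartesian_noise, size=coords.shape)
    return coords


def _core_torsion_angles(member: MoleculeRecord, core: Chem.Mol, coords: np.ndarray) -> np.ndarray | None:
    """Dihedral angles of the core's rotatable torsions, measured on a member."""
    match = member.mol.GetSubstructMatch(core)
    if not match:
        return None
    quads = _rotatable_torsions(core)
    if not quads:
        return None
    from .baselines import dihedral_deg

    return np.array(
        [dihedral_deg(coords, [match[a] for a in quad]) for quad in quads]
    )


def _torsion_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = np.abs(a - b) % 360.0
    return float(np.minimum(d, 360.0 - d).mean())


def _snap_core_torsions(
    member: MoleculeRecord, core: Chem.Mol, coords: np.ndarray, pattern: np.ndarray
) -> np.ndarray:
    """Set a member conformer's core torsions to the family pattern angles."""
    match = member.mol.GetSubstructMatch(core)
    quads = _rotatable_torsions(core)
    if not match or not quads:
        return coords
    mol = Chem.Mol(member.mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    mol.RemoveAllConformers()
    cid = mol.AddConformer(conf, assignId=True)
    conf = mol.GetConformer(cid)
    for quad, angle in zip(quads, pattern):
        mapped = [match[a] for a in quad]
        try:
            rdMolTransforms.SetDihedralDeg(conf, *mapped, float(angle))
        except ValueError:
            continue
    return np.array(conf.GetPositions(), dtype=float)


def make_benchmark(spec: SyntheticSpec) -> SyntheticDataset:
    """Build a labelled synthetic benchmark dataset, reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.family_structure:
        n_families = max(1, round(spec.n_molecules / spec.members_per_family))
        entries = family_smiles(n_families, spec.members_per_family)[: spec.n_molecules]
    else:
        pool = list(SMILES_POOL)
        entries = [
            (f"syn{i}", "", pool[int(rng.integers(len(pool)))])
            for i in range(spec.n_molecules)
        ]

    molecules: list[MoleculeRecord] = []
    ensembles: dict[str, LabelledEnsemble] = {}
    class_labels: dict[str, str] = {}
    families: dict[str, str] = {}
    flagged: list[str] = []
    core_cache: dict[str, Chem.Mol] = {}
    family_pattern: dict[str, np.ndarray] = {}

    n_bio_choices = sorted(spec.n_bioactive_probs)
    n_bio_probs = np.array([spec.n_bioactive_probs[k] for k in n_bio_choices], dtype=float)
    n_bio_probs = n_bio_probs / n_bio_probs.sum()

    for mol_id, family, smiles in entries:
        record = molecule_from_smiles(smiles, mol_id=mol_id)
        generated = generate_conformers(
            record, max_n=spec.max_conformers, seed=int(rng.integers(2**31 - 1))
        )
        want_bio_like = bool(rng.random() < spec.target_frac_with_bio_like)
        n_bio = int(rng.choice(n_bio_choices, p=n_bio_probs))

        if family and family not in core_cache:
            template = FAMILY_CORES[int(family.removeprefix("fam")) % len(FAMILY_CORES)]
            core_cache[family] = Chem.MolFromSmiles(template.replace("({R})", ""))

        ensemble = None
        for _attempt in range(spec.retry_cap):
            # Reference construction.  Family mode: start from the ensemble
            # conformer whose core torsions are closest to the family pattern
            # and snap its core torsions exactly onto the pattern, so every
            # member's bioactive reference shares the family core geometry;
            # the generator's retrieval of the bioactive conformation is then
            # emulated by replacing that conformer with a small-jitter copy of
            # the reference.  Plain mode: the reference is a jittered copy of
            # a randomly chosen conformer, which itself stays in the ensemble.
            ensemble_confs = list(generated)
            planted_idx = None
            if family and family in family_pattern:
                pattern = family_pattern[family]
                core = core_cache[family]
                dists = []
                for c in generated:
                    angles = _core_torsion_angles(record, core, c.coords)
                    dists.append(np.inf if angles is None else _torsion_distance(angles, pattern))
                planted_idx = int(np.argmin(dists))
                chosen = generated[planted_idx]
                ref_coords = _snap_core_torsions(record, core, chosen.coords, pattern)
            else:
                chosen = generated[int(rng.integers(len(generated)))]
                ref_coords = chosen.coords
            sigma = spec.small_jitter_deg if want_bio_like else spec.large_jitter_deg
            bioactive = [
                ConformerRecord(
                    mol_id=mol_id,
                    conf_id=k,
                    coords=_jitter_conformer(record, ref_coords, rng, sigma, spec.cartesian_noise),
                    source="bioactive",
                )
                for k in range(n_bio)
            ]
            if planted_idx is not None and want_bio_like:
                # plant a basin of conformers around the reference: the chosen
                # slot gets the tightest copy, further random slots get
                # increasingly loose copies, giving the ensemble a continuum
                # of ARMSD_bio values down into the bioactive-like regime
                other = [i for i in range(len(ensemble_confs)) if i != planted_idx]
                rng.shuffle(other)
                slots = [planted_idx] + other[: len(spec.basin_jitters_deg) - 1]
                for slot, sigma_b in zip(slots, spec.basin_jitters_deg):
                    old = ensemble_confs[slot]
                    ensemble_confs[slot] = ConformerRecord(
                        mol_id=mol_id,
                        conf_id=old.conf_id,
                        coords=_jitter_conformer(
                            record, ref_coords, rng, sigma_b, spec.cartesian_noise
                        ),
                        source="generated",
                        gen_order=old.gen_order,
                    )
            candidate = build_labelled_ensemble(record, ensemble_confs, bioactive)
            ok_bio = candidate.n_bio_like >= 1 or not want_bio_like
            if ok_bio and candidate.n_non_bio >= 1:
                ensemble = candidate
                break
            ensemble = candidate
        else:
            flagged.append(mol_id)

        if family:
            core = core_cache[family]
            if family not in family_pattern:
                angles = _core_torsion_angles(record, core, ensemble.bioactive[0].coords)
                if angles is not None:
                    family_pattern[family] = angles
            families[mol_id] = family
            class_labels[mol_id] = family
        molecules.append(record)
        ensembles[mol_id] = ensemble
    return SyntheticDataset(
        molecules=molecules,
        ensembles=ensembles,
        class_labels=class_labels,
        families=families,
        flagged=flagged,
    )


def make_toy_geometries() -> dict[str, dict]:
    """Closed-form geometric fixtures with their expected values attached."""
    hexagon = np.array(
        [
            [1.39 * np.cos(k * np.pi / 3.0), 1.39 * np.sin(k * np.pi / 3.0), 0.0]
            for k in range(6)
        ]
    )
    rng = np.random.default_rng(7)
    cloud = rng.normal(0.0, 1.5, size=(5, 3))
    tetra = np.array(
        [
            [0.0, 0.0, 0.0],       # central carbon
            [1.0, 1.0, 1.0],       # F
            [1.0, -1.0, -1.0],     # Cl
            [-1.0, 1.0, -1.0],     # Br
        ]
    )
    return {
        "collinear_pair": {
            "coords_a": np.array([[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            "coords_b": np.array([[-2.0, 0.0, 0.0], [2.0, 0.0, 0.0]]),
            "expected_armsd": 1.0,
        },
        "benzene_ring": {
            "coords": hexagon,
            "relabel": tuple((np.arange(6) + 1) % 6),  # 60 degree index rotation
            "expected_armsd": 0.0,
            "smiles": "c1ccccc1",
        },
        "chiral_center": {
            "smiles": "FC(Cl)Br",
            "coords": tetra,
            "mirrored": tetra * np.array([1.0, 1.0, -1.0]),
        },
        "two_copy_cloud": {
            "atomic_numbers": np.array([6, 6, 7, 8, 6]),
            "coords": cloud,
            "offset": np.array([50.0, 0.0, 0.0]),
            "expected_output_ratio": 2.0,
        },
    }
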