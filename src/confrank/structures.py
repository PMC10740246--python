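"""Ligand structure reading, standardization and reference matching.

A curated ligand is represented by a :class:`MoleculeRecord`: a heavy-atom
RDKit molecule plus its canonical reference SMILES.  Observed 3D structures
(e.g. from crystallographic SDF files) are standardized, their stereocentres
are perceived from geometry, and they are matched atom-by-atom against the
standardized reference structure with chirality taken into account.  When the
direct match fails — typically because the observed record carries degraded
bond orders — bond orders are re-assigned from the reference template and the
match is retried exactly once; ligands that still fail are reported as
mismatches rather than raising, so that batch curation can drop them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import DimensionError, StructureParseError

__all__ = [
    "MoleculeRecord",
    "AtomMapping",
    "molecule_from_smiles",
    "standardize_molecule",
    "assign_stereo_from_3d",
    "match_to_reference",
    "read_sdf_molecules",
    "write_molecule_table",
]


@dataclass
class MoleculeRecord:
    """A ligand's 2D identity: heavy-atom graph, stereo flags, reference SMILES."""

    mol_id: str
    mol: Chem.Mol
    reference_structure: str = ""

    def __post_init__(self) -> None:
        if self.mol is not None and not self.reference_structure:
            self.reference_structure = Chem.MolToSmiles(self.mol)

    @property
    def elements(self) -> list[int]:
        return [a.GetAtomicNum() for a in self.mol.GetAtoms()]

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.mol.GetBonds()
        ]

    @property
    def stereo(self) -> dict:
        atoms = {
            a.GetIdx(): str(a.GetChiralTag())
            for a in self.mol.GetAtoms()
            if a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED
        }
        bonds = {
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()): str(b.GetStereo())
            for b in self.mol.GetBonds()
            if b.GetStereo() != Chem.BondStereo.STEREONONE
        }
        return {"atoms": atoms, "bonds": bonds}

    @property
    def n_heavy_atoms(self) -> int:
        return self.mol.GetNumAtoms()


@dataclass
class AtomMapping:
    """Atom correspondence between an observed molecule and its reference."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    complete: bool = False
    used_template_retry: bool = False


def molecule_from_smiles(smiles: str, mol_id: str = "") -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"could not parse SMILES {smiles!r}")
    return standardize_molecule(MoleculeRecord(mol_id=mol_id or smiles, mol=mol))


_uncharger = rdMolStandardize.Uncharger()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser()


def standardize_molecule(raw: MoleculeRecord) -> MoleculeRecord:
    """Standardize and neutralize a molecule.

    Keeps the largest connected component, normalizes functional groups,
    neutralizes charged atoms where a proton can be added or removed without
    breaking valence, and strips explicit hydrogens.  The operation is
    idempotent: applying it twice yields the same canonical form.
    """
    mol = Chem.Mol(raw.mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several sanitization subclasses
        raise StructureParseError(f"{raw.mol_id}: invalid valence model ({exc})") from exc
    mol = _fragment_chooser.choose(mol)
    mol = rdMolStandardize.Normalize(mol)
    mol = _uncharger.uncharge(mol)
    mol = Chem.RemoveHs(mol)
    Chem.SanitizeMol(mol)
    ref = Chem.MolToSmiles(mol)
    return MoleculeRecord(mol_id=raw.mol_id, mol=mol, reference_structure=ref)


def assign_stereo_from_3d(record: MoleculeRecord, coords: np.ndarray) -> MoleculeRecord:
    """Set chirality tags of the heavy-atom graph from a 3D geometry."""
    coords = np.asarray(coords, dtype=float)
    mol = Chem.Mol(record.mol)
    if coords.shape != (mol.GetNumAtoms(), 3):
        raise DimensionError(
            f"{record.mol_id}: expected coords of shape ({mol.GetNumAtoms()}, 3), "
            f"got {coords.shape}"
        )
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    mol.RemoveAllConformers()
    mol.AddConformer(conf, assignId=True)
    Chem.AssignStereochemistryFrom3D(mol)
    mol.RemoveAllConformers()
    return MoleculeRecord(
        mol_id=record.mol_id, mol=mol, reference_structure=Chem.MolToSmiles(mol)
    )


def _complete_match(observed: Chem.Mol, reference: Chem.Mol) -> tuple[int, ...] | None:
    if observed.GetNumAtoms() != reference.GetNumAtoms():
        return None
    match = observed.GetSubstructMatch(reference, useChirality=True)
    if len(match) == observed.GetNumAtoms():
        return match
    return None


def match_to_reference(observed: MoleculeRecord, reference: MoleculeRecord) -> AtomMapping:
    """Chirality-aware atom mapping of an observed molecule onto its reference.

    On direct failure, bond orders of the observed molecule are re-assigned
    from the reference template and the match is retried once.  An unmatched
    ligand yields an incomplete mapping, not an exception, so batch curation
    can drop it and continue.
    """
    match = _complete_match(observed.mol, reference.mol)
    if match is not None:
        pairs = [(obs_idx, ref_idx) for ref_idx, obs_idx in enumerate(match)]
        return AtomMapping(pairs=sorted(pairs), complete=True)

    # Retry once with bond orders copied from the reference template.
    try:
        fixed = AllChem.AssignBondOrdersFromTemplate(reference.mol, observed.mol)
    except ValueError:
        return AtomMapping()
    Chem.AssignStereochemistry(fixed, cleanIt=True, force=True)
    match = _complete_match(fixed, reference.mol)
    if match is not None:
        pairs = [(obs_idx, ref_idx) for ref_idx, obs_idx in enumerate(match)]
        return AtomMapping(pairs=sorted(pairs), complete=True, used_template_retry=True)
    return AtomMapping(used_template_retry=True)


def read_sdf_molecules(path: str | Path, standardize: bool = True) -> Iterator[MoleculeRecord]:
    """Read V2000 SDF records as heavy-atom molecules.

    Hydrogen positions are discarded on read.  Stereo is perceived from the 3D
    coordinates of each record before standardization.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        Chem.AssignStereochemistryFrom3D(mol)
        mol3d = Chem.Mol(mol)
        mol.RemoveAllConformers()
        record = MoleculeRecord(mol_id=mol_id, mol=mol)
        if standardize:
            record = standardize_molecule(record)
        # keep the observed geometry available to callers
        record.mol3d = mol3d  # type: ignore[attr-defined]
        yield record


def write_molecule_table(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write the standardized molecule table as TSV."""
    with open(path, "w") as fh:
        fh.write("mol_id\treference_structure\tn_heavy_atoms\n")
        for rec in records:
            fh.write(f"{rec.mol_id}\t{rec.reference_structure}\t{rec.n_heavy_atoms}\n")
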