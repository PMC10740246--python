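import numpy as np
import pytest

from confrank.conformers import ConformerRecord, build_labelled_ensemble, generate_conformers
from confrank.structures import molecule_from_smiles
from confrank.synthetic import SyntheticSpec, make_benchmark, make_toy_geometries


@pytest.fixture(scope="session")
def toy():
    return make_toy_geometries()


@pytest.fixture(scope="session")
def ibuprofen():
    return molecule_from_smiles("CC(C)Cc1ccc(cc1)C(C)C(=O)O", "ibuprofen")


@pytest.fixture(scope="session")
def ibuprofen_confs(ibuprofen):
    return generate_conformers(ibuprofen, max_n=12, seed=3)


@pytest.fixture(scope="session")
def small_benchmark():
    """A small mixed-pool benchmark shared across tests (not family mode)."""
    spec = SyntheticSpec(n_molecules=10, max_conformers=20, seed=11)
    return make_benchmark(spec)


@pytest.fixture(scope="session")
def labelled_ensemble(ibuprofen, ibuprofen_confs):
    """An ensemble whose first conformer is exactly the bioactive reference."""
    bio = ConformerRecord(
        mol_id="ibuprofen", conf_id=0, coords=ibuprofen_confs[0].coords.copy(), source="bioactive"
    )
    return build_labelled_ensemble(ibuprofen, ibuprofen_confs, [bio])
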