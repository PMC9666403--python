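import numpy as np
import pytest
from hypothesis import settings

from tubmap import (
    ResidueRecord,
    StructureModel,
    ToyLatticeParams,
    assign_domains,
    attach_secondary_structure,
    make_ss_table,
    make_toy_lattice,
)

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

LIGAND_SITES = {"L1:GTP": "N-site", "L2:GTP": "E-site"}


@pytest.fixture(scope="session")
def toy():
    """Default toy lattice, seed 7."""
    return make_toy_lattice(ToyLatticeParams(seed=7))


@pytest.fixture(scope="session")
def toy_partition(toy):
    return assign_domains(toy.model, toy.spec)


@pytest.fixture(scope="session")
def toy_dir(toy, tmp_path_factory):
    """Toy lattice written to disk (structure.cif, ss.tsv, lattice.json, ...)."""
    d = tmp_path_factory.mktemp("toy7")
    toy.write(d)
    return d


def line_model(n=10, chain="A", spacing=4.0):
    """A straight chain of single-atom residues, for plumbing tests."""
    residues = [
        ResidueRecord(
            chain_id=chain,
            residue_number=i + 1,
            amino_acid="ACDEFGHIKLMNPQRSTVWY"[i % 20],
            atoms=[("CA", spacing * i, 0.0, 0.0)],
        )
        for i in range(n)
    ]
    return StructureModel(residues=residues, chain_roles={chain: "alpha"})


@pytest.fixture(scope="session")
def tuba_like():
    """A 451-residue chain annotated at 39% helix / 12% sheet / 49% loop."""
    model = line_model(n=451)
    attach_secondary_structure(model, make_ss_table(451))
    return model
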