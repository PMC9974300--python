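import numpy as np
import pytest

from ogdhc import synthetic_data as sd
from ogdhc.structure_io import Atom, Chain, Residue, Structure


@pytest.fixture(scope="session")
def mini_complex():
    """Miniature 24+16+12+6 complex with core, sub-models and recipe."""
    return sd.make_mini_ogdhc(seed=1)


@pytest.fixture(scope="session")
def assembled_mini(mini_complex):
    from ogdhc.assembly import assemble_complex

    return assemble_complex(
        mini_complex.core,
        mini_complex.submodels,
        mini_complex.recipe,
        monomer_masses_kda=sd.MONOMER_MASSES_KDA,
    )


def make_point_chain(chain_id, component, positions, start_number=1, names=None):
    """Chain of single-CA residues at explicit coordinates (test helper)."""
    residues = []
    for i, pos in enumerate(positions):
        name = names[i] if names else "ALA"
        residues.append(
            Residue(
                number=start_number + i,
                name=name,
                atoms=[Atom("CA", "C", tuple(np.asarray(pos, dtype=float)))],
            )
        )
    return Chain(id=chain_id, residues=residues, component=component)


@pytest.fixture
def point_chain_factory():
    return make_point_chain


@pytest.fixture
def homodimer():
    """Two copies of one component where the residue-1/residue-2 distance is
    50 Å within either copy but 15 Å between copies (A res1 at x=0, B res2
    at x=15)."""
    a = make_point_chain("A", "sub", [(0, 0, 0), (50, 0, 0)])
    b = make_point_chain("B", "sub", [(100, 0, 0), (15, 0, 0)])
    return Structure(chains=[a, b])
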