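"""Shared fixtures: expensive toy systems are built once per session."""

import numpy as np
import pytest

from gefscan.builder import build_peptide
from gefscan.energy import EnergyModel
from gefscan.fixtures import make_rotamer_puzzle, make_surface_helix, make_toy_dimer
from gefscan.prepare import build_all_atom_model
from gefscan.structure_model import StructureModel


@pytest.fixture(scope="session")
def default_model():
    m = EnergyModel.default()
    m.validate_reference()
    return m


@pytest.fixture(scope="session")
def helix12():
    return make_surface_helix(12)


@pytest.fixture(scope="session")
def dimer():
    return make_toy_dimer(n_contacts=1)


@pytest.fixture(scope="session")
def dimer_apart():
    return make_toy_dimer(n_contacts=0)


@pytest.fixture(scope="session")
def puzzle():
    return make_rotamer_puzzle(2, "pairwise_clash")


@pytest.fixture(scope="session")
def buried_site():
    """A poly-Ala helix with an obstacle chain blocking the space above
    residue A6's C-beta: a large side chain there clashes in every rotamer."""
    h1 = build_peptide("A" * 12, conformation="helix", chain_id="A")
    r6 = h1.get("A", 6)
    u = r6.pos("CB") - r6.pos("CA")
    u /= np.linalg.norm(u)
    ob = build_peptide("AAA", conformation="extended", chain_id="B")
    shift = r6.pos("CB") + 6.0 * u - ob.get("B", 2).pos("CA")
    for r in ob.residues():
        for a in r.atoms:
            a.pos = a.pos + shift
    return build_all_atom_model(StructureModel(h1.chains + ob.chains))
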