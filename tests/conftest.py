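import numpy as np
import pytest

from bcisolve import Atom, Bond, Molecule, fixtures


def make_molecule(types, bonds, charges=None, name="test"):
    """Build a molecule from type labels, 1-based bond pairs and charges."""
    n = len(types)
    charges = charges if charges is not None else np.zeros(n)
    atoms = [
        Atom(index=i + 1, name=f"{t}{i + 1}", element=t, atom_type=t,
             partial_charge=float(q))
        for i, (t, q) in enumerate(zip(types, charges))
    ]
    return Molecule(name=name, atoms=atoms, bonds=[Bond(a, b) for a, b in bonds])


@pytest.fixture
def mol_factory():
    return make_molecule


@pytest.fixture
def cisplatin_chelpg():
    """Cisplatin with the published DSD-BLYP/Sappo-TZP/DZP CHELPG charges."""
    return fixtures.load_molecule("cisplatin", "dsdblyp_chelpg")


@pytest.fixture
def ptcl4_chelpg():
    """[PtCl4]2- with the published PBE-QIDH/DKH-TZVPP/TZVP CHELPG charges."""
    return fixtures.load_molecule("tetrachloroplatinate", "pbeqidh_dkhtzvpp_chelpg")


@pytest.fixture
def diatomic():
    """Heteronuclear diatomic A-B with charges (-0.3, +0.3)."""
    return make_molecule(["A", "B"], [(1, 2)], [-0.3, 0.3], name="AB")
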