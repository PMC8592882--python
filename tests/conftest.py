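import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from nacgeo.structio import Structure, Trajectory


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210922)


@pytest.fixture
def peptide_structure() -> Structure:
    """A 5-residue CA/N/C toy peptide on two chains with one HETATM water."""
    names, elements, resnames, resids, chains, hetero = [], [], [], [], [], []
    coords = []
    pos = 0.0
    for i in range(5):
        chain = "A" if i < 3 else "B"
        for nm, el in (("N", "N"), ("CA", "C"), ("C", "C")):
            names.append(nm)
            elements.append(el)
            resnames.append("ALA")
            resids.append(i + 1)
            chains.append(chain)
            hetero.append(False)
            coords.append([pos, 0.0, 0.0])
            pos += 1.5
    names.append("O")
    elements.append("O")
    resnames.append("HOH")
    resids.append(100)
    chains.append("W")
    hetero.append(True)
    coords.append([50.0, 0.0, 0.0])
    return Structure.from_arrays(
        np.array(coords), name=names, element=elements, resname=resnames,
        resid=resids, chain=chains, hetero=hetero,
    )


@pytest.fixture
def two_frame_trajectory(peptide_structure) -> Trajectory:
    c0 = peptide_structure.coords
    return Trajectory(peptide_structure, np.stack([c0, c0 + [0.0, 1.0, 0.0]]))
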