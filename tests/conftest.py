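"""Shared fixtures: synthetic complexes and a hand-built PDB writer."""
from __future__ import annotations

import numpy as np
import pytest

from ifacesearch.interface import model_interface
from ifacesearch.structures import write_pdb
from ifacesearch.synthetic import SyntheticComplexSpec, make_toy_complex
from ifacesearch.tetrascan import SearchParams


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz,
    occ: float = 1.0,
    altloc: str = " ",
    element: str | None = None,
    record: str = "ATOM",
    icode: str = " ",
) -> str:
    """One fixed-width PDB coordinate line."""
    element = element or name[0]
    padded = f" {name:<3s}" if len(name) < 4 and len(element) == 1 else f"{name:<4s}"
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:5d} {padded}{altloc}{resname:>3s} {chain}{resseq:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture(scope="session")
def toy_structure():
    return make_toy_complex(SyntheticComplexSpec(seed=1))


@pytest.fixture(scope="session")
def toy_pair(toy_structure):
    return model_interface(toy_structure, "A", "B")


@pytest.fixture()
def params():
    return SearchParams()


@pytest.fixture()
def toy_pdb_path(tmp_path, toy_structure):
    path = tmp_path / "toy1.pdb"
    write_pdb(toy_structure, path)
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
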