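"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from helixstate import (
    Atom,
    StructureModel,
    make_toy_geometry,
)


@pytest.fixture(scope="session")
def toy_geometry():
    return make_toy_geometry()


def make_ca_model(first_res: int = 248, last_res: int = 476,
                  chain: str = "A") -> StructureModel:
    """C-alpha-only model with one residue per number in [first, last]."""
    atoms = []
    for k, res in enumerate(range(first_res, last_res + 1)):
        atoms.append(Atom(chain, res, "ALA", "CA", "C",
                          np.array([1.3 * k, 0.7 * (k % 5), 0.11 * k])))
    return StructureModel.from_atoms(atoms)


@pytest.fixture(scope="session")
def ca_model() -> StructureModel:
    return make_ca_model()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
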