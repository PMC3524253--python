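"""Shared fixtures: toy structures, surrogate backends, small PDB texts."""

from __future__ import annotations

import numpy as np
import pytest

from barriermap import (
    BackendConfig,
    SurrogateBackend,
    SurrogateParams,
    make_toy_system,
)
from barriermap.structure_io import Atom, StructureModel

GLY_PDB = """\
ATOM      1  N   GLY A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.458  10.000  10.000  1.00  0.00           C
ATOM      3  C   GLY A   1      12.009  11.420  10.000  1.00  0.00           C
ATOM      4  O   GLY A   1      11.251  12.390  10.000  1.00  0.00           O
ATOM      5  H   GLY A   1       9.500   9.200  10.000  1.00  0.00           H
ATOM      6  HA2 GLY A   1      11.800   9.500  10.900  1.00  0.00           H
ATOM      7  HA3 GLY A   1      11.800   9.500   9.100  1.00  0.00           H
END
"""


@pytest.fixture
def gly_pdb_text() -> str:
    return GLY_PDB


@pytest.fixture
def toy():
    """Seeded toy enzyme+substrate: (full model, EndpointPair, SurrogateParams)."""
    return make_toy_system(seed=1)


@pytest.fixture
def toy_backend(toy) -> SurrogateBackend:
    _, pair, params = toy
    return SurrogateBackend(params, pair.es)


@pytest.fixture
def opt_config() -> BackendConfig:
    return BackendConfig()  # PM6, localized orbitals, C15, G0.5


@pytest.fixture
def sp_config() -> BackendConfig:
    return BackendConfig(localized_orbitals=False, single_point=True)


def make_dimer(
    d: float,
    elements: tuple[str, str] = ("O", "C"),
    direction=None,
    origin=(0.0, 0.0, 0.0),
) -> StructureModel:
    """Two-atom structure separated by d along ``direction`` (default x)."""
    u = np.array([1.0, 0.0, 0.0]) if direction is None else np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    origin = np.asarray(origin, float)
    atoms = [
        Atom(1, "A1", elements[0], ("A", 1, ""), "DIM", origin.copy()),
        Atom(2, "A2", elements[1], ("A", 1, ""), "DIM", origin + d * u),
    ]
    return StructureModel(atoms=atoms, residue_order=[("A", 1, "")])


def harmonic_dimer_params(k: float = 100.0, r0: float = 1.2) -> SurrogateParams:
    """A single harmonic bond (the double-well term has zero height)."""
    return SurrogateParams(
        bonds=((1, 2, k, r0),), well_pair=(1, 2), barrier=0.0, d1=0.5, d2=5.0
    )


def point_cloud_model(points: np.ndarray, prefix: str = "X") -> StructureModel:
    """A one-residue carbon point cloud for superposition tests."""
    atoms = [
        Atom(i + 1, f"{prefix}{i+1}", "C", ("A", 1, ""), "CLD", p)
        for i, p in enumerate(points)
    ]
    return StructureModel(atoms=atoms, residue_order=[("A", 1, "")])
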