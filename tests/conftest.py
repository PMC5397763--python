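"""Shared fixtures: toy complexes, ensembles and hand-built snapshots."""

import numpy as np
import pytest

from interlock.structio import Ensemble, Residue, Snapshot, make_atom
from interlock.synthetic_data import (
    ToyComplexSpec,
    generate_ensemble,
    generate_toy_complex,
)

CANONICAL_SPEC = dict(
    n_res_a=30,
    n_res_b=20,
    contact_pairs=[(4, 6), (8, 10), (12, 14)],
    hbond_pairs=[(8, 10)],
    path_chain=[18, 21, 24, 27],
)


@pytest.fixture(scope="session")
def toy_spec() -> ToyComplexSpec:
    return ToyComplexSpec(**CANONICAL_SPEC)


@pytest.fixture(scope="session")
def toy_complex(toy_spec) -> Snapshot:
    return generate_toy_complex(toy_spec, seed=0)


@pytest.fixture(scope="session")
def toy_ensemble(toy_complex) -> Ensemble:
    """10 frames, mild noise, the last 3 with the interface separated."""
    return generate_ensemble(
        toy_complex, n_frames=10, noise_sd=0.05, broken_fraction=0.3, seed=1
    )


def single_atom_residue(chain: str, number: int, pos, name: str = "GLY") -> Residue:
    return Residue(chain, number, name, [make_atom("CA", "C", pos)])


def point_snapshot(points, chain: str = "A", name: str = "GLY") -> Snapshot:
    """Snapshot of single-CA residues at the given coordinates."""
    return Snapshot(
        [single_atom_residue(chain, k + 1, p, name) for k, p in enumerate(points)]
    )
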