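"""Shared fixtures: small molecules computed once per session."""

import pytest

from sesarea import fixtures as fx
from sesarea.pipeline import compute


@pytest.fixture(scope="session")
def diatomic_result():
    atoms, manifest = fx.diatomic()
    return atoms, manifest, compute(atoms)


@pytest.fixture(scope="session")
def triple_result():
    atoms, manifest = fx.triple()
    return atoms, manifest, compute(atoms)


@pytest.fixture(scope="session")
def tetrahedron_result():
    atoms, manifest = fx.tetrahedron()
    return atoms, manifest, compute(atoms)


@pytest.fixture(scope="session")
def spindle_result():
    atoms, manifest = fx.spindle_pair()
    return atoms, manifest, compute(atoms)


@pytest.fixture(scope="session")
def cage_result():
    atoms, manifest = fx.cage()
    return atoms, manifest, compute(atoms)


@pytest.fixture(scope="session")
def cluster_results():
    """A few seeded random clusters with their pipeline results."""
    out = []
    for seed in (11, 12, 13):
        atoms = fx.random_cluster(n=30, box=10.0, seed=seed)
        out.append((seed, atoms, compute(atoms)))
    return out
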