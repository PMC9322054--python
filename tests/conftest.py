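"""Shared fixtures: small lattices and deterministic RNG streams."""

import numpy as np
import pytest

from arealrisk.geometry import AreaLattice, make_weights


def grid_lattice(rows: int, cols: int, diagonal: bool = False) -> AreaLattice:
    """Hand-built r x c grid lattice (rook, optionally queen) as an oracle-
    independent construction: edges enumerated from indices, not polygons."""
    ids = [f"r{r}c{c}" for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((f"r{r}c{c}", f"r{r}c{c + 1}"))
            if r + 1 < rows:
                edges.append((f"r{r}c{c}", f"r{r + 1}c{c}"))
            if diagonal and r + 1 < rows:
                if c + 1 < cols:
                    edges.append((f"r{r}c{c}", f"r{r + 1}c{c + 1}"))
                if c - 1 >= 0:
                    edges.append((f"r{r}c{c}", f"r{r + 1}c{c - 1}"))
    return AreaLattice.from_edges(ids, edges)


@pytest.fixture
def rook4() -> AreaLattice:
    return grid_lattice(4, 4)


@pytest.fixture
def path3() -> AreaLattice:
    return AreaLattice.from_edges(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160101)


def random_lattice(rng, n_min=8, n_max=20) -> AreaLattice:
    """Random connected lattice via a random spanning tree plus extra edges."""
    n = int(rng.integers(n_min, n_max + 1))
    ids = [f"a{i}" for i in range(n)]
    edges = set()
    order = rng.permutation(n)
    for k in range(1, n):
        j = order[k]
        i = order[int(rng.integers(0, k))]
        edges.add(tuple(sorted((ids[i], ids[j]))))
    for _ in range(int(rng.integers(0, 2 * n))):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            edges.add(tuple(sorted((ids[i], ids[j]))))
    return AreaLattice.from_edges(ids, edges)


def checkerboard_values(rows, cols):
    return np.array([1.0 if (r + c) % 2 == 0 else -1.0
                     for r in range(rows) for c in range(cols)])


@pytest.fixture
def rook4_weights(rook4):
    return make_weights(rook4, "row_standardized")
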