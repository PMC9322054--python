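"""Areal adjacency structures.

The spatial backbone of small-area analysis: which units neighbour which.
Adjacency drives both the Moran's I spatial weights and the intrinsic CAR
prior of the BYM model, so this module is deliberately strict about its
invariants (symmetric edges, no self-loops, consistent neighbour counts,
connected-component bookkeeping).

Adjacency can be built from polygons (queen or rook contiguity) or supplied
directly as an edge list, which matters in practice because administrative
boundary files are often restricted while edge lists are shareable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

__all__ = [
    "AreaLattice",
    "WeightMatrix",
    "GeometryError",
    "build_queen_adjacency",
    "augment_links",
    "make_weights",
]


class GeometryError(ValueError):
    """Invalid geometric or adjacency input (duplicate ids, bad polygons...)."""


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class AreaLattice:
    """Adjacency structure of areal units.

    Parameters
    ----------
    area_ids
        Ordered unit identifiers; the order fixes the row order of every
        vector/matrix aligned with the lattice.
    edges
        Unordered id pairs, stored as sorted tuples. Symmetric by
        construction, no self-loops.
    neighbor_counts
        Per-area number of incident edges (``n_i`` in the iCAR prior).
    components
        Partition of areas into connected components (frozensets).
    centroids
        Optional per-area ``(lon, lat)`` in degrees.
    polygons
        Optional per-area planar geometry.
    """

    area_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    neighbor_counts: Mapping[str, int]
    components: tuple[frozenset[str], ...]
    centroids: Mapping[str, tuple[float, float]] | None = None
    polygons: Mapping[str, BaseGeometry] | None = None
    _index: Mapping[str, int] = field(default=None, repr=False, compare=False)

    @classmethod
    def from_edges(
        cls,
        area_ids: Sequence[str],
        edges: Iterable[tuple[str, str]],
        centroids: Mapping[str, tuple[float, float]] | None = None,
        polygons: Mapping[str, BaseGeometry] | None = None,
    ) -> "AreaLattice":
        ids = tuple(str(a) for a in area_ids)
        if len(set(ids)) != len(ids):
            dupes = [a for a in ids if ids.count(a) > 1]
            raise GeometryError(f"duplicate area ids: {sorted(set(dupes))}")
        known = set(ids)
        norm: set[tuple[str, str]] = set()
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise GeometryError(f"self-loop on area {a!r}")
            if a not in known or b not in known:
                missing = a if a not in known else b
                raise GeometryError(f"edge references unknown area {missing!r}")
            norm.add(_norm_edge(a, b))
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from(norm)
        counts = {a: g.degree(a) for a in ids}
        comps = tuple(frozenset(c) for c in nx.connected_components(g))
        return cls(ids, frozenset(norm), counts, comps, centroids, polygons,
                   _index={a: i for i, a in enumerate(ids)})

    def __post_init__(self):
        if self._index is None:
            object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.area_ids)})

    # -- basic views -------------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def index_of(self, area_id: str) -> int:
        return self._index[area_id]

    def degrees(self) -> np.ndarray:
        """Neighbour counts n_i as an int array in lattice order."""
        return np.array([self.neighbor_counts[a] for a in self.area_ids], dtype=int)

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as positional index arrays (i_idx, j_idx), i < j."""
        if not self.edges:
            z = np.empty(0, dtype=int)
            return z, z.copy()
        pairs = sorted(self.edges)
        i_idx = np.array([self._index[a] for a, _ in pairs], dtype=int)
        j_idx = np.array([self._index[b] for _, b in pairs], dtype=int)
        return i_idx, j_idx

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.area_ids)
        g.add_edges_from(self.edges)
        return g

    def singleton_ids(self) -> list[str]:
        return [a for a in self.area_ids if self.neighbor_counts[a] == 0]

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Symmetric binary 0/1 adjacency as CSR."""
        n = self.n_areas
        i_idx, j_idx = self.edge_index_arrays()
        data = np.ones(2 * len(i_idx))
        rows = np.concatenate([i_idx, j_idx])
        cols = np.concatenate([j_idx, i_idx])
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


@dataclass(frozen=True)
class WeightMatrix:
    """Spatial weights over a lattice, binary or row-standardised.

    ``S0`` is the sum of all weights, as it enters Moran's I. Areas with no
    neighbours have an all-zero row and are listed in ``zero_neighbor_ids``.
    """

    lattice: AreaLattice
    style: str
    W: sp.csr_matrix
    S0: float
    zero_neighbor_ids: tuple[str, ...]

    def to_records(self):
        """Yield (id_i, id_j, w_ij) for the nonzero weights."""
        coo = self.W.tocoo()
        ids = self.lattice.area_ids
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield ids[i], ids[j], float(w)


def build_queen_adjacency(
    polygons: Mapping[str, BaseGeometry] | Iterable[tuple[str, BaseGeometry]],
    contiguity: str = "queen",
    snap: float = 0.0,
) -> AreaLattice:
    """Build contiguity adjacency from per-area polygons.

    Queen contiguity: two areas are adjacent iff their boundaries share at
    least one point (corner contact counts). Rook contiguity requires a
    shared boundary segment of positive length.

    Parameters
    ----------
    polygons
        Mapping or iterable of ``(area_id, geometry)``. Duplicate ids and
        invalid/empty geometries are rejected with the offending id.
    contiguity
        ``"queen"`` (default) or ``"rook"``.
    snap
        Optional snap distance for dirty inputs: polygons within ``snap``
        of each other count as adjacent. Exact predicates when 0.
    """
    if isinstance(polygons, Mapping):
        items = list(polygons.items())
    else:
        items = [(str(k), g) for k, g in polygons]
    ids = [str(k) for k, _ in items]
    if len(set(ids)) != len(ids):
        seen, dupes = set(), set()
        for a in ids:
            (dupes if a in seen else seen).add(a)
        raise GeometryError(f"duplicate area ids: {sorted(dupes)}")
    geoms = []
    for k, g in items:
        if g is None or not isinstance(g, BaseGeometry) or g.is_empty or not g.is_valid:
            raise GeometryError(f"invalid geometry for area {k!r}")
        geoms.append(g)
    if contiguity not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule {contiguity!r}")

    edges: set[tuple[str, str]] = set()
    if len(geoms) > 1:
        tree = STRtree(geoms)
        if snap > 0:
            left, right = tree.query(geoms, predicate="dwithin", distance=snap)
        else:
            left, right = tree.query(geoms, predicate="intersects")
        for i, j in zip(left, right):
            if i >= j:
                continue
            if contiguity == "rook" and snap == 0:
                inter = geoms[i].intersection(geoms[j])
                if inter.length == 0 and inter.area == 0:
                    continue  # point contact only: not rook-adjacent
            edges.add(_norm_edge(ids[i], ids[j]))

    cents = {k: (g.centroid.x, g.centroid.y) for k, g in zip(ids, geoms)}
    return AreaLattice.from_edges(ids, edges, centroids=cents,
                                  polygons=dict(zip(ids, geoms)))


def augment_links(lattice: AreaLattice, extra_edges: Iterable[tuple[str, str]]) -> AreaLattice:
    """Return a lattice with extra links added (road/ferry connections).

    Used to connect island areas that have no contiguous neighbour so the
    structured spatial prior sees the "true" connectedness. Idempotent for
    edges already present; never removes edges.
    """
    extra = list(extra_edges)
    known = set(lattice.area_ids)
    for a, b in extra:
        if str(a) == str(b):
            raise GeometryError(f"self-loop requested on {a!r}")
        for x in (a, b):
            if str(x) not in known:
                raise GeometryError(f"unknown area id {x!r} in extra edge")
    merged = set(lattice.edges) | {_norm_edge(str(a), str(b)) for a, b in extra}
    return AreaLattice.from_edges(lattice.area_ids, merged,
                                  centroids=lattice.centroids,
                                  polygons=lattice.polygons)


def make_weights(lattice: AreaLattice, style: str = "row_standardized") -> WeightMatrix:
    """Build a spatial weight matrix from a lattice.

    ``binary``: w_ij = 1 for every edge. ``row_standardized``: each
    connected area's row sums to 1. Zero-neighbour areas keep an all-zero
    row and are flagged in the result.
    """
    if style not in ("binary", "row_standardized"):
        raise ValueError(f"unknown weight style {style!r}")
    W = lattice.adjacency_matrix().astype(float)
    if style == "row_standardized":
        deg = lattice.degrees().astype(float)
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        W = sp.diags(inv) @ W
        W = sp.csr_matrix(W)
    S0 = float(W.sum())
    zero = tuple(lattice.singleton_ids())
    return WeightMatrix(lattice, style, W, S0, zero)
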