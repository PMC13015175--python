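"""Contiguity graphs and spatial / spatiotemporal weight matrices.

Areal units (cities) are represented by an ordered :class:`RegionGraph`
whose adjacency is first-order queen contiguity: two units are neighbours
when their boundaries share at least one point (an edge or a single
vertex).  All downstream structures — binary and row-standardised weights
for autocorrelation statistics, the space-time weight matrix, and the
ICAR precision of the Bayesian model — are derived from this graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "RegionGraph",
    "WeightsMatrix",
    "STWeights",
    "build_queen_adjacency",
    "row_standardize",
    "build_st_weights",
    "read_region_geojson",
    "write_edges_csv",
    "write_weights_csv",
    "ST_SCHEMES",
]

ST_SCHEMES = ("contemporaneous+lag0self", "contemporaneous+lag1self", "full_st")


@dataclass(frozen=True)
class RegionGraph:
    """Symmetric, irreflexive adjacency over an ordered set of region ids."""

    region_ids: tuple[str, ...]
    neighbors: Mapping[str, frozenset[str]]
    components: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        ids = set(self.region_ids)
        if len(ids) != len(self.region_ids):
            raise ValueError("duplicate region ids")
        for i, nbrs in self.neighbors.items():
            if i in nbrs:
                raise ValueError(f"self-adjacency at {i!r}")
            for j in nbrs:
                if i not in self.neighbors[j]:
                    raise ValueError("asymmetric adjacency")
        seen: set[str] = set()
        for comp in self.components:
            if comp & seen:
                raise ValueError("overlapping components")
            seen |= comp
        if seen != ids:
            raise ValueError("components do not partition the id set")

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def index(self) -> dict[str, int]:
        return {rid: k for k, rid in enumerate(self.region_ids)}

    def degree(self, rid: str) -> int:
        return len(self.neighbors[rid])

    def isolated(self) -> tuple[str, ...]:
        return tuple(r for r in self.region_ids if not self.neighbors[r])

    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Binary adjacency as a CSR matrix in ``region_ids`` order."""
        idx = self.index()
        rows, cols = [], []
        for i in self.region_ids:
            for j in self.neighbors[i]:
                rows.append(idx[i])
                cols.append(idx[j])
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    @classmethod
    def from_edges(cls, region_ids: Sequence[str],
                   edges: Iterable[tuple[str, str]]) -> "RegionGraph":
        g = nx.Graph()
        g.add_nodes_from(region_ids)
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-edge at {i!r}")
            g.add_edge(i, j)
        nbrs = {r: frozenset(g.neighbors(r)) for r in region_ids}
        comps = tuple(frozenset(c) for c in
                      sorted(nx.connected_components(g), key=min))
        return cls(tuple(region_ids), nbrs, comps)


@dataclass(frozen=True)
class WeightsMatrix:
    """Spatial weights; ``mode`` is ``binary`` or ``row_standardized``."""

    graph: RegionGraph
    mode: str
    matrix: sparse.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "row_standardized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        m = self.matrix
        if m.shape != (self.graph.n, self.graph.n):
            raise ValueError("matrix shape does not match graph")
        if self.mode == "binary":
            vals = np.unique(m.data)
            if vals.size and not np.isin(vals, [0.0, 1.0]).all():
                raise ValueError("binary weights must be 0/1")
        else:
            rs = np.asarray(m.sum(axis=1)).ravel()
            bad = [r for r, s in zip(self.graph.region_ids, rs)
                   if self.graph.neighbors[r] and abs(s - 1.0) > 1e-12]
            if bad:
                raise ValueError(f"rows not summing to 1: {bad[:5]}")

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())


@dataclass(frozen=True)
class STWeights:
    """Joint space-time weights over cells ordered (region-major, year-minor).

    Cell ``(i, t)`` maps to flat index ``i * T + t``, matching the
    row-major flattening of an ``(n, T)`` panel array.
    """

    graph: RegionGraph
    years: tuple[int, ...]
    scheme: str
    matrix: sparse.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        if self.scheme not in ST_SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        nt = self.graph.n * len(self.years)
        if self.matrix.shape != (nt, nt):
            raise ValueError("matrix shape does not match n*T")
        if self.matrix.diagonal().any():
            raise ValueError("nonzero diagonal")
        if (abs(self.matrix - self.matrix.T) > 1e-12).nnz:
            raise ValueError("asymmetric space-time weights")

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())


def build_queen_adjacency(polygons: Mapping[str, BaseGeometry],
                          snap_tolerance: float = 0.0) -> RegionGraph:
    """Queen-contiguity graph: neighbours share >= 1 boundary point.

    ``snap_tolerance`` (off by default) treats boundaries within that
    distance as touching, for sliver-ridden real-world layers; fixtures
    with exact shared vertices need tolerance 0.
    """
    ids = list(polygons)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids")
    geoms = []
    for rid in ids:
        g = polygons[rid]
        if g is None or g.is_empty:
            raise ValueError(f"empty geometry for feature {rid!r}")
        if not g.is_valid:
            raise ValueError(f"invalid geometry for feature {rid!r}")
        geoms.append(g)
    tree = STRtree(geoms)
    edges: set[tuple[str, str]] = set()
    for a, ga in enumerate(geoms):
        query_geom = ga if snap_tolerance <= 0 else ga.buffer(snap_tolerance)
        for b in tree.query(query_geom):
            b = int(b)
            if b <= a:
                continue
            gb = geoms[b]
            if snap_tolerance > 0:
                touch = ga.boundary.dwithin(gb.boundary, snap_tolerance)
            else:
                touch = ga.boundary.intersects(gb.boundary)
            if touch:
                edges.add((ids[a], ids[b]))
    return RegionGraph.from_edges(ids, edges)


def binary_weights(graph: RegionGraph) -> WeightsMatrix:
    """Binary 0/1 weights straight from the adjacency."""
    return WeightsMatrix(graph, "binary", graph.adjacency_matrix())


def row_standardize(binary: WeightsMatrix) -> WeightsMatrix:
    """Divide each row by its sum; isolated (all-zero) rows are kept as-is."""
    if binary.mode != "binary":
        raise ValueError("row_standardize expects a binary WeightsMatrix")
    m = binary.matrix.tocsr(copy=True).astype(float)
    rs = np.asarray(m.sum(axis=1)).ravel()
    inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
    m = sparse.diags(inv) @ m
    return WeightsMatrix(binary.graph, "row_standardized", m.tocsr())


def build_st_weights(graph: RegionGraph, years: Sequence[int],
                     scheme: str = "contemporaneous+lag1self") -> STWeights:
    """Space-time weight matrix combining contiguity and temporal continuity.

    Schemes (all symmetric, zero diagonal, binary):

    * ``contemporaneous+lag0self`` — spatial neighbours within the same
      year only;
    * ``contemporaneous+lag1self`` (default) — additionally each cell is
      linked to itself at adjacent years: ``w=1`` iff ``(i~j and t=s)``
      or ``(i=j and |t-s|=1)``;
    * ``full_st`` — additionally links spatial neighbours at adjacent
      years (``i~j and |t-s|=1``).
    """
    if scheme not in ST_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    years = tuple(years)
    if not years:
        raise ValueError("need at least one year")
    n, big_t = graph.n, len(years)
    a = graph.adjacency_matrix()
    eye_t = sparse.eye(big_t, format="csr")
    # temporal lag-1 structure on the ordered years
    lag = sparse.diags([np.ones(big_t - 1)] * 2, [1, -1], format="csr") \
        if big_t > 1 else sparse.csr_matrix((1, 1))
    m = sparse.kron(a, eye_t, format="csr")
    if scheme in ("contemporaneous+lag1self", "full_st"):
        m = m + sparse.kron(sparse.eye(n, format="csr"), lag, format="csr")
    if scheme == "full_st":
        m = m + sparse.kron(a, lag, format="csr")
    return STWeights(graph, years, scheme, m.tocsr())


def read_region_geojson(path: str) -> tuple[dict[str, BaseGeometry],
                                            dict[str, str]]:
    """Read a FeatureCollection; returns (geometries, city->province map).

    Planar coordinates are assumed; features must carry ``city_id`` and
    ``province_id`` properties.
    """
    with open(path) as fh:
        fc = json.load(fh)
    geoms: dict[str, BaseGeometry] = {}
    provinces: dict[str, str] = {}
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        if "city_id" not in props or "province_id" not in props:
            raise ValueError("feature missing city_id/province_id")
        cid = str(props["city_id"])
        if cid in geoms:
            raise ValueError(f"duplicate city_id {cid!r}")
        geoms[cid] = shape(feat["geometry"])
        provinces[cid] = str(props["province_id"])
    return geoms, provinces


def write_edges_csv(graph: RegionGraph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("i,j\n")
        for i in graph.region_ids:
            for j in sorted(graph.neighbors[i]):
                if i < j:
                    fh.write(f"{i},{j}\n")


def write_weights_csv(w: WeightsMatrix, path: str) -> None:
    ids = w.graph.region_ids
    coo = w.matrix.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write("i,j,w\n")
        for k in order:
            fh.write(f"{ids[coo.row[k]]},{ids[coo.col[k]]},{coo.data[k]:.12g}\n")
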