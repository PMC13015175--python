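import warnings

import numpy as np
import pytest
from shapely.geometry import Polygon

from stmap.geo_weights import RegionGraph, build_queen_adjacency

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


def square(ix: int, iy: int) -> Polygon:
    return Polygon([(ix, iy), (ix + 1, iy), (ix + 1, iy + 1), (ix, iy + 1)])


def lattice_polygons(nx: int, ny: int) -> dict[str, Polygon]:
    return {f"C{iy * nx + ix:03d}": square(ix, iy)
            for iy in range(ny) for ix in range(nx)}


def queen_edges_brute(nx: int, ny: int) -> set[tuple[str, str]]:
    """Independent queen adjacency for a lattice from index arithmetic."""
    def cid(ix, iy):
        return f"C{iy * nx + ix:03d}"
    edges = set()
    for iy in range(ny):
        for ix in range(nx):
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    jx, jy = ix + dx, iy + dy
                    if (dx, dy) != (0, 0) and 0 <= jx < nx and 0 <= jy < ny:
                        a, b = cid(ix, iy), cid(jx, jy)
                        edges.add((min(a, b), max(a, b)))
    return edges


@pytest.fixture(scope="session")
def grid6() -> RegionGraph:
    return build_queen_adjacency(lattice_polygons(6, 6))


@pytest.fixture(scope="session")
def grid4() -> RegionGraph:
    return build_queen_adjacency(lattice_polygons(4, 4))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20130)
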