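"""Toy triangulated cortical surfaces.

The searchlight machinery only needs a connected 2-manifold with vertex
coordinates and edge adjacency. An icosphere — a subdivided icosahedron —
is the simplest closed surface with near-uniform vertex density, so it
stands in for a cortical hemisphere mesh. Regions of interest are grown
as edge-connected vertex patches and recorded in a vertex->region map
(0 = background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import sparse

__all__ = ["SurfaceMesh", "make_toy_surface"]


@dataclass
class SurfaceMesh:
    """Triangle mesh with vertex region labels and cached adjacency."""

    vertices: np.ndarray  # (m, 3)
    faces: np.ndarray  # (f, 3) int
    region_map: np.ndarray  # (m,) int, 0 = background

    _adjacency: sparse.csr_matrix | None = field(default=None, repr=False)
    _neighbors: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.region_map = np.asarray(self.region_map, dtype=int)
        m = len(self.vertices)
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= m:
            raise ValueError("face indices out of range")
        if self.region_map.shape != (m,):
            raise ValueError("region_map must have one entry per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) array with col0 < col1."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @property
    def adjacency(self) -> sparse.csr_matrix:
        if self._adjacency is None:
            e = self.edges
            m = self.n_vertices
            data = np.ones(len(e), dtype=np.int8)
            a = sparse.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(m, m))
            self._adjacency = (a + a.T).tocsr()
        return self._adjacency

    @property
    def neighbors(self) -> list[np.ndarray]:
        """Per-vertex sorted arrays of edge neighbors."""
        if self._neighbors is None:
            a = self.adjacency
            self._neighbors = [a.indices[a.indptr[i]:a.indptr[i + 1]]
                               for i in range(self.n_vertices)]
        return self._neighbors

    def is_connected(self) -> bool:
        n_comp, _ = sparse.csgraph.connected_components(self.adjacency, directed=False)
        return n_comp == 1

    def region_vertices(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.region_map == region)

    @property
    def n_regions(self) -> int:
        return int(self.region_map.max())

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + len(self.faces)

    def to_obj(self, path: str | Path) -> None:
        mesh = trimesh.Trimesh(self.vertices, self.faces, process=False)
        Path(path).write_text(trimesh.exchange.obj.export_obj(mesh))

    @classmethod
    def from_obj(cls, path: str | Path,
                 region_map: np.ndarray | None = None) -> "SurfaceMesh":
        mesh = trimesh.load(str(path), file_type="obj", process=False)
        m = len(mesh.vertices)
        rm = np.zeros(m, dtype=int) if region_map is None else region_map
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), rm)


def make_toy_surface(
    subdivisions: int = 3,
    n_regions: int = 1,
    region_size: int = 30,
    seed: int = 0,
) -> SurfaceMesh:
    """Icosphere with ``n_regions`` disjoint edge-connected vertex patches.

    An icosphere with s subdivisions has ``10 * 4**s + 2`` vertices and
    ``20 * 4**s`` faces. Regions are grown breadth-first from random seed
    vertices until each holds ``region_size`` vertices; growth is
    deterministic for a fixed seed.
    """
    if subdivisions < 2:
        raise ValueError("need subdivisions >= 2 for a usable vertex count")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    vertices = np.asarray(ico.vertices, dtype=float)
    faces = np.asarray(ico.faces, dtype=int)
    m = len(vertices)
    if n_regions * region_size > m:
        raise ValueError(
            f"{n_regions} regions of {region_size} vertices exceed the "
            f"{m}-vertex mesh"
        )
    mesh = SurfaceMesh(vertices, faces, np.zeros(m, dtype=int))
    rng = np.random.default_rng(seed)
    region_map = np.zeros(m, dtype=int)
    neighbors = mesh.neighbors
    order = rng.permutation(m)
    cursor = 0
    for rid in range(1, n_regions + 1):
        # first free vertex in the random order seeds the region
        while cursor < m and region_map[order[cursor]] != 0:
            cursor += 1
        if cursor >= m:
            raise ValueError("ran out of free vertices while placing regions")
        seed_v = order[cursor]
        grown = [seed_v]
        region_map[seed_v] = rid
        frontier = [seed_v]
        while len(grown) < region_size:
            candidates = sorted(
                {int(nb) for v in frontier for nb in neighbors[v]
                 if region_map[nb] == 0}
            )
            if not candidates:
                raise ValueError(
                    f"region {rid} blocked at {len(grown)} vertices; "
                    "reduce region_size or n_regions"
                )
            take = candidates[: region_size - len(grown)]
            for v in take:
                region_map[v] = rid
            grown.extend(take)
            frontier = take
    mesh.region_map = region_map
    return mesh
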