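"""Two-hemisphere icosphere surface meshes.

A cortical-surface stand-in: each hemisphere is a recursively subdivided
icosahedron projected to the unit sphere, mirroring the standard
``fsaverageN`` family of templates (subdivision level 6 gives 40,962
vertices per hemisphere).  The two hemispheres are identical icospheres
with disjoint vertex blocks and no connecting edges; all analyses treat
them as a single vertex set, left hemisphere first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

MAX_SUBDIVISION_LEVEL = 7


class ResolutionError(ValueError):
    """Requested mesh resolution exceeds the desk-scale guard."""


def vertices_per_hemisphere(level: int) -> int:
    """Closed-form icosphere vertex count, 10 * 4**level + 2."""
    return 10 * 4**level + 2


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Canonical unit icosahedron (12 vertices, 20 faces, 0-based)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One 4-fold midpoint subdivision with shared-edge deduplication.

    New vertices are appended in lexicographic order of the (sorted)
    edge they bisect, which makes vertex ordering deterministic for a
    given level.
    """
    edges = np.vstack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
    )
    edges.sort(axis=1)
    uniq, inverse = np.unique(edges, axis=0, return_inverse=True)
    mid = verts[uniq[:, 0]] + verts[uniq[:, 1]]
    mid /= np.linalg.norm(mid, axis=1, keepdims=True)
    new_verts = np.vstack([verts, mid])

    n = len(verts)
    m01 = n + inverse[: len(faces)]
    m12 = n + inverse[len(faces): 2 * len(faces)]
    m20 = n + inverse[2 * len(faces):]
    v0, v1, v2 = faces[:, 0], faces[:, 1], faces[:, 2]
    new_faces = np.vstack(
        [
            np.column_stack([v0, m01, m20]),
            np.column_stack([v1, m12, m01]),
            np.column_stack([v2, m20, m12]),
            np.column_stack([m01, m12, m20]),
        ]
    )
    return new_verts, new_faces


def _single_icosphere(level: int) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = _icosahedron()
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)
    return verts, faces


@dataclass
class SurfaceMesh:
    """Triangulated two-hemisphere surface.

    Vertices of the left hemisphere occupy the lower index block
    ``[0, n_per_hemisphere)``; the right hemisphere follows.  Both
    hemispheres lie on the unit sphere (registered spheres, as in
    surface-based fMRI); they share no edges.
    """

    vertices: np.ndarray          # (V, 3) float64, unit norm
    faces: np.ndarray             # (F, 3) int64, 0-based
    hemisphere: np.ndarray        # (V,) '<U1', 'L' or 'R'
    zone_label: np.ndarray        # (V,) int64, -1 = no zone
    level: int
    _adj: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_per_hemisphere(self) -> int:
        return int(np.sum(self.hemisphere == "L"))

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean vertex adjacency (cached)."""
        if self._adj is None:
            i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
            j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
            data = np.ones(len(i), dtype=np.int8)
            a = sp.coo_matrix((data, (i, j)), shape=(self.n_vertices,) * 2)
            a = a + a.T
            a.data[:] = 1
            self._adj = a.tocsr()
        return self._adj

    def hop_distance(self, sources, limit: float = np.inf) -> np.ndarray:
        """Graph-hop distance from source vertices (inf beyond ``limit``).

        Returns shape (len(sources), V) if sources is a sequence, else (V,).
        """
        return dijkstra(
            self.adjacency(), unweighted=True, indices=sources,
            limit=limit, min_only=False,
        )

    def geodesic_disc(self, center: int, radius: int) -> np.ndarray:
        """Vertex indices within ``radius`` hops of ``center``."""
        d = self.hop_distance(center, limit=radius)
        return np.flatnonzero(np.isfinite(d))

    def neighbors(self, v: int) -> np.ndarray:
        a = self.adjacency()
        return a.indices[a.indptr[v]: a.indptr[v + 1]]

    def validate(self) -> None:
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise ValueError("face references an invalid vertex index")
        nh = self.n_per_hemisphere
        if nh != vertices_per_hemisphere(self.level):
            raise ValueError("per-hemisphere vertex count off the 10*4^L+2 formula")
        n_comp, comp = connected_components(self.adjacency(), directed=False)
        if n_comp != 2:
            raise ValueError(f"expected 2 connected components, found {n_comp}")
        if len(np.unique(comp[: nh])) != 1 or len(np.unique(comp[nh:])) != 1:
            raise ValueError("hemispheres are not each a single component")


def build_icosphere(level: int) -> SurfaceMesh:
    """Build a two-hemisphere icosphere mesh at a subdivision level.

    Each hemisphere has ``10 * 4**level + 2`` vertices and
    ``20 * 4**level`` faces; level 6 matches the 40,962 vertices per
    hemisphere of a standard high-resolution surface template.

    Parameters
    ----------
    level : int
        Number of 4-fold midpoint subdivisions, 0..7.
    """
    if level < 0:
        raise ValueError("subdivision level must be non-negative")
    if level > MAX_SUBDIVISION_LEVEL:
        raise ResolutionError(
            f"subdivision level {level} exceeds the guard "
            f"({MAX_SUBDIVISION_LEVEL}); larger meshes are not supported"
        )
    verts, faces = _single_icosphere(level)
    n = len(verts)
    vertices = np.vstack([verts, verts])
    all_faces = np.vstack([faces, faces + n])
    hemi = np.array(["L"] * n + ["R"] * n)
    zones = np.full(2 * n, -1, dtype=np.int64)
    return SurfaceMesh(vertices=vertices, faces=all_faces, hemisphere=hemi,
                       zone_label=zones, level=level)
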