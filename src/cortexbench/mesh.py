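"""Unit-sphere triangle meshes standing in for FreeSurfer spherical templates.

Real analyses resample each subject's cortical surface to a common spherical
template (e.g. fsaverage6, ~37.7k vertices per hemisphere) so that vertex v
means the same anatomical location in every subject.  Here an icosphere plays
that role at configurable resolution; all downstream code only assumes unit
vertices with a fixed ordering.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass(frozen=True)
class SphereMesh:
    """Closed triangulated mesh on the unit sphere.

    vertices : (n, 3) float64, each row unit-norm
    faces    : (m, 3) int, counter-clockwise triangles
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("SphereMesh vertices must lie on the unit sphere")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def fingerprint(self) -> str:
        """Stable hash identifying (vertices, faces) for provenance checks."""
        h = hashlib.sha256()
        h.update(np.round(self.vertices, 12).tobytes())
        h.update(self.faces.tobytes())
        return h.hexdigest()[:16]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def median_edge_angle(self) -> float:
        """Median great-circle length of mesh edges, radians."""
        e = self.edges()
        dots = np.einsum("ij,ij->i", self.vertices[e[:, 0]], self.vertices[e[:, 1]])
        return float(np.median(np.arccos(np.clip(dots, -1.0, 1.0))))

    def vertex_neighbors(self) -> list[np.ndarray]:
        """Adjacency list (sorted neighbor indices per vertex)."""
        e = self.edges()
        nbrs: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for a, b in e:
            nbrs[a].append(b)
            nbrs[b].append(a)
        return [np.array(sorted(n), dtype=np.int64) for n in nbrs]

    def is_closed_manifold(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def make_icosphere(subdivision_level: int) -> SphereMesh:
    """Icosahedron subdivided `subdivision_level` times, renormalized to radius 1.

    Vertex count is 10 * 4**level + 2 (12, 42, 162, 642, 2562, ...).  Level 4
    (2,562 vertices) is the desk-scale default template; level 6 would match
    fsaverage6's order of magnitude.
    """
    if not isinstance(subdivision_level, (int, np.integer)):
        raise TypeError("subdivision_level must be an integer")
    if not 0 <= subdivision_level <= 7:
        raise ValueError(f"subdivision_level must be in [0, 7], got {subdivision_level}")
    tm = trimesh.creation.icosphere(subdivisions=int(subdivision_level), radius=1.0)
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    return SphereMesh(vertices=vertices, faces=np.asarray(tm.faces, dtype=np.int64))


def spherical_angles(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(latitude, longitude) in radians for unit 3-vectors.

    latitude = arcsin(z) in [-pi/2, pi/2]; longitude = atan2(y, x) in (-pi, pi].
    """
    v = np.atleast_2d(np.asarray(vertices, dtype=np.float64))
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero vector has no spherical angles")
    v = v / norms[:, None]
    lat = np.arcsin(np.clip(v[:, 2], -1.0, 1.0))
    lon = np.arctan2(v[:, 1], v[:, 0])
    # atan2 returns -pi for (-1, -0); fold to the half-open (-pi, pi] convention
    lon = np.where(lon <= -np.pi, np.pi, lon)
    return lat, lon
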