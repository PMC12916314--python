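"""Spherical-to-planar projection of vertex-wise maps.

Two projection families are compared throughout: the equirectangular
latitude/longitude map (simple, but area-inflating near the poles) and the
Lambert cylindrical equal-area map, whose Jacobian is constant so equal
sphere areas occupy equal image areas — the defining property of
area-preserving cortical projections.

Conventions (fixed): row 0 at latitude +pi/2 (north at top), longitude
half-open in (-pi, pi] with lambda = 0 at the image center column; forward
maps are linear onto [0, H-1] x [0, W-1] so the poles sit exactly on the
first/last rows and (0, 0) on the center pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import SphereMesh, spherical_angles

_EPS_DIST = 1e-8  # radians, regularizer for inverse-distance weights

PROJECTION_METHODS = ("latlong", "equal_area")


@dataclass(frozen=True)
class ProjectionGrid:
    height: int = 224
    width: int = 224
    method: str = "equal_area"

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("grid must be at least 8 x 8")
        if self.method not in PROJECTION_METHODS:
            raise ValueError(f"method must be one of {PROJECTION_METHODS}")


def _check_unit(vertices: np.ndarray) -> np.ndarray:
    v = np.atleast_2d(np.asarray(vertices, dtype=np.float64))
    n = np.linalg.norm(v, axis=1)
    if np.any(n < 1e-12):
        raise ValueError("zero vector cannot be projected")
    return v / n[:, None]


def latlong_coords(vertices: np.ndarray, grid: ProjectionGrid) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular forward map: row ∝ latitude, col ∝ longitude."""
    v = _check_unit(vertices)
    lat, lon = spherical_angles(v)
    row = (0.5 - lat / np.pi) * (grid.height - 1)
    col = (lon / np.pi + 1.0) / 2.0 * (grid.width - 1)
    return row, col


def equal_area_coords(vertices: np.ndarray, grid: ProjectionGrid) -> tuple[np.ndarray, np.ndarray]:
    """Lambert cylindrical equal-area forward map: row ∝ sin(latitude)."""
    v = _check_unit(vertices)
    lat, lon = spherical_angles(v)
    row = (1.0 - np.sin(lat)) / 2.0 * (grid.height - 1)
    col = (lon / np.pi + 1.0) / 2.0 * (grid.width - 1)
    return row, col


def forward_coords(vertices: np.ndarray, grid: ProjectionGrid) -> tuple[np.ndarray, np.ndarray]:
    if grid.method == "latlong":
        return latlong_coords(vertices, grid)
    return equal_area_coords(vertices, grid)


def _pixel_centers_on_sphere(grid: ProjectionGrid) -> np.ndarray:
    """Inverse-project every pixel center to the unit sphere, (H*W, 3)."""
    r = np.arange(grid.height, dtype=np.float64)
    c = np.arange(grid.width, dtype=np.float64)
    lon = (2.0 * c / (grid.width - 1) - 1.0) * np.pi
    if grid.method == "latlong":
        lat = (0.5 - r / (grid.height - 1)) * np.pi
    else:
        lat = np.arcsin(np.clip(1.0 - 2.0 * r / (grid.height - 1), -1.0, 1.0))
    latg, long_ = np.meshgrid(lat, lon, indexing="ij")
    x = np.cos(latg) * np.cos(long_)
    y = np.cos(latg) * np.sin(long_)
    z = np.sin(latg)
    return np.stack([x, y, z], axis=-1).reshape(-1, 3)


@dataclass
class ProjectionMap:
    """Precomputed pixel -> vertex interpolation for one (mesh, grid) pair.

    vertex_idx : (H*W, k) int    — contributing vertices per pixel
    weights    : (H*W, k) float  — nonnegative, rows sum to 1 on valid pixels
    valid      : (H, W) bool     — False where the nearest vertex exceeds max_angle
    """

    grid: ProjectionGrid
    vertex_idx: np.ndarray
    weights: np.ndarray
    valid: np.ndarray
    mesh_fingerprint: str
    n_vertices: int
    k_neighbors: int
    max_angle: float

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("vertex_idx", data=self.vertex_idx)
            f.create_dataset("weights", data=self.weights)
            f.create_dataset("valid", data=self.valid)
            f.attrs["meta"] = json.dumps({
                "height": self.grid.height, "width": self.grid.width,
                "method": self.grid.method, "mesh_fingerprint": self.mesh_fingerprint,
                "n_vertices": self.n_vertices, "k_neighbors": self.k_neighbors,
                "max_angle": self.max_angle,
            })

    @classmethod
    def load(cls, path) -> "ProjectionMap":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            return cls(
                grid=ProjectionGrid(meta["height"], meta["width"], meta["method"]),
                vertex_idx=f["vertex_idx"][()],
                weights=f["weights"][()],
                valid=f["valid"][()],
                mesh_fingerprint=meta["mesh_fingerprint"],
                n_vertices=meta["n_vertices"],
                k_neighbors=meta["k_neighbors"],
                max_angle=meta["max_angle"],
            )


def build_projection(
    mesh: SphereMesh,
    grid: ProjectionGrid,
    k_neighbors: int = 3,
    max_angle: float | None = None,
) -> ProjectionMap:
    """Inverse-distance interpolation map from pixel centers to mesh vertices.

    Each pixel center is inverse-projected to the sphere; its k nearest mesh
    vertices (great-circle metric) contribute with weights ∝ 1/(angle + eps).
    Pixels whose nearest vertex is farther than `max_angle` (default: 3x the
    mesh's median edge length) are marked invalid and render as 0.
    """
    if mesh.n_vertices == 0:
        raise ValueError("mesh has no vertices")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    k = min(k_neighbors, mesh.n_vertices)
    if max_angle is None:
        max_angle = 3.0 * mesh.median_edge_angle() if mesh.n_vertices > 1 else np.pi
    centers = _pixel_centers_on_sphere(grid)
    tree = cKDTree(mesh.vertices)
    chord, idx = tree.query(centers, k=k)
    chord = np.atleast_2d(chord.reshape(len(centers), k))
    idx = idx.reshape(len(centers), k)
    angle = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    valid = (angle[:, 0] <= max_angle).reshape(grid.height, grid.width)
    w = 1.0 / (angle + _EPS_DIST)
    w /= w.sum(axis=1, keepdims=True)
    return ProjectionMap(
        grid=grid, vertex_idx=idx.astype(np.int64), weights=w, valid=valid,
        mesh_fingerprint=mesh.fingerprint(), n_vertices=mesh.n_vertices,
        k_neighbors=k, max_angle=float(max_angle),
    )


@dataclass
class ImageStack:
    """Subjects x channels x H x W image array with per-channel validity masks."""

    data: np.ndarray
    channels: list[str]
    valid_mask: np.ndarray          # (C, H, W) bool
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("ImageStack data must be (subjects, channels, H, W)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel labels do not match data")
        if self.valid_mask.shape != self.data.shape[1:]:
            raise ValueError("valid_mask must be (channels, H, W)")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("valid_mask", data=self.valid_mask)
            f.attrs["meta"] = json.dumps(
                {"channels": self.channels, "normalized": self.normalized})

    @classmethod
    def load(cls, path) -> "ImageStack":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            return cls(data=f["data"][()], channels=list(meta["channels"]),
                       valid_mask=f["valid_mask"][()], normalized=meta["normalized"])


def project_features(pmap: ProjectionMap, values: np.ndarray) -> np.ndarray:
    """Render (subjects, n_vertices) maps to (subjects, H, W) image planes.

    Linear in the vertex values; invalid pixels are 0.
    """
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    if values.shape[1] != pmap.n_vertices:
        raise ValueError(
            f"feature maps have {values.shape[1]} vertices, projection expects "
            f"{pmap.n_vertices}"
        )
    px = np.einsum("spk,pk->sp", values[:, pmap.vertex_idx], pmap.weights)
    img = px.reshape(values.shape[0], pmap.grid.height, pmap.grid.width)
    img[:, ~pmap.valid] = 0.0
    return img


def stack_images(
    planes: dict[str, np.ndarray], masks: dict[str, np.ndarray]
) -> ImageStack:
    """Assemble per-channel (S, H, W) planes into an ImageStack (channel-sorted input order)."""
    channels = list(planes)
    data = np.stack([planes[c] for c in channels], axis=1)
    valid = np.stack([masks[c] for c in channels], axis=0)
    return ImageStack(data=data, channels=channels, valid_mask=valid)


def znormalize_images(stack: ImageStack) -> ImageStack:
    """Per subject x channel plane: mean 0, SD 1 over valid pixels; invalid pixels 0.

    Constant planes (SD ~ 0) become all-zero rather than dividing by zero.
    """
    out = stack.data.copy()
    for c in range(out.shape[1]):
        m = stack.valid_mask[c]
        if not m.any():
            out[:, c] = 0.0
            continue
        vals = out[:, c][:, m]                      # (S, n_valid)
        mean = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        normed = np.where(sd > 1e-12, (vals - mean) / np.where(sd > 1e-12, sd, 1.0), 0.0)
        plane = np.zeros_like(out[:, c])
        plane[:, m] = normed
        out[:, c] = plane
    return ImageStack(data=out, channels=list(stack.channels),
                      valid_mask=stack.valid_mask.copy(), normalized=True)


def area_distortion_profile(
    pmap: ProjectionMap, mesh: SphereMesh, n_bands: int | None = None
) -> pd.DataFrame:
    """Vertex counts per image-row band — the QC diagnostic for area distortion.

    Under the equal-area map a uniform mesh lands uniformly across bands; under
    latitude/longitude the density follows cos(latitude), collapsing at the poles.
    """
    if n_bands is None:
        n_bands = min(8, pmap.grid.height)
    rows, _ = forward_coords(mesh.vertices, pmap.grid)
    edges = np.linspace(0.0, pmap.grid.height - 1.0, n_bands + 1)
    counts, _ = np.histogram(rows, bins=edges)
    return pd.DataFrame({
        "band": np.arange(n_bands),
        "row_start": edges[:-1],
        "row_end": edges[1:],
        "n_vertices": counts,
        "density": counts / max(mesh.n_vertices, 1),
    })
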