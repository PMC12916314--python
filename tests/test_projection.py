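import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chisquare

from cortexbench.mesh import SphereMesh
from cortexbench.projection import (
    ImageStack,
    ProjectionGrid,
    ProjectionMap,
    area_distortion_profile,
    build_projection,
    equal_area_coords,
    latlong_coords,
    project_features,
    stack_images,
    znormalize_images,
)

GRID = ProjectionGrid(64, 64, "latlong")
EA_GRID = ProjectionGrid(64, 64, "equal_area")


def uniform_sphere(n, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestForwardCoords:
    def test_latlong_center_poles_and_quarter_turn(self):
        h, w = GRID.height, GRID.width
        row, col = latlong_coords(np.array([1.0, 0, 0]), GRID)
        assert row[0] == pytest.approx((h - 1) / 2) and col[0] == pytest.approx((w - 1) / 2)
        row, _ = latlong_coords(np.array([0.0, 0, 1]), GRID)
        assert row[0] == pytest.approx(0.0)
        row, col = latlong_coords(np.array([0.0, 1, 0]), GRID)
        assert col[0] == pytest.approx(3 * (w - 1) / 4) and row[0] == pytest.approx((h - 1) / 2)

    def test_equal_area_center_and_sin_latitude_rows(self):
        h = EA_GRID.height
        row, col = equal_area_coords(np.array([1.0, 0, 0]), EA_GRID)
        assert row[0] == pytest.approx((h - 1) / 2)
        # [0, 30] and [30, 90] degree latitude bands have equal sphere area
        # (sin 30 = 1/2) and must span equal numbers of rows
        def row_of(lat):
            v = np.array([np.cos(lat), 0.0, np.sin(lat)])
            return equal_area_coords(v, EA_GRID)[0][0]
        assert row_of(0) - row_of(np.pi / 6) == pytest.approx(row_of(np.pi / 6) - row_of(np.pi / 2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            latlong_coords(np.zeros(3), GRID)
        with pytest.raises(ValueError):
            equal_area_coords(np.zeros(3), EA_GRID)

    def test_uniform_points_fill_equal_area_bands_uniformly(self):
        """The analytic equal-area property, Monte-Carlo: 10k uniform points, 8 bands."""
        pts = uniform_sphere(10_000, seed=1)
        edges = np.linspace(0, EA_GRID.height - 1, 9)
        rows_ea, _ = equal_area_coords(pts, EA_GRID)
        rows_ll, _ = latlong_coords(pts, GRID)
        p_ea = chisquare(np.histogram(rows_ea, bins=edges)[0]).pvalue
        p_ll = chisquare(np.histogram(rows_ll, bins=edges)[0]).pvalue
        assert p_ea > 0.01
        assert p_ll < 1e-6


class TestBuildProjection:
    def test_weights_normalized_and_deterministic(self, mesh3):
        p1 = build_projection(mesh3, EA_GRID)
        p2 = build_projection(mesh3, EA_GRID)
        valid = p1.valid.ravel()
        assert np.allclose(p1.weights[valid].sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(p1.weights, p2.weights) and np.array_equal(p1.vertex_idx, p2.vertex_idx)

    def test_k1_gives_unit_weights(self, mesh3):
        p = build_projection(mesh3, EA_GRID, k_neighbors=1)
        assert np.allclose(p.weights, 1.0)

    def test_nearest_vertex_dominates(self, mesh3):
        p = build_projection(mesh3, EA_GRID, k_neighbors=3)
        assert np.all(p.weights[:, 0] >= p.weights[:, 1:].max(axis=1) - 1e-12)

    def test_constant_map_projects_to_constant(self, mesh3):
        p = build_projection(mesh3, EA_GRID)
        img = project_features(p, np.full((1, mesh3.n_vertices), 7.0))
        assert np.allclose(img[0][p.valid], 7.0)
        assert not img[0][~p.valid].any()

    def test_empty_mesh_rejected(self):
        empty = SphereMesh(vertices=np.empty((0, 3)), faces=np.empty((0, 3), dtype=int))
        with pytest.raises(ValueError):
            build_projection(empty, EA_GRID)

    def test_save_load_round_trip(self, mesh2, tmp_path):
        p = build_projection(mesh2, EA_GRID)
        p.save(tmp_path / "pmap.h5")
        q = ProjectionMap.load(tmp_path / "pmap.h5")
        assert np.array_equal(p.weights, q.weights)
        assert q.grid == p.grid and q.mesh_fingerprint == p.mesh_fingerprint


class TestProjectFeatures:
    def test_zero_maps_give_zero_images(self, mesh3):
        p = build_projection(mesh3, EA_GRID)
        assert not project_features(p, np.zeros((3, mesh3.n_vertices))).any()

    def test_linearity(self, mesh3):
        p = build_projection(mesh3, EA_GRID)
        rng = np.random.default_rng(8)
        x = rng.standard_normal((2, mesh3.n_vertices))
        y = rng.standard_normal((2, mesh3.n_vertices))
        lhs = project_features(p, 2 * x - y)
        rhs = 2 * project_features(p, x) - project_features(p, y)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_mesh_mismatch_rejected(self, mesh2, mesh3):
        p = build_projection(mesh2, EA_GRID)
        with pytest.raises(ValueError):
            project_features(p, np.zeros((1, mesh3.n_vertices)))

    def test_cap_indicator_covers_its_area_fraction(self, mesh4):
        """A 30-degree cap occupies (1 - cos 30)/2 of the sphere, hence of the image.

        Nearest-vertex rendering (k=1) keeps the cap boundary unbiased; higher
        k smears an interpolation ring outward.
        """
        p = build_projection(mesh4, EA_GRID, k_neighbors=1)
        cap = (mesh4.vertices[:, 2] >= np.cos(np.pi / 6)).astype(float)
        img = project_features(p, cap[None, :])[0]
        frac = (img[p.valid] > 0).mean()
        assert frac == pytest.approx((1 - np.cos(np.pi / 6)) / 2, abs=0.01)


class TestZNormalize:
    def _stack(self, data, valid=None):
        c, h, w = data.shape[1:]
        if valid is None:
            valid = np.ones((c, h, w), dtype=bool)
        return ImageStack(data=data, channels=[f"ch{i}" for i in range(c)], valid_mask=valid)

    def test_constant_plane_becomes_zero(self):
        out = znormalize_images(self._stack(np.full((1, 1, 8, 8), 5.0)))
        assert not out.data.any() and out.normalized

    def test_two_value_plane(self):
        plane = np.ones((8, 8)) * 1.0
        plane[:, 4:] = 3.0
        out = znormalize_images(self._stack(plane[None, None]))
        assert set(np.unique(out.data)) == {-1.0, 1.0}

    def test_random_plane_standardized(self):
        rng = np.random.default_rng(2)
        out = znormalize_images(self._stack(rng.standard_normal((3, 2, 16, 16))))
        flat = out.data.reshape(6, -1)
        assert np.abs(flat.mean(axis=1)).max() < 1e-9
        assert np.allclose(flat.std(axis=1), 1.0, atol=1e-9)

    def test_invalid_pixels_excluded_then_zeroed(self):
        valid = np.ones((1, 8, 8), dtype=bool)
        valid[0, :2] = False
        rng = np.random.default_rng(3)
        out = znormalize_images(self._stack(rng.standard_normal((2, 1, 8, 8)), valid))
        assert not out.data[:, 0, :2].any()
        inside = out.data[:, 0][:, valid[0]]
        assert np.abs(inside.mean(axis=1)).max() < 1e-9


class TestAreaDistortionProfile:
    def test_equal_area_density_flat(self, mesh4):
        p = build_projection(mesh4, EA_GRID)
        prof = area_distortion_profile(p, mesh4, n_bands=8)
        interior = prof["n_vertices"].iloc[1:-1]
        assert interior.max() / interior.min() < 1.5

    def test_latlong_polar_bands_sparser(self, mesh4):
        p = build_projection(mesh4, GRID)
        prof = area_distortion_profile(p, mesh4, n_bands=8)
        counts = prof["n_vertices"].to_numpy()
        assert counts[0] < counts[3] and counts[-1] < counts[4]

    def test_single_vertex_mesh_single_band(self):
        mesh = SphereMesh(vertices=np.array([[0.0, 0.0, 1.0]]), faces=np.empty((0, 3), dtype=int))
        p = build_projection(mesh, EA_GRID, k_neighbors=1, max_angle=np.pi)
        prof = area_distortion_profile(p, mesh, n_bands=8)
        assert (prof["n_vertices"] > 0).sum() == 1


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_projection_preserves_total_weight_property(seed):
    """Any vertex map bounded in [lo, hi] projects into [lo, hi] (convex weights)."""
    rng = np.random.default_rng(seed)
    import cortexbench as cb
    mesh = cb.make_icosphere(1)
    p = build_projection(mesh, ProjectionGrid(16, 16, "equal_area"))
    m = rng.uniform(-2.0, 5.0, (1, mesh.n_vertices))
    img = project_features(p, m)[0][p.valid]
    assert img.min() >= m.min() - 1e-9 and img.max() <= m.max() + 1e-9
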