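"""Ribbon intensity sampling and closest-distance thickness."""

import numpy as np
import pytest
import trimesh.triangles as tmtri

from gwrkit.io import VolumeGrid
from gwrkit.mesh import TriangleMesh
from gwrkit.phantom import PhantomSpec, build_shell_phantom, icosphere
from gwrkit.sampling import (
    SamplerConfig,
    compute_thickness,
    point_mesh_distance,
    sample_gm_intensity,
    sample_wm_intensity,
)


def flat_grid_mesh(n: int = 5, spacing: float = 1.0, z: float = 0.0) -> TriangleMesh:
    """n x n planar grid in the xy plane at height z, upward-facing faces."""
    xs = np.arange(n) * spacing
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + n, a + 1], [a + 1, a + n, a + n + 1]]
    return TriangleMesh(verts, np.array(faces))


def linear_z_volume(shape=(12, 12, 12)) -> VolumeGrid:
    """I(x, y, z) = z with an identity affine."""
    data = np.broadcast_to(np.arange(shape[2], dtype=float), shape).copy()
    return VolumeGrid(data, np.eye(4))


def uniform_volume(value=100.0, shape=(10, 10, 10)) -> VolumeGrid:
    return VolumeGrid(np.full(shape, value), np.eye(4))


class TestGmSampling:
    def test_uniform_field_sampled_exactly(self):
        white = flat_grid_mesh(5, 1.0, z=3.0)
        pial = flat_grid_mesh(5, 1.0, z=6.0)
        white = TriangleMesh(white.vertices + [2, 2, 0], white.faces)
        pial = TriangleMesh(pial.vertices + [2, 2, 0], pial.faces)
        gm = sample_gm_intensity(uniform_volume(), white, pial)
        assert np.abs(gm.values - 100.0).max() < 1e-6

    def test_linear_field_at_35pct_depth(self):
        # white at z=0, pial at z=2, depth 0.35 -> I = 0.70 exactly
        white = flat_grid_mesh(5, 1.0, z=0.0)
        pial = flat_grid_mesh(5, 1.0, z=2.0)
        shift = np.array([3, 3, 0])
        white = TriangleMesh(white.vertices + shift, white.faces)
        pial = TriangleMesh(pial.vertices + shift, pial.faces)
        gm = sample_gm_intensity(linear_z_volume(), white, pial, SamplerConfig())
        assert np.abs(gm.values - 0.70).max() < 1e-6

    def test_noiseless_shell_gives_pure_gm(self):
        spec = PhantomSpec(
            white_radius=30,
            thickness_base=3.0,
            thickness_amplitude=0.0,
            noise_sd=0.0,
            voxel_size=0.5,
            subdivision=3,
            seed=0,
        )
        white, pial, vol, _ = build_shell_phantom(spec)
        gm = sample_gm_intensity(vol, white, pial)
        assert gm.n_missing == 0
        assert np.abs(gm.values - spec.intensity_gm).max() < 1e-9

    def test_mismatched_vertex_counts_raise(self):
        white = flat_grid_mesh(4)
        pial = flat_grid_mesh(5)
        with pytest.raises(ValueError, match="vertex counts"):
            sample_gm_intensity(uniform_volume(), white, pial)

    def test_out_of_volume_is_missing(self):
        white = flat_grid_mesh(3, 1.0, z=0.0)
        pial = flat_grid_mesh(3, 1.0, z=50.0)  # sample point leaves the 10^3 volume
        gm = sample_gm_intensity(uniform_volume(), white, pial)
        assert gm.missing.all()


class TestWmSampling:
    def test_uniform_field(self):
        white, pial, vol, _ = build_shell_phantom(
            PhantomSpec(white_radius=10, voxel_size=1.0, subdivision=2, noise_sd=0,
                        thickness_amplitude=0.0, seed=0)
        )
        wm = sample_wm_intensity(uniform_volume(100.0, (40, 40, 40)),
                                 TriangleMesh(white.vertices + 20, white.faces))
        assert np.abs(wm.valid_values() - 100.0).max() < 1e-9

    def test_sphere_sample_lands_in_wm(self):
        spec = PhantomSpec(
            white_radius=30, thickness_base=3.0, thickness_amplitude=0.0,
            noise_sd=0.0, voxel_size=0.5, subdivision=3, seed=0,
        )
        white, _, vol, _ = build_shell_phantom(spec)
        wm = sample_wm_intensity(vol, white, SamplerConfig(wm_offset=1.0))
        assert wm.n_missing == 0
        assert np.abs(wm.values - spec.intensity_wm).max() < 1e-9

    def test_linear_field_along_normal(self):
        # white patch at z=5 facing +z; 1 mm inward -> z=4 -> I = 4.0
        white = flat_grid_mesh(5, 1.0, z=5.0)
        white = TriangleMesh(white.vertices + [3, 3, 0], white.faces)
        wm = sample_wm_intensity(linear_z_volume(), white, SamplerConfig(wm_offset=1.0))
        assert np.abs(wm.values - 4.0).max() < 1e-6


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(gm_depth_fraction=0.0),
        dict(gm_depth_fraction=1.0),
        dict(wm_offset=0.0),
        dict(interpolation="nearest"),
        dict(out_of_volume_policy="clamp"),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SamplerConfig(**kwargs)


def brute_force_point_mesh(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Oracle: exact distance to every triangle, take the minimum."""
    tris = mesh.vertices[mesh.faces]
    out = np.empty(len(points))
    for i, p in enumerate(points):
        closest = tmtri.closest_point(tris, np.tile(p, (len(tris), 1)))
        out[i] = np.linalg.norm(closest - p, axis=1).min()
    return out


class TestThickness:
    def test_concentric_spheres(self):
        white = icosphere(4, 30.0)
        pial = TriangleMesh(white.vertices * (33.0 / 30.0), white.faces)
        t = compute_thickness(white, pial)
        assert np.abs(t.values - 3.0).max() / 3.0 < 0.02

    def test_identical_meshes_give_zero(self, ico1):
        t = compute_thickness(ico1, ico1)
        assert np.abs(t.values).max() < 1e-12

    def test_parallel_flat_patches(self):
        white = flat_grid_mesh(7, 1.0, z=0.0)
        pial = flat_grid_mesh(7, 1.0, z=2.5)
        t = compute_thickness(white, pial)
        interior = np.all((white.vertices[:, :2] >= 1) & (white.vertices[:, :2] <= 5), axis=1)
        assert np.abs(t.values[interior] - 2.5).max() < 1e-9

    def test_symmetry(self, ico3_r30):
        pial = TriangleMesh(ico3_r30.vertices * 1.1, ico3_r30.faces)
        a = compute_thickness(ico3_r30, pial)
        b = compute_thickness(pial, ico3_r30)
        assert np.allclose(a.values, b.values)

    def test_candidate_search_matches_brute_force(self, rng):
        mesh = icosphere(2, 10.0)
        bumpy = TriangleMesh(
            mesh.vertices * (1 + 0.1 * rng.standard_normal((mesh.n_vertices, 1))),
            mesh.faces,
        )
        points = rng.normal(scale=8.0, size=(50, 3))
        fast = point_mesh_distance(points, bumpy)
        slow = brute_force_point_mesh(points, bumpy)
        assert np.abs(fast - slow).max() < 1e-9

    def test_intersecting_surfaces_warn(self, ico1):
        inner = TriangleMesh(ico1.vertices * 0.5, ico1.faces)  # pial inside white
        with pytest.warns(UserWarning, match="negative clearance"):
            compute_thickness(ico1, inner)
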