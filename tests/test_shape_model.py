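"""Meshing, rigid correspondence and PCA contracts, with brute-force
oracles for reference selection and landmark matching."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from kneetwin.phantom import KneePhantom, PhantomConfig, sample_landmark_population
from kneetwin.relaxometry import RigidTransform
from kneetwin.shape_model import (
    FEATURE_GRID,
    LandmarkedSurface,
    assemble_feature_table,
    build_pca,
    farthest_point_sample,
    icp_register,
    mask_to_mesh,
    match_landmarks,
    select_reference,
    synthesize_mode,
    vertex_curvatures,
)
from kneetwin.volumes import GridSpec, LabelVolume


def _sphere_volume(radius=10.0, spacing=1.0, margin=5.0):
    n = int(2 * (radius + margin) / spacing) | 1
    grid = GridSpec((n, n, n), (spacing,) * 3,
                    tuple(-(n - 1) * spacing / 2 for _ in range(3)))
    X, Y, Z = np.meshgrid(*grid.world_coords(), indexing="ij")
    data = ((X**2 + Y**2 + Z**2) <= radius**2).astype(np.int32)
    return LabelVolume(data, grid, {"s": 1})


@pytest.fixture(scope="module")
def sphere_mesh():
    return mask_to_mesh(_sphere_volume())


class TestMaskToMesh:
    def test_sphere_area_within_three_percent(self, sphere_mesh):
        assert abs(sphere_mesh.area - 4 * np.pi * 100) / (4 * np.pi * 100) < 0.03

    def test_single_voxel_closed_surface(self):
        grid = GridSpec((7, 7, 7), (1.0, 1.0, 1.0))
        data = np.zeros((7, 7, 7), dtype=np.int32)
        data[3, 3, 3] = 1
        mesh = mask_to_mesh(LabelVolume(data, grid, {}), smooth_sigma=0)
        assert mesh.is_watertight
        assert mesh.euler_number == 2

    def test_two_blobs_give_two_components(self):
        grid = GridSpec((20, 20, 20), (1.0, 1.0, 1.0))
        data = np.zeros((20, 20, 20), dtype=np.int32)
        data[2:6, 2:6, 2:6] = 1
        data[12:17, 12:17, 12:17] = 1
        mesh = mask_to_mesh(LabelVolume(data, grid, {}))
        assert len(mesh.split(only_watertight=False)) == 2

    def test_empty_mask_rejected(self):
        grid = GridSpec((8, 8, 8), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="empty"):
            mask_to_mesh(LabelVolume(np.zeros((8, 8, 8), dtype=np.int32), grid, {}))


class TestICP:
    def _cloud(self, rng, n=600):
        return rng.normal(size=(n, 3)) * np.array([10.0, 7.0, 5.0])

    def test_identity_when_clouds_equal(self, rng):
        cloud = self._cloud(rng)
        tr, _reg, rms = icp_register(cloud, cloud)
        assert rms < 1e-10
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-8)

    def test_recovers_known_transform(self, rng):
        fixed = self._cloud(rng)
        T = RigidTransform.from_axis_angle([0, 0, 1], np.deg2rad(10.0), (3, 2, 1))
        tr, reg, rms = icp_register(T.apply(fixed), fixed)
        # recovered transform is the inverse of T
        angle_err = np.arccos(
            np.clip((np.trace(tr.rotation @ T.rotation) - 1) / 2, -1, 1)
        )
        assert angle_err < 1e-3
        assert np.max(np.abs(reg - fixed)) < 1e-2

    def test_jittered_cloud_rms_bounded(self, rng):
        fixed = self._cloud(rng)
        moving = fixed + rng.normal(0, 0.1, fixed.shape)
        _tr, _reg, rms = icp_register(moving, fixed)
        assert rms <= 0.2  # within 2x the jitter SD

    def test_degenerate_cloud_rejected(self, rng):
        flat = np.column_stack([rng.normal(size=(50, 2)), np.zeros(50)])
        with pytest.raises(ValueError, match="degenerate"):
            icp_register(flat, self._cloud(rng))


class TestSelectReference:
    def test_identical_clouds_tie_break_to_first(self, rng):
        cloud = rng.normal(size=(100, 3)) * 5
        assert select_reference([cloud.copy() for _ in range(4)]) == 0

    def test_outlier_never_selected(self, rng):
        base = rng.normal(size=(200, 3)) * np.array([8.0, 6.0, 4.0])
        clouds = [base + rng.normal(0, 0.05, base.shape) for _ in range(5)]
        clouds.insert(2, base * 1.8)  # gross outlier at index 2
        assert select_reference(clouds) != 2

    def test_matches_brute_force_total_rms(self, rng):
        base = rng.normal(size=(150, 3)) * np.array([8.0, 6.0, 4.0])
        clouds = [base + rng.normal(0, s, base.shape) for s in (0.3, 0.05, 0.4)]
        chosen = select_reference(clouds)
        # brute-force: symmetric nearest-neighbour rms between all pairs
        total = np.zeros(3)
        for j in range(3):
            for l in range(3):
                if j == l:
                    continue
                d1, _ = cKDTree(clouds[l]).query(clouds[j])
                d2, _ = cKDTree(clouds[j]).query(clouds[l])
                total[j] += 0.5 * (np.sqrt(np.mean(d1**2)) + np.sqrt(np.mean(d2**2)))
        assert chosen == int(np.argmin(total))

    def test_two_clouds(self, rng):
        base = rng.normal(size=(100, 3)) * 5
        assert select_reference([base, base + rng.normal(0, 0.1, base.shape)]) == 0


class TestMatchLandmarks:
    def test_identity_maps_to_self(self, sphere_mesh):
        verts = np.asarray(sphere_mesh.vertices)
        idx = farthest_point_sample(verts, 100)
        H, K = vertex_curvatures(sphere_mesh)
        ref = LandmarkedSurface(verts[idx], "femur", "ref",
                                scalars={"mean_curvature": H[idx],
                                         "gaussian_curvature": K[idx]})
        out = match_landmarks(ref, sphere_mesh)
        assert np.array_equal(out.coords, verts[idx])

    def test_round_trip_displacement_below_edge_length(self, sphere_mesh):
        verts = np.asarray(sphere_mesh.vertices)
        idx = farthest_point_sample(verts, 100)
        H, K = vertex_curvatures(sphere_mesh)
        ref = LandmarkedSurface(verts[idx], "femur", "ref",
                                scalars={"mean_curvature": H[idx],
                                         "gaussian_curvature": K[idx]})
        T = RigidTransform.from_axis_angle([1, 1, 0], np.deg2rad(8.0), (2, -1, 1))
        moved = sphere_mesh.copy()
        moved.vertices = T.apply(verts)
        tr, _reg, _rms = icp_register(
            np.asarray(moved.vertices), verts, max_iter=50, tol=1e-8
        )
        back = moved.copy()
        back.vertices = tr.apply(np.asarray(moved.vertices))
        out = match_landmarks(ref, back)
        edge = float(np.mean(sphere_mesh.edges_unique_length))
        disp = np.linalg.norm(out.coords - ref.coords, axis=1)
        assert np.median(disp) < edge

    def test_zero_curvature_weight_is_nearest_vertex(self, sphere_mesh, rng):
        verts = np.asarray(sphere_mesh.vertices)
        pts = verts[rng.integers(0, len(verts), 50)] + rng.normal(0, 0.3, (50, 3))
        H, K = vertex_curvatures(sphere_mesh)
        ref = LandmarkedSurface(pts, "femur", "ref",
                                scalars={"mean_curvature": np.zeros(50),
                                         "gaussian_curvature": np.zeros(50)})
        out = match_landmarks(ref, sphere_mesh, weights=(1.0, 0.0, 0.0))
        _, brute = cKDTree(verts).query(pts)
        assert np.array_equal(out.scalars["vertex_index"], brute)

    def test_degenerate_triangles_rejected(self):
        import trimesh

        bad = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]],
            faces=[[0, 1, 2], [0, 1, 3]],
            process=False,
        )
        with pytest.raises(ValueError, match="degenerate triangles"):
            vertex_curvatures(bad)


class TestPCA:
    def test_rank3_population_concentrates_variance(self, rng):
        B = np.linalg.qr(rng.normal(size=(50, 3)))[0]
        X = (rng.normal(size=(40, 3)) * np.array([5, 2, 1])) @ B.T
        model = build_pca(X, n_modes=6)
        assert model.explained_variance_fractions[:3].sum() > 0.99

    def test_identical_subjects_zero_sds(self):
        X = np.tile(np.arange(12.0), (5, 1))
        model = build_pca(X, n_modes=3)
        assert model.degenerate
        assert np.all(model.mode_sds == 0)

    def test_scores_are_uncorrelated(self, rng):
        X = rng.normal(size=(60, 20))
        model = build_pca(X, n_modes=5)
        cov = np.cov(model.scores.T)
        off = cov - np.diag(np.diag(cov))
        assert np.all(np.abs(off) < 1e-8 * np.max(np.diag(cov)))

    def test_components_orthonormal(self, rng):
        model = build_pca(rng.normal(size=(30, 40)), n_modes=8)
        G = model.components @ model.components.T
        assert np.allclose(G, np.eye(8), atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(10, 6))
        model = build_pca(X, n_modes=9)  # capped to n-1 = 9 then d = 6
        recon = model.mean + model.scores @ model.components
        assert np.allclose(recon, X, atol=1e-8)

    def test_explained_variance_fractions_monotone(self, rng):
        model = build_pca(rng.normal(size=(50, 30)), n_modes=10)
        frac = model.explained_variance_fractions
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1 + 1e-12


class TestSynthesizeMode:
    def test_k_zero_returns_mean(self, rng):
        model = build_pca(rng.normal(size=(20, 30)), n_modes=4)
        assert np.array_equal(synthesize_mode(model, 0, 0.0), model.mean)

    def test_plus_minus_three_are_negatives(self, rng):
        model = build_pca(rng.normal(size=(20, 30)), n_modes=4)
        up = synthesize_mode(model, 1, 3.0) - model.mean
        dn = synthesize_mode(model, 1, -3.0) - model.mean
        assert np.allclose(up, -dn)

    def test_single_planted_mode_recovers_basis(self):
        cfg = PhantomConfig(n_subjects=80, n_deformation_modes=1,
                            deformation_sds=(20.0,), seed=3)
        phantom = KneePhantom(cfg)
        _scores, mats = sample_landmark_population(cfg)
        model = build_pca(mats["femur"], n_modes=3, tissue="femur",
                          biomarker="bone_shape")
        basis = phantom.basis["femur"][:, 0]
        comp = model.components[0]
        sign = np.sign(comp @ basis)
        assert np.allclose(sign * comp, basis, atol=1e-6)

    def test_mode_out_of_range_rejected(self, rng):
        model = build_pca(rng.normal(size=(20, 30)), n_modes=4)
        with pytest.raises(IndexError):
            synthesize_mode(model, 7, 1.0)
        with pytest.raises(ValueError, match="cap"):
            synthesize_mode(model, 0, 4.5)

    def test_displacement_proportional_to_component(self, rng):
        model = build_pca(rng.normal(size=(20, 30)), n_modes=4)
        disp = synthesize_mode(model, 2, 1.7) - model.mean
        assert np.allclose(disp, 1.7 * model.mode_sds[2] * model.components[2])


class TestFeatureTable:
    def _models(self, rng, n_sub=20, grid=FEATURE_GRID, n_modes=10):
        models = []
        for tissue, biomarker in grid:
            X = rng.normal(size=(n_sub, 60))
            models.append(build_pca(X, n_modes, tissue=tissue,
                                    biomarker=biomarker,
                                    subject_ids=list(range(n_sub))))
        return models

    def test_full_grid_yields_110_columns(self, rng):
        table = assemble_feature_table(self._models(rng))
        assert table.shape[1] == 110
        assert not table.columns.duplicated().any()

    def test_single_model_yields_its_modes(self, rng):
        table = assemble_feature_table(self._models(rng, grid=FEATURE_GRID[:1]))
        assert table.shape[1] == 10

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError, match="no shape models"):
            assemble_feature_table([])

    def test_roster_mismatch_names_subjects(self, rng):
        models = self._models(rng, grid=FEATURE_GRID[:2])
        models[1].subject_ids = list(range(1, 21))
        with pytest.raises(ValueError, match="roster mismatch"):
            assemble_feature_table(models)
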