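"""End-to-end feature extraction: synthetic population -> 110-feature table.

For each subject the driver meshes every bone and meniscus, registers it
rigidly to a reference knee (chosen by registration error), transfers the
reference landmarks by curvature-weighted matching, projects cartilage
thickness and fitted T2 onto the bone-surface landmarks, and finally fits
one PCA per tissue-biomarker pair.  With the full grid (3 bones x {shape,
thickness, T2} + 2 menisci x shape, 10 modes each) the feature table has
exactly 110 columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from . import morphometry, relaxometry, shape_model
from .phantom import _CARTILAGE, PhantomConfig, make_echo_series, make_population
from .shape_model import (
    FEATURE_GRID,
    LandmarkedSurface,
    ShapeModel,
    assemble_feature_table,
    build_pca,
    farthest_point_sample,
    icp_register,
    mask_to_mesh,
    match_landmarks,
    select_reference,
    vertex_curvatures,
)
from .volumes import LabelVolume

__all__ = ["PipelineResult", "extract_features"]

log = logging.getLogger(__name__)

BONE_TO_CARTILAGE = {bone: cart for cart, (bone, *_rest) in _CARTILAGE.items()}


@dataclass
class PipelineResult:
    features: pd.DataFrame  # subjects x feature columns
    models: dict[tuple[str, str], ShapeModel]
    reference_subject: dict[str, int]
    truths: list


def _outward_normals(mesh: trimesh.Trimesh) -> np.ndarray:
    """Vertex normals oriented away from the mesh centroid."""
    v = np.asarray(mesh.vertices)
    n = np.asarray(mesh.vertex_normals).copy()
    flip = np.einsum("ij,ij->i", n, v - v.mean(axis=0)) < 0
    n[flip] *= -1
    return n


def _subsample(points: np.ndarray, n: int) -> np.ndarray:
    if len(points) <= n:
        return points
    stride = max(1, len(points) // n)
    return points[::stride][:n]


def extract_features(
    config: PhantomConfig,
    n_modes: int = 10,
    cloud_size: int = 600,
    reference_pool: int = 20,
    curvature_weights: tuple[float, float, float] = (1.0, 0.5, 0.5),
) -> PipelineResult:
    """Run the full imaging-biomarker pipeline on a synthetic population.

    ``cloud_size`` is the per-mesh subsample used for ICP and reference
    selection; ``reference_pool`` caps how many subjects compete to be the
    reference knee (registration-error selection is quadratic in the pool).
    """
    shape_tissues = [t for t in shape_model.FEATURE_GRID if t[1] in
                     ("bone_shape", "meniscus_shape")]
    tissues = [t for (t, _b) in shape_tissues if t in config.tissues]

    pop = make_population(config, volumes=False)
    phantom_truths = [t for (_l, _e, t) in pop]

    # per-subject volumes, meshes and cartilage T2 maps (one pass)
    from .phantom import KneePhantom

    phantom = KneePhantom(config)
    meshes: dict[str, list[trimesh.Trimesh]] = {t: [] for t in tissues}
    clouds: dict[str, list[np.ndarray]] = {t: [] for t in tissues}
    labelmaps: list[LabelVolume] = []
    t2_volumes: list[dict[str, np.ndarray]] = []
    for i, truth in enumerate(phantom_truths):
        lab = phantom.labelmap(truth.scores)
        labelmaps.append(lab)
        echo = make_echo_series(lab, truth, config)
        t2s = {}
        for cart in _CARTILAGE:
            if cart not in config.tissues:
                continue
            fit = relaxometry.t2_map(echo, lab, cart)
            t2 = fit.t2.copy()
            t2[~fit.converged] = np.nan  # non-converged voxels excluded
            t2s[cart] = t2
        t2_volumes.append(t2s)
        for t in tissues:
            mesh = mask_to_mesh(lab, t)
            meshes[t].append(mesh)
            clouds[t].append(_subsample(np.asarray(mesh.vertices), cloud_size))
        if (i + 1) % 20 == 0:
            log.info("extract_features: meshed %d/%d subjects", i + 1, len(pop))

    models: dict[tuple[str, str], ShapeModel] = {}
    reference_subject: dict[str, int] = {}
    subject_ids = list(range(config.n_subjects))

    for tissue in tissues:
        pool = clouds[tissue][: max(2, reference_pool)]
        ref_idx = select_reference(pool, max_iter=3)
        reference_subject[tissue] = ref_idx
        ref_mesh = meshes[tissue][ref_idx]
        ref_verts = np.asarray(ref_mesh.vertices)
        lm_idx = farthest_point_sample(ref_verts, config.n_landmarks)
        H, K = vertex_curvatures(ref_mesh)
        reference = LandmarkedSurface(
            coords=ref_verts[lm_idx],
            tissue=tissue,
            subject_id=ref_idx,
            scalars={"mean_curvature": H[lm_idx], "gaussian_curvature": K[lm_idx]},
        )
        is_bone = tissue in BONE_TO_CARTILAGE
        cart = BONE_TO_CARTILAGE.get(tissue)
        if cart is not None and cart not in config.tissues:
            is_bone, cart = False, None

        shape_rows, thick_rows, t2_rows = [], [], []
        valid_mask_ref: np.ndarray | None = None
        for i in range(config.n_subjects):
            tr, _reg, _rms = icp_register(
                clouds[tissue][i], clouds[tissue][ref_idx], max_iter=30, tol=1e-5
            )
            moved = meshes[tissue][i].copy()
            moved.vertices = tr.apply(np.asarray(moved.vertices))
            matched = match_landmarks(reference, moved, weights=curvature_weights)
            shape_rows.append(matched.coords.ravel())
            if not is_bone:
                continue
            # project cartilage scalars at the matched vertices, in subject space
            vidx = matched.scalars["vertex_index"]
            sub_mesh = meshes[tissue][i]
            pts = np.asarray(sub_mesh.vertices)[vidx]
            normals = _outward_normals(sub_mesh)[vidx]
            probe = trimesh.Trimesh(
                vertices=pts, faces=np.zeros((0, 3), dtype=int), process=False
            )
            cart_lab = LabelVolume(
                (labelmaps[i].mask(cart)).astype(np.int32),
                labelmaps[i].grid,
                {cart: 1},
            )
            thick = morphometry.project_to_bone_surface(
                probe, cart_lab, vertex_normals=normals
            )
            t2f = morphometry.project_to_bone_surface(
                probe, cart_lab, scalar_volume=t2_volumes[i][cart],
                layer="total", mode="scalar", vertex_normals=normals,
            )
            if valid_mask_ref is None:
                valid_mask_ref = thick.valid.copy()
            tvals = np.where(thick.valid, thick.values, 0.0)  # no cartilage -> 0 mm
            t2vals = t2f.values.copy()
            fill = np.nanmean(t2vals[t2f.valid]) if t2f.valid.any() else 0.0
            t2vals[~t2f.valid] = fill
            thick_rows.append(tvals)
            t2_rows.append(t2vals)

        models[(tissue, "meniscus_shape" if not is_bone else "bone_shape")] = build_pca(
            np.asarray(shape_rows), n_modes,
            tissue=tissue,
            biomarker="meniscus_shape" if not is_bone else "bone_shape",
            subject_ids=subject_ids,
        )
        if is_bone:
            # restrict scalar fields to landmarks covered by cartilage on the
            # reference subject so the field is defined population-wide
            cov = valid_mask_ref if valid_mask_ref is not None else slice(None)
            models[(tissue, "cartilage_thickness")] = build_pca(
                np.asarray(thick_rows)[:, cov], n_modes,
                tissue=tissue, biomarker="cartilage_thickness",
                subject_ids=subject_ids,
            )
            models[(tissue, "cartilage_t2")] = build_pca(
                np.asarray(t2_rows)[:, cov], n_modes,
                tissue=tissue, biomarker="cartilage_t2",
                subject_ids=subject_ids,
            )
        log.info("extract_features: finished tissue %s", tissue)

    features = assemble_feature_table(models.values())
    return PipelineResult(
        features=features,
        models=models,
        reference_subject=reference_subject,
        truths=phantom_truths,
    )
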