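"""Cartilage thickness morphometry and bone-surface projection.

Thickness: the cartilage mask is reduced to its morphological skeleton and
the Euclidean distance transform (anisotropic spacing respected) is read at
skeleton voxels; full thickness is twice the distance to the boundary.

Projection: for each bone-surface vertex a ray is cast along the outward
normal; the in-cartilage chord gives projected thickness, and scalar
volumes (e.g. a T2 map) are averaged over the chord — the proximal half is
the deep layer, the distal half the superficial layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage.morphology import skeletonize

from .volumes import LabelVolume

__all__ = ["ThicknessMap", "SurfaceScalarField", "thickness_map", "project_to_bone_surface"]


@dataclass
class ThicknessMap:
    """Thickness (mm) sampled at medial-skeleton voxels of a cartilage mask."""

    skeleton_voxels: np.ndarray  # (N, 3) integer indices
    thickness: np.ndarray  # (N,) mm
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if np.any(self.thickness <= 0):
            raise ValueError("thickness must be positive at every skeleton voxel")


@dataclass
class SurfaceScalarField:
    """Per-vertex scalar values on a bone surface mesh."""

    values: np.ndarray  # (V,), NaN where invalid
    valid: np.ndarray  # (V,) bool
    layer: str  # {"superficial", "deep", "total"}

    def __post_init__(self) -> None:
        if self.layer not in ("superficial", "deep", "total"):
            raise ValueError(f"unknown layer tag {self.layer!r}")


def thickness_map(
    cartilage_mask: LabelVolume, tissue=None, refine: int = 4
) -> ThicknessMap:
    """Skeleton-based thickness of a cartilage mask.

    At each voxel of the morphological skeleton, thickness = 2 x Euclidean
    distance to the mask boundary (mm, anisotropic spacing respected).  The
    factor 2 makes the value the full local thickness: the skeleton runs
    along the mid-surface, halfway between the two faces of the shell.

    The distance transform is evaluated against the 0.5 level of the
    trilinearly interpolated mask, resampled ``refine``-times finer.  That
    level set tracks the underlying boundary without orientation bias — a
    plain coarse EDT instead reads distances to background voxel *centres*
    (up to half a voxel too far on axis-aligned boundaries), while a
    nearest-neighbour refinement measures to the voxel-cube staircase (up
    to half a cube diagonal too near on oblique ones).
    """
    mask = cartilage_mask.mask(tissue) if tissue is not None else cartilage_mask.data > 0
    if not mask.any():
        raise ValueError("cartilage mask is empty")
    spacing = np.asarray(cartilage_mask.grid.spacing, dtype=float)
    fine_axes = [
        (np.arange(n * refine) + 0.5) / refine - 0.5 for n in mask.shape
    ]
    fine_coords = np.stack(np.meshgrid(*fine_axes, indexing="ij"))
    fine = (
        ndimage.map_coordinates(
            mask.astype(np.float32), fine_coords, order=1, mode="nearest"
        )
        >= 0.5
    )
    edt_fine = ndimage.distance_transform_edt(fine, sampling=spacing / refine)
    # discrete skeleton voxels sit up to ~half a voxel off the true medial
    # ridge, biasing 2xEDT low; the EDT never exceeds the true half
    # thickness, so reading its local maximum within 3/4 voxel recovers the
    # ridge value without overshooting on constant-thickness bodies
    half_width = int(np.ceil(0.75 * refine))
    edt_fine = ndimage.maximum_filter(edt_fine, size=2 * half_width + 1)
    skel = skeletonize(mask)
    if not skel.any():
        # single-voxel-thin masks can skeletonize to nothing; use the mask core
        edt = ndimage.distance_transform_edt(mask, sampling=spacing)
        skel = mask & (edt >= edt[mask].max())
    vox = np.argwhere(skel)
    # coarse voxel centre in fine-index coordinates
    coords = (vox * refine + (refine - 1) / 2.0).T
    dist = ndimage.map_coordinates(edt_fine, coords, order=1)
    thick = 2.0 * dist
    if thick.max() < min(spacing):
        raise ValueError("mask is thinner than one voxel everywhere")
    keep = thick > 0
    return ThicknessMap(
        skeleton_voxels=vox[keep],
        thickness=thick[keep],
        spacing=cartilage_mask.grid.spacing,
    )


def project_to_bone_surface(
    bone_mesh: trimesh.Trimesh,
    cartilage_mask: LabelVolume,
    scalar_volume: np.ndarray | None = None,
    layer: str = "total",
    mode: str = "thickness",
    step_fraction: float = 0.25,
    max_distance_mm: float = 15.0,
    vertex_normals: np.ndarray | None = None,
) -> SurfaceScalarField:
    """Project cartilage thickness or a scalar map onto the bone surface.

    For each vertex, march along the outward normal in steps of
    ``step_fraction`` x the smallest voxel dimension; the chord between the
    first and last in-cartilage samples defines the perpendicular cartilage
    cross-section.  ``mode='thickness'`` records the chord length;
    ``mode='scalar'`` averages ``scalar_volume`` over the chord samples of
    the requested layer (deep = proximal half, superficial = distal half).
    Vertices whose ray never enters cartilage are invalid.
    """
    if mode not in ("thickness", "scalar"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "scalar" and scalar_volume is None:
        raise ValueError("scalar_volume is required in scalar mode")
    grid = cartilage_mask.grid
    mask = cartilage_mask.data > 0
    verts = np.asarray(bone_mesh.vertices, dtype=float)
    normals = (
        np.asarray(vertex_normals, dtype=float)
        if vertex_normals is not None
        else np.asarray(bone_mesh.vertex_normals, dtype=float)
    )
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.maximum(norms, 1e-12)

    step = step_fraction * min(grid.spacing)
    n_steps = int(np.ceil(max_distance_mm / step))
    ts = (np.arange(n_steps) + 0.5) * step  # sample at step midpoints
    # (V, S, 3) sample points; nearest-voxel lookup
    pts = verts[:, None, :] + normals[:, None, :] * ts[None, :, None]
    idx = np.round(grid.world_to_index(pts.reshape(-1, 3))).astype(int)
    shape = np.asarray(grid.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    hit = np.zeros(len(idx), dtype=bool)
    ii = idx[inside]
    hit[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    hit = hit.reshape(len(verts), n_steps)

    any_hit = hit.any(axis=1)
    first = np.argmax(hit, axis=1)
    last = n_steps - 1 - np.argmax(hit[:, ::-1], axis=1)
    values = np.full(len(verts), np.nan)
    if mode == "thickness":
        # chord endpoints at the outer edges of the first/last hit samples
        values[any_hit] = (last[any_hit] - first[any_hit] + 1) * step
    else:
        svol = np.asarray(scalar_volume, dtype=float)
        flat = np.full(len(idx), np.nan)
        flat[inside] = svol[ii[:, 0], ii[:, 1], ii[:, 2]]
        samples = flat.reshape(len(verts), n_steps)
        for v in np.nonzero(any_hit)[0]:
            lo, hi = first[v], last[v] + 1
            vals = samples[v, lo:hi][hit[v, lo:hi]]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                any_hit[v] = False
                continue
            mid = vals.size // 2 + vals.size % 2  # deep = proximal half (ties to deep)
            if layer == "deep":
                values[v] = vals[:mid].mean()
            elif layer == "superficial":
                values[v] = vals[mid:].mean() if vals.size > mid else vals.mean()
            else:
                values[v] = vals.mean()
    valid = any_hit & np.isfinite(values)
    values[~valid] = np.nan
    return SurfaceScalarField(values=values, valid=valid, layer=layer)
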