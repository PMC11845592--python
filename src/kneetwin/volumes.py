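"""Core volumetric containers and NIfTI-1 I/O.

All volumes live on axis-aligned grids: world coordinate of voxel index
``(i, j, k)`` is ``origin + index * spacing`` (mm).  NIfTI affines are
diagonal by construction; oblique acquisitions are handled upstream by
:func:`kneetwin.relaxometry.rigid_resample`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["GridSpec", "LabelVolume", "EchoSeries"]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned sampling grid: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world coordinates (N, 3) to fractional voxel indices."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class LabelVolume:
    """3D integer label grid with voxel spacing — a segmentation mask."""

    data: np.ndarray
    grid: GridSpec
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-dimensional")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must hold integers")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError("data shape does not match grid shape")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    def mask(self, tissue: str | int) -> np.ndarray:
        """Boolean mask for one tissue (by name or label value)."""
        value = self.labels[tissue] if isinstance(tissue, str) else int(tissue)
        return self.data == value

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.grid.affine)
        img.header.set_zooms(self.grid.spacing)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, labels: dict[str, int] | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.int32)
        grid = _grid_from_affine(data.shape, img.affine)
        return cls(data=data, grid=grid, labels=labels or {})


@dataclass
class EchoSeries:
    """Multi-echo signal stack: one 3D volume per echo time.

    ``signals`` has shape (n_echoes, nx, ny, nz); ``echo_times`` are ms,
    strictly increasing, at least three of them (the three-parameter
    mono-exponential fit needs >= 3 samples).
    """

    signals: np.ndarray
    echo_times: np.ndarray
    grid: GridSpec
    valid: np.ndarray | None = None  # False where resampling left no data

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.signals.ndim != 4:
            raise ValueError("signals must be (echo, x, y, z)")
        if self.signals.shape[0] != self.echo_times.size:
            raise ValueError(
                f"{self.signals.shape[0]} echo volumes but "
                f"{self.echo_times.size} echo times"
            )
        if self.echo_times.size < 3:
            raise ValueError("need at least 3 echoes for a 3-parameter fit")
        if np.any(np.diff(self.echo_times) <= 0) or np.any(self.echo_times <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if tuple(self.signals.shape[1:]) != tuple(self.grid.shape):
            raise ValueError("echo volumes do not match grid shape")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.size)

    def save(self, prefix) -> list[str]:
        """Write one NIfTI per echo: ``{prefix}_e{k:02d}.nii.gz``."""
        paths = []
        for k in range(self.n_echoes):
            img = nib.Nifti1Image(self.signals[k].astype(np.float32), self.grid.affine)
            img.header.set_zooms(self.grid.spacing)
            p = f"{prefix}_e{k:02d}.nii.gz"
            nib.save(img, p)
            paths.append(p)
        return paths

    @classmethod
    def load(cls, paths, echo_times) -> "EchoSeries":
        vols, grid = [], None
        for p in paths:
            img = nib.load(str(p))
            vols.append(np.asanyarray(img.dataobj).astype(float))
            g = _grid_from_affine(vols[-1].shape, img.affine)
            if grid is None:
                grid = g
            elif g != grid:
                raise ValueError(f"echo volume {p} is on a different grid")
        return cls(signals=np.stack(vols), echo_times=np.asarray(echo_times), grid=grid)


def _grid_from_affine(shape, affine) -> GridSpec:
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return GridSpec(shape=tuple(int(s) for s in shape), spacing=spacing, origin=origin)
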