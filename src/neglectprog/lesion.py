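"""Binary lesion volumes and voxel-level bookkeeping.

All cohort volumes live on a common grid in a shared standard space
(the study convention is MNI at 1x1x1 mm; the synthetic cohorts use a
small toy grid).  Computation happens in 0-based, row-major voxel index
space; the affine is carried only for I/O and display.  Values are
strictly binary — near-binary data (within 1e-6 of 0/1, e.g. from
resampling) are snapped, anything else is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "LesionVolume",
    "VoxelIndexSet",
    "GridMismatchError",
    "NonBinaryVolumeError",
    "read_lesion",
    "write_lesion",
    "restrict_to_mask",
    "lesion_volume_ml",
    "roi_overlap",
    "voxel_frequency_filter",
    "vectorize",
    "devectorize",
]

_BINARY_TOL = 1e-6


class GridMismatchError(ValueError):
    """Volumes do not share grid shape / voxel size / space."""


class NonBinaryVolumeError(ValueError):
    """Volume data are not within tolerance of {0, 1}."""


def _snap_binary(data: np.ndarray) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    near0 = np.abs(arr) <= _BINARY_TOL
    near1 = np.abs(arr - 1.0) <= _BINARY_TOL
    if not np.all(near0 | near1):
        bad = arr[~(near0 | near1)]
        raise NonBinaryVolumeError(
            f"volume contains {bad.size} non-binary values "
            f"(e.g. {bad.flat[0]:.6g}); expected values in {{0, 1}} within {_BINARY_TOL:g}"
        )
    return near1.astype(np.uint8)


@dataclass(frozen=True)
class LesionVolume:
    """A binary 3D volume on a shared grid.

    ``grid`` is uint8 in {0, 1}; ``affine`` maps voxel indices to mm
    coordinates; ``space_tag`` identifies the common space so that
    volumes from different spaces are never silently combined.
    """

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_tag: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", _snap_binary(self.grid))
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.grid.ndim}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(float(s) for s in nib.affines.voxel_sizes(self.affine))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def n_voxels(self) -> int:
        """Number of lesioned (value 1) voxels."""
        return int(self.grid.sum())

    @property
    def volume_ml(self) -> float:
        return lesion_volume_ml(self)

    def same_grid_as(self, other: "LesionVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine)
            and self.space_tag == other.space_tag
        )

    def _require_same_grid(self, other: "LesionVolume", what: str) -> None:
        if not self.same_grid_as(other):
            raise GridMismatchError(
                f"{what}: grids differ "
                f"(shape {self.shape} vs {other.shape}, space "
                f"{self.space_tag!r} vs {other.space_tag!r})"
            )


def read_lesion(path: str | Path, space_tag: str = "MNI") -> LesionVolume:
    """Load a binary lesion/ROI/mask volume from NIfTI."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    return LesionVolume(grid=data, affine=img.affine, space_tag=space_tag)


def write_lesion(volume: LesionVolume, path: str | Path) -> Path:
    """Write a lesion volume as NIfTI (uint8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.grid.astype(np.uint8), volume.affine)
    nib.save(img, str(path))
    return path


def restrict_to_mask(lesion: LesionVolume, mask: LesionVolume) -> LesionVolume:
    """Voxelwise AND of a lesion with a tissue mask (e.g. cerebrum-only)."""
    lesion._require_same_grid(mask, "restrict_to_mask")
    return LesionVolume(
        grid=lesion.grid & mask.grid, affine=lesion.affine, space_tag=lesion.space_tag
    )


def lesion_volume_ml(lesion: LesionVolume) -> float:
    """Lesioned volume in millilitres: voxel count x voxel volume (mm^3) / 1000."""
    return lesion.n_voxels * lesion.voxel_volume_mm3 / 1000.0


def roi_overlap(lesion: LesionVolume, roi: LesionVolume) -> tuple[LesionVolume, float]:
    """Portion of the lesion inside the ROI, and its size in ml.

    The returned map is the ROI-based lesion overlap; its ml size is the
    "ROI lesion size" predictor.
    """
    overlap = restrict_to_mask(lesion, roi)
    return overlap, overlap.volume_ml


@dataclass(frozen=True)
class VoxelIndexSet:
    """Ordered linear (row-major, C-order) voxel indices retained after filtering."""

    indices: np.ndarray
    grid_shape: tuple[int, int, int]
    variant: Literal["whole_brain", "roi_overlap"] = "whole_brain"
    min_patients: int = 5

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("indices must be 1D")
        if idx.size and (idx.min() < 0 or idx.max() >= int(np.prod(self.grid_shape))):
            raise ValueError("indices out of grid bounds")
        if np.unique(idx).size != idx.size:
            raise ValueError("indices must be unique")
        object.__setattr__(self, "indices", np.sort(idx))
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "grid_shape": list(self.grid_shape),
            "ordering": "row-major (C order) linear indices, 0-based, sorted ascending",
            "variant": self.variant,
            "min_patients": self.min_patients,
            "n_voxels": len(self),
            "indices": self.indices.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "VoxelIndexSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            indices=np.asarray(payload["indices"], dtype=np.int64),
            grid_shape=tuple(payload["grid_shape"]),
            variant=payload["variant"],
            min_patients=payload["min_patients"],
        )


def _common_grid(volumes: Sequence[LesionVolume], what: str) -> None:
    if not volumes:
        raise ValueError(f"{what}: empty cohort")
    first = volumes[0]
    for v in volumes[1:]:
        first._require_same_grid(v, what)


def voxel_frequency_filter(
    volumes: Sequence[LesionVolume],
    min_patients: int = 5,
    variant: Literal["whole_brain", "roi_overlap"] = "whole_brain",
) -> VoxelIndexSet:
    """Retain voxels damaged in at least ``min_patients`` patients.

    Rarely affected voxels carry too little statistical power, so voxels
    damaged in fewer than ``min_patients`` (default 5) patients are
    excluded before PCA.  Computed once on the whole cohort — as the
    study protocol does — which leaks cohort-level voxel frequencies
    across CV folds; see the methods note.
    """
    _common_grid(volumes, "voxel_frequency_filter")
    if len(volumes) < min_patients:
        raise ValueError(
            f"need at least min_patients={min_patients} volumes, got {len(volumes)}"
        )
    counts = np.zeros(volumes[0].shape, dtype=np.int32)
    for v in volumes:
        counts += v.grid
    keep = np.flatnonzero(counts.ravel(order="C") >= min_patients)
    return VoxelIndexSet(
        indices=keep,
        grid_shape=volumes[0].shape,
        variant=variant,
        min_patients=min_patients,
    )


def vectorize(volumes: Sequence[LesionVolume], index_set: VoxelIndexSet) -> np.ndarray:
    """Stack volumes into a patients x retained-voxels binary matrix."""
    _common_grid(volumes, "vectorize")
    if volumes[0].shape != index_set.grid_shape:
        raise GridMismatchError(
            f"vectorize: index set grid {index_set.grid_shape} "
            f"!= volume grid {volumes[0].shape}"
        )
    if len(index_set) == 0:
        raise ValueError("vectorize: empty voxel index set")
    flat = np.stack([v.grid.ravel(order="C") for v in volumes])
    return flat[:, index_set.indices].astype(np.uint8)


def devectorize(
    row: np.ndarray,
    index_set: VoxelIndexSet,
    template: LesionVolume,
) -> LesionVolume:
    """Scatter one feature row back onto the grid (non-retained voxels = 0)."""
    if template.shape != index_set.grid_shape:
        raise GridMismatchError("devectorize: template grid != index set grid")
    flat = np.zeros(int(np.prod(index_set.grid_shape)), dtype=float)
    flat[index_set.indices] = np.asarray(row, dtype=float)
    grid = flat.reshape(index_set.grid_shape, order="C")
    return LesionVolume(grid=grid, affine=template.affine, space_tag=template.space_tag)
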