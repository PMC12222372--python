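"""Volume-of-interest TAC extraction from 4D PET and 3D label masks.

Segmentation masks (e.g. from an automatic CT segmentation tool) are cleaned
by keeping only their largest 26-connected component, optionally resampled
from the CT grid onto the PET grid by nearest-neighbour voxel-centre
mapping, and reduced to per-frame mean activities.  For the portal vein —
a thin vessel whose mean is depressed by partial-volume and respiratory
motion — a percentile TAC is provided: per frame, the mean of the voxels at
or above the 90th percentile of the in-mask values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .curves import FrameSchedule, FrameTAC

__all__ = [
    "EmptyVoiError",
    "DegenerateVoiWarning",
    "ImageGeometry",
    "VoiMask",
    "largest_connected_component",
    "resample_mask",
    "mean_tac",
    "percentile_tac",
]


class EmptyVoiError(ValueError):
    """Raised when an operation meets an empty mask."""


class DegenerateVoiWarning(UserWarning):
    """Emitted when a mask is too small for a meaningful percentile TAC."""


@dataclass(frozen=True, eq=False)
class ImageGeometry:
    """Voxel grid shape, physical voxel size (mm) and voxel-to-world affine."""

    shape: tuple
    voxel_size: tuple
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        affine = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "affine", affine)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError("geometry needs a positive 3-D shape")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @classmethod
    def axis_aligned(cls, shape, voxel_size, origin=(0.0, 0.0, 0.0)) -> "ImageGeometry":
        affine = np.diag([*voxel_size, 1.0])
        affine[:3, 3] = origin
        return cls(tuple(shape), tuple(voxel_size), affine)

    @classmethod
    def from_nifti(cls, img) -> "ImageGeometry":
        shape = img.shape[:3]
        zooms = img.header.get_zooms()[:3]
        return cls(tuple(shape), tuple(zooms), np.asarray(img.affine, dtype=float))


@dataclass(eq=False)
class VoiMask:
    """Binary 3-D mask with its grid geometry and anatomical label."""

    data: np.ndarray
    geometry: ImageGeometry
    label: str

    def __post_init__(self) -> None:
        data = np.asarray(self.data).astype(bool)
        self.data = data
        if data.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match geometry {self.geometry.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


#: Full 26-neighbourhood connectivity structure.
_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def largest_connected_component(mask: VoiMask) -> VoiMask:
    """Keep only the largest 26-connected component of the mask.

    Ties are broken towards the component containing the lowest flat voxel
    index (the first one met in scan order).
    """
    if mask.n_voxels == 0:
        raise EmptyVoiError(f"mask '{mask.label}' is empty")
    labelled, n = ndimage.label(mask.data, structure=_STRUCTURE_26)
    if n == 1:
        return VoiMask(mask.data.copy(), mask.geometry, mask.label)
    counts = np.bincount(labelled.ravel())[1:]
    # ndimage assigns labels in scan order, so argmax of the counts picks the
    # earliest (lowest-index) component among equally sized ones.
    winner = int(np.argmax(counts)) + 1
    return VoiMask(labelled == winner, mask.geometry, mask.label)


def resample_mask(mask: VoiMask, target: ImageGeometry) -> VoiMask:
    """Nearest-neighbour resampling of a mask onto another grid.

    A target voxel is inside the resampled mask iff its centre, mapped
    through the two affines, lands in a source mask voxel.  Both geometries
    must be expressed in the same world frame.
    """
    if mask.geometry.shape == target.shape and np.allclose(
        mask.geometry.affine, target.affine
    ):
        return VoiMask(mask.data.copy(), target, mask.label)
    idx = np.indices(target.shape).reshape(3, -1)
    ones = np.ones((1, idx.shape[1]))
    world = target.affine @ np.vstack([idx, ones])
    src = np.linalg.inv(mask.geometry.affine) @ world
    src_idx = np.round(src[:3]).astype(int)
    inside = np.all(
        (src_idx >= 0) & (src_idx < np.array(mask.geometry.shape)[:, None]), axis=0
    )
    out = np.zeros(target.shape, dtype=bool)
    sel = inside.nonzero()[0]
    if sel.size:
        vals = mask.data[src_idx[0, sel], src_idx[1, sel], src_idx[2, sel]]
        out.reshape(-1)[sel] = vals
    if not out.any():
        warnings.warn(
            f"mask '{mask.label}' does not overlap the target field of view",
            stacklevel=2,
        )
    return VoiMask(out, target, mask.label)


def _check_pet(pet4d: np.ndarray, mask: VoiMask, schedule: FrameSchedule) -> np.ndarray:
    pet4d = np.asarray(pet4d, dtype=float)
    if pet4d.ndim != 4:
        raise ValueError("dynamic PET must be a 4-D array (x, y, z, frame)")
    if pet4d.shape[:3] != mask.geometry.shape:
        raise ValueError("PET grid does not match the mask geometry")
    if pet4d.shape[3] != schedule.n_frames:
        raise ValueError(
            f"PET has {pet4d.shape[3]} frames but the schedule has {schedule.n_frames}"
        )
    return pet4d


def mean_tac(pet4d: np.ndarray, mask: VoiMask, schedule: FrameSchedule) -> FrameTAC:
    """Per-frame arithmetic mean of the in-mask voxel values."""
    pet4d = _check_pet(pet4d, mask, schedule)
    if mask.n_voxels == 0:
        raise EmptyVoiError(f"mask '{mask.label}' is empty")
    values = pet4d[mask.data].mean(axis=0)
    return FrameTAC(schedule, values, label=mask.label, allow_negative=True)


def percentile_tac(
    pet4d: np.ndarray, mask: VoiMask, schedule: FrameSchedule, q: float = 90.0
) -> FrameTAC:
    """Mean of the hottest in-mask voxels, per frame.

    For each frame the q-th percentile of the in-mask values is computed
    (linear interpolation between order statistics) and the returned value
    is the mean of the voxels at or above that threshold, so the selected
    voxel set may change between frames.  With q = 0 this reduces exactly to
    :func:`mean_tac`.  Masks with fewer than 10 voxels cannot support a top
    decile; they fall back to the per-frame maximum with a warning.
    """
    pet4d = _check_pet(pet4d, mask, schedule)
    if mask.n_voxels == 0:
        raise EmptyVoiError(f"mask '{mask.label}' is empty")
    if not 0.0 <= q <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    voxels = pet4d[mask.data]  # (n_voxels, n_frames)
    if voxels.shape[0] < 10 and q > 0:
        warnings.warn(
            f"mask '{mask.label}' has only {voxels.shape[0]} voxels; "
            "using the per-frame maximum instead of a percentile",
            DegenerateVoiWarning,
            stacklevel=2,
        )
        values = voxels.max(axis=0)
    else:
        thresholds = np.percentile(voxels, q, axis=0)
        values = np.array(
            [col[col >= thr].mean() for col, thr in zip(voxels.T, thresholds)]
        )
    return FrameTAC(schedule, values, label=mask.label, allow_negative=True)
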