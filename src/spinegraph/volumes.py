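"""Volumetric image / label-map containers and NIfTI I/O.

Internal array convention is ``(slice, height, width)`` with 0-based
indexing; the slice axis is the low-resolution acquisition axis and defaults
to axis 0.  Files follow ``<subject>_img.nii.gz`` / ``<subject>_seg.nii.gz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "LabelMap3D",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "extract_slices",
    "stack_slices",
]

DEFAULT_AXIS_ROLES = {"slice": 0, "height": 1, "width": 2}


def as_array(x) -> np.ndarray:
    """Unwrap a Volume3D/LabelMap3D (or pass an array through)."""
    if isinstance(x, (Volume3D, LabelMap3D)):
        return x.data
    return np.asarray(x)


class VolumeIOError(IOError):
    pass


@dataclass
class Volume3D:
    """Real-valued 3D grid plus voxel spacing (mm) and axis-role metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_roles: dict = field(default_factory=lambda: dict(DEFAULT_AXIS_ROLES))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError(f"Volume3D requires a 3D grid, got {self.data.ndim}D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap3D:
    """Integer label grid; values in {0..C} referring to a label schema."""

    data: np.ndarray
    schema_ref: str = "T9-S1"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError(f"LabelMap3D requires a 3D grid, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.rint(self.data).astype(np.int16)

    @property
    def shape(self):
        return self.data.shape


def _load_nifti(path) -> tuple[np.ndarray, tuple]:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt / non-NIfTI input
        raise VolumeIOError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path) -> Volume3D:
    data, spacing = _load_nifti(path)
    return Volume3D(data=data, spacing=spacing)


def write_volume(volume: Volume3D, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_labelmap(path, schema_ref: str = "T9-S1") -> LabelMap3D:
    data, spacing = _load_nifti(path)
    data = np.rint(data).astype(np.int16)
    return LabelMap3D(data=data, schema_ref=schema_ref, spacing=spacing)


def write_labelmap(labelmap: LabelMap3D, path) -> None:
    affine = np.diag(list(labelmap.spacing) + [1.0])
    data = np.rint(labelmap.data).astype(np.int16)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def extract_slices(volume, axis: int = 0) -> list[np.ndarray]:
    """Split a volume into ordered 2D slices along ``axis``."""
    data = as_array(volume)
    return [np.take(data, i, axis=axis) for i in range(data.shape[axis])]


def stack_slices(slices, axis: int = 0) -> np.ndarray:
    """Inverse of :func:`extract_slices`; exact round trip."""
    if len(slices) == 0:
        raise ValueError("cannot stack an empty slice list")
    return np.stack(slices, axis=axis)
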