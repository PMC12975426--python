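"""Preprocessing for the two-stage pipeline.

Spine-centered cropping, zero-padding to a uniform grid, intensity
normalization, downsampling for the coarse 3D stage, slice preparation for
the 2D refinement stage, and rotation/intensity augmentation.

Two normalization modes are provided because the acquisition protocol can
be summarized either way: ``zscore`` (subtract mean, divide by SD) and
``mean_ratio`` ((x - mean) / mean).  Statistics are computed over the whole
padded grid by default for determinism; ``mask_aware`` restricts them to
nonzero voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .volumes import LabelMap3D, Volume3D, as_array

__all__ = [
    "PreprocessConfig",
    "locate_spine_bbox",
    "central_bbox",
    "crop_and_pad",
    "normalize_intensity",
    "resize_volume",
    "resize_labelmap",
    "resize_probmap",
    "prepare_refine_slices",
    "augment_sample",
]


@dataclass
class PreprocessConfig:
    """Shapes and augmentation ranges for preprocessing.

    Defaults match clinical-scale acquisition (pad to 182x256x128, coarse
    grid 18x256x128, refinement slices 512x256); :meth:`phantom_scale`
    returns the desk-scale configuration used with the synthetic phantoms.
    """

    pad_shape: tuple = (182, 256, 128)
    coarse_shape: tuple = (18, 256, 128)
    slice_shape: tuple = (512, 256)
    slice_axis: int = 0
    normalization_mode: str = "zscore"  # or "mean_ratio"
    mask_aware: bool = False
    margin: int = 2
    rotation_limit: float = 15.0  # degrees, in-plane rotation
    brightness_limit: float = 0.05  # additive, fraction of intensity range
    contrast_limit: float = 0.10  # multiplicative scale

    def __post_init__(self):
        if any(s < 1 for s in self.pad_shape + self.coarse_shape + self.slice_shape):
            raise ValueError("all shapes must be positive")
        if self.rotation_limit < 0:
            raise ValueError("rotation_limit must be >= 0")

    @classmethod
    def phantom_scale(cls, **overrides) -> "PreprocessConfig":
        """Desk-scale configuration matched to the 48x96x48 phantom grid.

        The coarse grid (16,96,48) downsamples only the slice axis, the same
        axis the clinical-scale configuration reduces (182 -> 18 slices).
        """
        base = dict(pad_shape=(48, 96, 48), coarse_shape=(16, 96, 48),
                    slice_shape=(96, 48))
        base.update(overrides)
        return cls(**base)


def _as_array(x) -> np.ndarray:
    return as_array(x)


def locate_spine_bbox(labelmap, margin: int = 0) -> tuple[tuple[int, int], ...]:
    """Bounding box (inclusive-exclusive per axis) of all foreground voxels.

    Returns ``((lo0, hi0), (lo1, hi1), (lo2, hi2))`` covering the foreground
    plus ``margin`` voxels, clipped to the grid.
    """
    data = _as_array(labelmap)
    fg = np.argwhere(data > 0)
    if fg.size == 0:
        raise ValueError("labelmap has no foreground voxels; cannot locate spine")
    lo = np.maximum(fg.min(axis=0) - margin, 0)
    hi = np.minimum(fg.max(axis=0) + 1 + margin, data.shape)
    return tuple((int(a), int(b)) for a, b in zip(lo, hi))


def central_bbox(shape, pad_shape) -> tuple[tuple[int, int], ...]:
    """Centered box of ``pad_shape`` clipped to ``shape`` (inference mode)."""
    box = []
    for n, target in zip(shape, pad_shape):
        size = min(n, target)
        lo = (n - size) // 2
        box.append((lo, lo + size))
    return tuple(box)


def crop_and_pad(volume, box, pad_shape):
    """Crop ``box`` out of the grid and center it in a zero grid of ``pad_shape``.

    Content larger than ``pad_shape`` along an axis is center-cropped to fit
    (with a warning).  Returns the same container type it was given.
    """
    if any(s < 1 for s in pad_shape):
        raise ValueError("pad_shape must be >= 1 in all axes")
    data = _as_array(volume)
    crop = data[tuple(slice(lo, hi) for lo, hi in box)]
    if any(c > p for c, p in zip(crop.shape, pad_shape)):
        warnings.warn(
            f"cropped content {crop.shape} exceeds pad_shape {tuple(pad_shape)}; "
            "center-cropping to fit", stacklevel=2)
        sl = []
        for c, p in zip(crop.shape, pad_shape):
            lo = max((c - p) // 2, 0)
            sl.append(slice(lo, lo + min(c, p)))
        crop = crop[tuple(sl)]
    out = np.zeros(tuple(pad_shape), dtype=data.dtype)
    offs = [(p - c) // 2 for c, p in zip(crop.shape, pad_shape)]
    out[tuple(slice(o, o + c) for o, c in zip(offs, crop.shape))] = crop
    return _rewrap(volume, out)


def _rewrap(template, data):
    if isinstance(template, Volume3D):
        return Volume3D(data=data, spacing=template.spacing,
                        axis_roles=dict(template.axis_roles))
    if isinstance(template, LabelMap3D):
        return LabelMap3D(data=data, schema_ref=template.schema_ref,
                          spacing=template.spacing)
    return data


def normalize_intensity(volume, mode: str = "zscore", mask_aware: bool = False):
    """Normalize intensities; degenerate inputs yield zeros with a warning."""
    data = np.asarray(_as_array(volume), dtype=np.float64)
    sel = data[data != 0] if mask_aware and np.any(data != 0) else data
    mu = sel.mean()
    if mode == "zscore":
        sd = sel.std()
        if sd < 1e-8:
            warnings.warn("constant volume: z-score undefined, returning zeros",
                          stacklevel=2)
            return _rewrap(volume, np.zeros_like(data))
        out = (data - mu) / sd
    elif mode == "mean_ratio":
        if abs(mu) < 1e-8:
            warnings.warn("zero-mean volume: mean-ratio undefined, returning zeros",
                          stacklevel=2)
            return _rewrap(volume, np.zeros_like(data))
        out = (data - mu) / mu
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return _rewrap(volume, out)


def resize_volume(volume, shape, interp: str = "linear"):
    """Resize to ``shape``; images linear, label maps nearest."""
    if any(s < 1 for s in shape):
        raise ValueError(f"invalid target shape {shape}")
    data = _as_array(volume)
    if tuple(data.shape) == tuple(shape):
        return _rewrap(volume, data.copy())
    order = {"linear": 1, "nearest": 0}[interp]
    out = _sk_resize(data.astype(np.float64), shape, order=order,
                     anti_aliasing=False, preserve_range=True, mode="edge")
    if interp == "nearest":
        out = np.rint(out).astype(data.dtype)
    return _rewrap(volume, out)


def resize_labelmap(labelmap, shape):
    return resize_volume(labelmap, shape, interp="nearest")


def resize_probmap(probs: np.ndarray, shape) -> np.ndarray:
    """Resize a (C+1, D, H, W) probability field and renormalize per voxel."""
    probs = np.asarray(probs, dtype=np.float64)
    out = np.stack([
        _sk_resize(probs[c], shape, order=1, anti_aliasing=False,
                   preserve_range=True, mode="edge")
        for c in range(probs.shape[0])
    ])
    out = np.clip(out, 0.0, None)
    total = out.sum(axis=0, keepdims=True)
    total[total < 1e-12] = 1.0
    return out / total


def prepare_refine_slices(volume_highres, coarse_probmap, slice_axis: int = 0):
    """Pair each high-resolution image slice with its probability slice stack.

    ``coarse_probmap`` must already be resized to the high-resolution grid.
    Returns a list of ``(image_slice, prob_slices)`` with ``prob_slices`` of
    shape (C+1, H, W), one pair per position along the slice axis.
    """
    img = _as_array(volume_highres)
    probs = np.asarray(coarse_probmap)
    if probs.ndim != 4:
        raise ValueError(f"probability map must be 4D (C, D, H, W), got {probs.ndim}D")
    if probs.shape[1:] != img.shape:
        raise ValueError(
            f"probability grid {probs.shape[1:]} does not match image grid {img.shape}")
    pairs = []
    for i in range(img.shape[slice_axis]):
        pairs.append((np.take(img, i, axis=slice_axis),
                      np.take(probs, i, axis=slice_axis + 1)))
    return pairs


def augment_sample(volume, labelmap, rng: np.random.Generator,
                   config: PreprocessConfig | None = None):
    """Random in-plane rotation plus brightness/contrast jitter.

    The rotation angle is uniform in [-rotation_limit, +rotation_limit]
    about the slice axis; the label map is rotated with nearest
    interpolation, intensity jitter touches the image only.  Deterministic
    for a fixed generator state.
    """
    cfg = config or PreprocessConfig()
    img = np.asarray(_as_array(volume), dtype=np.float64)
    lab = _as_array(labelmap)
    angle = float(rng.uniform(-cfg.rotation_limit, cfg.rotation_limit))
    contrast = float(rng.uniform(1.0 - cfg.contrast_limit, 1.0 + cfg.contrast_limit))
    brightness = float(rng.uniform(-cfg.brightness_limit, cfg.brightness_limit))
    plane = tuple(ax for ax in range(3) if ax != cfg.slice_axis)
    if angle != 0.0:
        img = ndimage.rotate(img, angle, axes=plane, reshape=False, order=1,
                             mode="constant", cval=0.0)
        lab = ndimage.rotate(lab, angle, axes=plane, reshape=False, order=0,
                             mode="constant", cval=0)
    span = img.max() - img.min()
    img = img * contrast + brightness * span
    return _rewrap(volume, img), _rewrap(labelmap, lab.astype(_as_array(labelmap).dtype))
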