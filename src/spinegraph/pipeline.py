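"""Two-stage inference: coarse 3D probabilities -> slice-wise 2D refinement.

Stage 1 preprocesses a volume (crop, pad, normalize, downsample to the
coarse grid) and runs the 3D network to obtain per-structure probability
maps with global anatomical context.  Stage 2 upsamples those maps to the
refinement grid, fuses each high-resolution image slice with its
probability slices, refines every slice with the 2D network, restacks, and
takes the per-voxel argmax (ties break toward the lowest class index).

An :class:`IdentityRefiner` passes the coarse probabilities through
unchanged, which makes the two-stage output exactly the upsampled coarse
argmax -- a useful consistency baseline.
"""

from __future__ import annotations

import numpy as np

from .networks import Checkpoint, CoarseNet, RefineNet
from .preprocess import (PreprocessConfig, central_bbox, crop_and_pad,
                         locate_spine_bbox, normalize_intensity, resize_labelmap,
                         resize_probmap, resize_volume)
from .volumes import LabelMap3D, Volume3D, as_array, stack_slices

__all__ = [
    "IdentityRefiner",
    "preprocess_volume",
    "preprocess_pair",
    "infer_coarse",
    "run_two_stage",
]


class IdentityRefiner:
    """Refiner that returns the coarse probability slices unchanged."""

    def refine_slices(self, image_slices, prob_slices):
        return [np.asarray(p) for p in prob_slices]


def _as_net(model, kind):
    if isinstance(model, Checkpoint):
        return model.build_net()
    if isinstance(model, (CoarseNet, RefineNet)) or hasattr(model, "refine_slices"):
        return model
    raise TypeError(f"cannot interpret {type(model).__name__} as a {kind} model")


def preprocess_volume(volume, config: PreprocessConfig, labelmap=None,
                      to_coarse: bool = True):
    """Crop/pad/normalize a volume; optionally downsample to the coarse grid.

    With a label map the crop box is the spine bounding box (training mode);
    otherwise a centered box of ``pad_shape`` (inference mode).
    """
    data = as_array(volume)
    if labelmap is not None:
        box = locate_spine_bbox(labelmap, margin=config.margin)
    else:
        box = central_bbox(data.shape, config.pad_shape)
    vol = crop_and_pad(data, box, config.pad_shape)
    vol = normalize_intensity(vol, mode=config.normalization_mode,
                              mask_aware=config.mask_aware)
    if to_coarse:
        vol = resize_volume(vol, config.coarse_shape, interp="linear")
    return np.asarray(vol), box


def preprocess_pair(volume, labelmap, config: PreprocessConfig,
                    to_coarse: bool = True):
    """Preprocess an (image, labels) pair onto a common grid."""
    vol, box = preprocess_volume(volume, config, labelmap=labelmap,
                                 to_coarse=to_coarse)
    lab = as_array(labelmap)
    lab = crop_and_pad(lab, box, config.pad_shape)
    if to_coarse:
        lab = resize_labelmap(lab, config.coarse_shape)
    return vol, np.asarray(lab)


def infer_coarse(volume, coarse_model, config: PreprocessConfig) -> np.ndarray:
    """Coarse per-voxel class probabilities (C+1, *coarse_shape).

    Deterministic for a fixed checkpoint; probabilities sum to 1 per voxel.
    """
    net = _as_net(coarse_model, "coarse")
    vol, _ = preprocess_volume(volume, config, to_coarse=True)
    return net.predict_proba(vol)


def largest_component_cleanup(labels: np.ndarray) -> np.ndarray:
    """Keep only the largest 26-connected component of each foreground class."""
    from scipy import ndimage as ndi
    out = labels.copy()
    structure = np.ones((3, 3, 3), dtype=bool)
    for cls in np.unique(labels):
        if cls == 0:
            continue
        comp, n = ndi.label(labels == cls, structure=structure)
        if n > 1:
            sizes = np.bincount(comp.ravel())[1:]
            keep = 1 + int(np.argmax(sizes))
            out[(labels == cls) & (comp != keep)] = 0
    return out


def run_two_stage(volume, coarse_model, refine_model,
                  config: PreprocessConfig, cleanup: bool = False) -> LabelMap3D:
    """Full cascade: coarse 3D -> upsample -> fuse -> 2D refine -> argmax.

    The output grid is the refinement grid: ``pad_shape`` slices resized
    in-plane to ``slice_shape``.  ``cleanup`` optionally keeps only the
    largest connected component per class (off by default).
    """
    refiner = _as_net(refine_model, "refine")
    try:
        coarse_probs = infer_coarse(volume, coarse_model, config)
    except Exception as exc:
        raise RuntimeError(f"coarse stage failed: {exc}") from exc

    try:
        highres, _ = preprocess_volume(volume, config, to_coarse=False)
        refine_grid = (config.pad_shape[config.slice_axis],) + tuple(config.slice_shape)
        if tuple(highres.shape) != refine_grid:
            # in-plane resize of every slice to slice_shape
            order = [config.slice_axis] + [a for a in range(3)
                                           if a != config.slice_axis]
            # operate in (slice, h, w) layout, then restore
            moved = np.transpose(highres, order)
            moved = resize_volume(moved, refine_grid, interp="linear")
            highres = moved  # pipeline output stays in slice-first layout
        probs_up = resize_probmap(coarse_probs, highres.shape)
        img_slices = [highres[i] for i in range(highres.shape[0])]
        prob_slices = [probs_up[:, i] for i in range(highres.shape[0])]
    except Exception as exc:
        raise RuntimeError(f"fusion stage failed: {exc}") from exc

    try:
        refined = refiner.refine_slices(img_slices, prob_slices)
        prob_volume = np.stack(refined, axis=1)  # (C+1, D, H, W)
    except Exception as exc:
        raise RuntimeError(f"refinement stage failed: {exc}") from exc

    labels = np.argmax(prob_volume, axis=0).astype(np.int16)
    if cleanup:
        labels = largest_component_cleanup(labels)
    return LabelMap3D(data=labels)
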