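"""Synthetic spine phantoms: T2-like volumes with 19-class label maps.

Each phantom is a cranio-caudal chain of elliptic slabs -- alternating
vertebral bodies and intervertebral discs -- whose centers follow a smooth
curvature curve.  The generator reproduces the statistical structure the
segmentation method assumes:

* distinct intensity classes (discs brighter than vertebral bodies, as in
  T2-weighted MR),
* inter-subject size and curvature variability,
* additive Gaussian noise and a smooth multiplicative bias field,
* frequently missing cranial structures (the T9--T11 levels truncate from
  the top with a configurable probability, so the per-label voxel-count
  distribution across a cohort is long-tailed),
* disc degeneration as thinning plus an intensity drop.

Default grid is 48x96x48 voxels (axis 1 is the longitudinal axis) so the
whole pipeline trains on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .anatomy import DEFAULT_LEVELS, build_schema
from .volumes import LabelMap3D, Volume3D, write_labelmap, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort"]


@dataclass
class PhantomSpec:
    """Geometry, intensity and variability parameters of the phantom cohort."""

    shape: tuple = (48, 96, 48)
    levels: tuple = DEFAULT_LEVELS
    longitudinal_axis: int = 1
    vertebra_height: tuple = (5, 6)  # voxels, sampled per structure
    disc_height: tuple = (2, 3)
    body_width: tuple = (9, 13)  # half-axis along axis 0
    body_depth: tuple = (9, 13)  # half-axis along axis 2
    curvature_amplitude: tuple = (1.0, 4.0)  # voxels
    curvature_wavelength: tuple = (70.0, 130.0)
    vertebra_intensity: float = 0.45
    disc_intensity: float = 0.80
    background_intensity: float = 0.10
    intensity_jitter: float = 0.04  # per-structure fractional jitter of the mean
    noise_sd: float = 0.03
    bias_amplitude: float = 0.2
    p_missing_cranial: float = 0.3  # chance each next top level is truncated
    n_missing_max: int = 3
    p_disc_thinning: float = 0.2
    disc_thinning_factor: float = 0.5
    top_margin: int = 3

    def __post_init__(self):
        if self.vertebra_height[0] < 1 or self.disc_height[0] < 1:
            raise ValueError("structure heights must be >= 1 voxel")
        if not (0.0 <= self.p_missing_cranial <= 1.0):
            raise ValueError("p_missing_cranial must be in [0, 1]")
        means = (self.vertebra_intensity, self.disc_intensity,
                 self.background_intensity)
        if len({round(m, 6) for m in means}) != 3:
            raise ValueError("vertebra/disc/background intensities must be distinct")


def _n_missing(rng: np.random.Generator, spec: PhantomSpec) -> int:
    """Number of top levels truncated: nested, so T9 is the rarest label."""
    k = 0
    while k < spec.n_missing_max and rng.random() < spec.p_missing_cranial:
        k += 1
    return k


def _smooth_bias(shape, amplitude, rng):
    coarse = rng.standard_normal((3, 3, 3))
    fieldv = ndimage.zoom(coarse, [s / 3 for s in shape], order=3)
    fieldv = fieldv[tuple(slice(0, s) for s in shape)]
    peak = np.abs(fieldv).max()
    if peak > 0:
        fieldv = fieldv / peak
    return 1.0 + amplitude * fieldv


def generate_phantom(spec: PhantomSpec | None = None, seed=0):
    """Generate one (Volume3D, LabelMap3D) phantom pair.

    Deterministic for a fixed ``seed``.  Raises ``ValueError`` naming the
    minimum grid height when the chain cannot fit along the longitudinal
    axis.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    schema = build_schema(spec.levels)
    ax = spec.longitudinal_axis
    length = spec.shape[ax]

    # subject-level geometry
    amp = rng.uniform(*spec.curvature_amplitude)
    wavelength = rng.uniform(*spec.curvature_wavelength)
    phase = rng.uniform(0, 2 * np.pi)
    width = rng.uniform(*spec.body_width)
    depth = rng.uniform(*spec.body_depth)

    # per-structure heights and intensities (drawn for the full chain so the
    # stream of random numbers is independent of which levels are truncated)
    heights, means, thinned = [], [], []
    for lab in schema:
        if lab.kind == "vertebra":
            h = int(rng.integers(spec.vertebra_height[0], spec.vertebra_height[1] + 1))
            mu = spec.vertebra_intensity
            thin = False
        else:
            h = int(rng.integers(spec.disc_height[0], spec.disc_height[1] + 1))
            mu = spec.disc_intensity
            thin = rng.random() < spec.p_disc_thinning
            if thin:
                h = max(1, int(round(h * spec.disc_thinning_factor)))
                mu *= 0.75  # degenerated discs lose T2 signal
        mu *= 1.0 + rng.uniform(-spec.intensity_jitter, spec.intensity_jitter)
        heights.append(h)
        means.append(mu)
        thinned.append(thin)

    k_missing = _n_missing(rng, spec)
    # drop the top k vertebrae and the k discs directly below them
    drop = set()
    vert_positions = [i for i, lab in enumerate(schema) if lab.kind == "vertebra"]
    for j in range(k_missing):
        drop.add(vert_positions[j])  # vertebra at chain index 2j
        drop.add(vert_positions[j] + 1)  # the disc just caudal to it
    present = [i for i in range(len(schema)) if i not in drop]

    needed = spec.top_margin * 2 + sum(heights[i] for i in present)
    if needed > length:
        raise ValueError(
            f"grid too small for the requested chain: longitudinal axis has "
            f"{length} voxels but at least {needed} are required")

    other_axes = tuple(a for a in range(3) if a != ax)
    n0, n2 = spec.shape[other_axes[0]], spec.shape[other_axes[1]]
    g0 = np.arange(n0)[:, None]
    g2 = np.arange(n2)[None, :]

    label = np.zeros(spec.shape, dtype=np.int16)
    vol = np.full(spec.shape, spec.background_intensity, dtype=np.float64)

    cursor = spec.top_margin
    for i in present:
        lab = schema[i]
        h = heights[i]
        rx = width * (1.06 if lab.kind == "disc" else 1.0)
        rz = depth * (1.06 if lab.kind == "disc" else 1.0)
        for y in range(cursor, cursor + h):
            c0 = n0 / 2.0 + amp * np.sin(2 * np.pi * y / wavelength + phase)
            c2 = n2 / 2.0 + 0.3 * amp * np.cos(2 * np.pi * y / wavelength + phase)
            mask = ((g0 - c0) / rx) ** 2 + ((g2 - c2) / rz) ** 2 <= 1.0
            idx = [slice(None)] * 3
            idx[ax] = y
            plane_lab = label[tuple(idx)]
            plane_vol = vol[tuple(idx)]
            plane_lab[mask] = lab.id
            plane_vol[mask] = means[i]
        cursor += h

    vol *= _smooth_bias(spec.shape, spec.bias_amplitude, rng)
    vol += rng.normal(0.0, spec.noise_sd, size=spec.shape)

    volume = Volume3D(data=vol.astype(np.float32), spacing=(1.0, 1.0, 1.0))
    labelmap = LabelMap3D(data=label, schema_ref="-".join(
        (spec.levels[0], spec.levels[-1])))
    return volume, labelmap


def generate_cohort(n: int, spec: PhantomSpec | None = None, seed=0,
                    out_dir=None) -> pd.DataFrame:
    """Generate ``n`` phantoms; optionally write NIfTI pairs + manifest CSV.

    The manifest has one row per subject with the present labels and
    per-label voxel counts; with ``p_missing_cranial > 0`` the cranial
    labels are systematically rarer across the cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or PhantomSpec()
    schema = build_schema(spec.levels)
    children = np.random.SeedSequence(seed).spawn(n)
    rows = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, child in enumerate(children):
        sub = f"sub-{i:03d}"
        volume, labelmap = generate_phantom(spec, seed=child)
        counts = np.bincount(labelmap.data.ravel(), minlength=len(schema) + 1)
        row = {"subject": sub,
               "present_labels": ";".join(str(l.id) for l in schema
                                          if counts[l.id] > 0)}
        for lab in schema:
            row[f"n_{lab.name.replace('/', '_')}"] = int(counts[lab.id])
        rows.append(row)
        if out_dir is not None:
            write_volume(volume, out_dir / f"{sub}_img.nii.gz")
            write_labelmap(labelmap, out_dir / f"{sub}_seg.nii.gz")
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
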