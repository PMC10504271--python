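"""Synthetic chest-CT phantoms with crescent pneumothorax lesions.

Pneumothorax presents on axial CT as a rim of near-air attenuation between
the partially collapsed lung and the chest wall.  The phantom emulates the
attenuation structure that matters for segmentation: an elliptical soft-
tissue body (~ +40 HU) on an air background (−1000 HU), two low-attenuation
lung fields (~ −800 HU), and — with configurable probability — one crescent-
shaped region at near-air attenuation (~ −950 HU) hugging the outer lung
margin, obtained as the set difference between the lung ellipse and a
shrunken, medially shifted inner ellipse.  Additive Gaussian HU noise
models quantum mottle.

Each sample is a pure function of ``(seed, index)``, so datasets are
reproducible and order-independent.  No attempt is made at anatomical
realism (ribs, mediastinum, 3-D continuity): the phantoms exist so the
preprocessing / training / evaluation pipeline is exercisable end to end
without patient data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import (CTImage, SegmentationMask, write_mask_png,
                      write_nifti_volume)

HU_AIR = -1000.0


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Study-condition parameters of the phantom population.

    ``lesion_area_range`` is the target lesion area as a fraction of the
    affected lung's area; ``noise_sd`` is in HU.
    """

    n_samples: int = 60
    side: int = 512
    lesion_probability: float = 0.75
    lesion_area_range: tuple[float, float] = (0.08, 0.35)
    hu_body: float = 40.0
    hu_lung: float = -800.0
    hu_pneumo: float = -950.0
    noise_sd: float = 20.0
    slices_per_patient: int = 4
    seed: int = 0

    def __post_init__(self):
        if not (self.hu_pneumo < self.hu_lung < self.hu_body):
            raise ValueError("HU ordering must be pneumothorax < lung < body")
        if not 0.0 <= self.lesion_probability <= 1.0:
            raise ValueError("lesion_probability must be in [0, 1]")
        lo, hi = self.lesion_area_range
        if not (0.0 < lo <= hi < 0.9):
            raise ValueError(f"infeasible lesion_area_range {self.lesion_area_range}")
        if self.side < 16:
            raise ValueError("side must be >= 16")


def _ellipse(side: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _crescent(side: int, lung: np.ndarray, cy: float, cx: float,
              ry: float, rx: float, lateral_sign: float,
              target_frac: float) -> np.ndarray:
    """Lung minus a shrunken, medially shifted inner ellipse.

    The medial shift is found by bisection so the crescent area lands on
    ``target_frac`` of the lung area (pixel-counted).
    """
    lung_area = lung.sum()

    def crescent_at(shift: float) -> np.ndarray:
        scale = 1.0 - 0.3 * shift / rx  # inner lung shrinks as it displaces
        inner = _ellipse(side, cy, cx - lateral_sign * shift,
                         ry * scale, rx * scale)
        return lung & ~inner

    lo, hi = 0.0, 1.2 * rx
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if crescent_at(mid).sum() / lung_area < target_frac:
            lo = mid
        else:
            hi = mid
    return crescent_at(0.5 * (lo + hi))


def generate_sample(spec: PhantomSpec, index: int) -> tuple[CTImage, SegmentationMask]:
    """Deterministically synthesise phantom ``index`` under ``spec``."""
    rng = np.random.default_rng([spec.seed, int(index)])
    s = spec.side
    img = np.full((s, s), HU_AIR)

    # body ellipse, slightly jittered
    body_ry = s * rng.uniform(0.33, 0.38)
    body_rx = s * rng.uniform(0.40, 0.45)
    cy, cx = s * 0.5 + s * rng.uniform(-0.02, 0.02), s * 0.5
    img[_ellipse(s, cy, cx, body_ry, body_rx)] = spec.hu_body

    mask = np.zeros((s, s), dtype=np.uint8)
    lesion_side = None
    if rng.uniform() < spec.lesion_probability:
        lesion_side = rng.integers(0, 2)  # 0 = left lung, 1 = right lung

    for side_idx, sign in ((0, -1.0), (1, 1.0)):
        lry = s * rng.uniform(0.20, 0.26)
        lrx = s * rng.uniform(0.12, 0.16)
        lcy = cy + s * rng.uniform(-0.02, 0.02)
        lcx = cx + sign * s * rng.uniform(0.20, 0.24)
        lung = _ellipse(s, lcy, lcx, lry, lrx)
        img[lung] = spec.hu_lung
        if lesion_side is not None and side_idx == lesion_side:
            frac = rng.uniform(*spec.lesion_area_range)
            crescent = _crescent(s, lung, lcy, lcx, lry, lrx, sign, frac)
            img[crescent] = spec.hu_pneumo
            mask |= crescent.astype(np.uint8)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    patient = f"P{int(index) // spec.slices_per_patient:04d}"
    ct = CTImage(pixels=img, patient_id=patient,
                 slice_index=int(index) % spec.slices_per_patient,
                 pixel_spacing=(0.7, 0.7))
    return ct, SegmentationMask(mask)


def generate_arrays(spec: PhantomSpec) -> tuple[list[CTImage], list[SegmentationMask]]:
    """All samples of the spec, in index order, kept in memory."""
    pairs = [generate_sample(spec, i) for i in range(spec.n_samples)]
    return [p[0] for p in pairs], [p[1] for p in pairs]


def generate_dataset(spec: PhantomSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write the phantom cohort to disk (NIfTI images, PNG masks).

    Returns (and writes as ``manifest.csv``) a manifest with one row per
    sample: file paths, patient-style grouping id, slice index and a
    has-lesion flag for stratified bookkeeping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(spec.n_samples):
        ct, mask = generate_sample(spec, i)
        img_path = out / f"sample_{i:04d}.nii.gz"
        mask_path = out / f"sample_{i:04d}_mask.png"
        write_nifti_volume(img_path, [ct.pixels])
        write_mask_png(mask_path, mask)
        rows.append({
            "sample": i,
            "patient_id": ct.patient_id,
            "slice_index": ct.slice_index,
            "image": img_path.name,
            "mask": mask_path.name,
            "has_lesion": bool(mask.pixels.any()),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
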