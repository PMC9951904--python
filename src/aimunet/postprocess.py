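"""Post-processing: probability-map thresholding and volume assembly.

Thresholding follows the asymmetric rule: a pixel strictly greater than the
threshold (default 0.5) is foreground; a pixel less than **or equal to** the
threshold is background (ties go to background).  Per-slice masks from one
patient stack into a (n_slices, height, width) binary volume exportable as
NIfTI; tumor masks can optionally be clipped to the predicted liver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .imaging_io import BinaryMask, write_nifti


class AssemblyError(ValueError):
    """Slices being stacked do not form one consistent patient volume."""


@dataclass
class ProbabilityMap:
    """Pre-threshold network output for one slice, with provenance."""

    pixels: np.ndarray
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"probability map must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("probability map values must lie in [0, 1]")


@dataclass
class PredictedMask:
    """A thresholded mask that remembers which slice it came from."""

    mask: BinaryMask
    patient_id: str
    slice_index: int


def binarize(prob: ProbabilityMap, threshold: float = 0.5,
             label_kind: str = "liver") -> PredictedMask:
    """pixel > threshold -> 1; pixel <= threshold -> 0."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    mask = BinaryMask(pixels=(prob.pixels > threshold).astype(np.uint8),
                      label_kind=label_kind)
    return PredictedMask(mask=mask, patient_id=prob.patient_id,
                         slice_index=prob.slice_index)


def clip_tumor_to_liver(tumor: BinaryMask, liver: BinaryMask) -> BinaryMask:
    """Optionally constrain predicted tumor voxels to the predicted liver."""
    if tumor.pixels.shape != liver.pixels.shape:
        raise AssemblyError("tumor and liver masks must share dimensions")
    return BinaryMask(pixels=tumor.pixels & liver.pixels, label_kind="tumor")


def stack_volume(masks: Sequence[PredictedMask]) -> np.ndarray:
    """Ordered per-slice masks -> (n_slices, height, width) binary volume."""
    if not masks:
        raise AssemblyError("cannot stack an empty list of masks")
    patients = {m.patient_id for m in masks}
    if len(patients) > 1:
        raise AssemblyError(f"masks from multiple patients: {sorted(patients)}")
    shape = masks[0].mask.pixels.shape
    for m in masks:
        if m.mask.pixels.shape != shape:
            raise AssemblyError("all masks must share dimensions")
    idx = [m.slice_index for m in masks]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise AssemblyError("slice_index must be strictly increasing")
    return np.stack([m.mask.pixels for m in masks], axis=0)


def export_volume(path, masks: Sequence[PredictedMask]) -> np.ndarray:
    """Stack and write as NIfTI; returns the stacked array."""
    volume = stack_volume(masks)
    write_nifti(path, volume.astype(np.uint8))
    return volume
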