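"""Slice preprocessing: HU windowing, histogram equalization, resizing,
unit normalization, six-view augmentation and patient-level splitting.

The fixed pipeline order is window -> equalize -> resize -> normalize; the
composed pipeline maps any raw slice into [0, 1] at the network input size.
Augmentation multiplies a training set exactly sevenfold (originals plus the
six views) and is applied to training pairs only, never validation/test.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple, Union

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import resize as sk_resize
from skimage.transform import rotate as sk_rotate

from ._rand import keyed_rng
from .config import AugmentationPolicy, SplitSpec
from .imaging_io import BinaryMask, CTSlice

DEFAULT_WINDOW = (-100.0, 200.0)
NETWORK_SIDE = 256


def window_hounsfield(ct: CTSlice, lo: float = DEFAULT_WINDOW[0],
                      hi: float = DEFAULT_WINDOW[1]) -> CTSlice:
    """Clamp HU values to [lo, hi] (default soft-tissue window [-100, 200])."""
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got ({lo}, {hi})")
    if ct.intensity_state != "raw_hu":
        raise ValueError(f"windowing expects raw HU input, got {ct.intensity_state!r}")
    return CTSlice(pixels=np.clip(ct.pixels, lo, hi), patient_id=ct.patient_id,
                   slice_index=ct.slice_index, intensity_state="windowed")


def equalize_histogram(ct: CTSlice, n_bins: int = 256) -> CTSlice:
    """Global histogram equalization over a fixed binning of the windowed range.

    Each pixel maps to the normalized cumulative histogram of its bin, so the
    mapping is monotone non-decreasing in intensity (rank order is preserved)
    and the output lies in (0, 1].  A constant slice maps to a constant.
    """
    if ct.intensity_state != "windowed":
        raise ValueError(f"equalization expects a windowed slice, got {ct.intensity_state!r}")
    px = ct.pixels
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.ones_like(px)
    else:
        idx = np.minimum(((px - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
        hist = np.bincount(idx.ravel(), minlength=n_bins)
        cdf = np.cumsum(hist) / px.size
        out = cdf[idx]
    return CTSlice(pixels=out, patient_id=ct.patient_id, slice_index=ct.slice_index,
                   intensity_state="equalized")


def resize_to_network(item: Union[CTSlice, BinaryMask], side: int = NETWORK_SIDE):
    """Resize to side x side: bilinear for images, nearest-neighbour for masks."""
    if side < 16:
        raise ValueError(f"side must be >= 16, got {side}")
    if isinstance(item, BinaryMask):
        if item.pixels.shape == (side, side):
            return item
        out = sk_resize(item.pixels, (side, side), order=0, preserve_range=True,
                        anti_aliasing=False)
        return BinaryMask(pixels=out.astype(np.uint8), label_kind=item.label_kind)
    if item.pixels.shape == (side, side):
        return item
    out = sk_resize(item.pixels, (side, side), order=1, preserve_range=True,
                    anti_aliasing=False)
    return CTSlice(pixels=out, patient_id=item.patient_id, slice_index=item.slice_index,
                   intensity_state=item.intensity_state)


def normalize_unit(ct: CTSlice) -> CTSlice:
    """Affine map of [min, max] to [0, 1]; constant slices map to all zeros."""
    if ct.intensity_state != "equalized":
        raise ValueError(f"normalization expects an equalized slice, got {ct.intensity_state!r}")
    px = ct.pixels
    lo, hi = px.min(), px.max()
    out = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    return CTSlice(pixels=out, patient_id=ct.patient_id, slice_index=ct.slice_index,
                   intensity_state="normalized")


def preprocess_slice(ct: CTSlice, window: Tuple[float, float] = DEFAULT_WINDOW,
                     side: int = NETWORK_SIDE) -> CTSlice:
    """The full fixed pipeline: window -> equalize -> resize -> normalize."""
    out = window_hounsfield(ct, *window)
    out = equalize_histogram(out)
    out = resize_to_network(out, side)
    return normalize_unit(out)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _grid_distortion_coords(shape: Tuple[int, int], cells: int, magnitude: float,
                            rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Albumentations-style grid distortion: cell sizes are stretched or
    compressed per axis by factors in [1-magnitude, 1+magnitude]."""
    coords = []
    for size in shape:
        nodes = np.linspace(0, size - 1, cells + 1)
        steps = rng.uniform(1 - magnitude, 1 + magnitude, cells)
        warped = np.concatenate([[0.0], np.cumsum(steps * np.diff(nodes))])
        warped *= (size - 1) / warped[-1]
        axis = np.interp(np.arange(size), warped, nodes)
        coords.append(axis)
    ry, rx = np.meshgrid(coords[0], coords[1], indexing="ij")
    return ry, rx


def _warp(pixels: np.ndarray, ry: np.ndarray, rx: np.ndarray, order: int) -> np.ndarray:
    return map_coordinates(pixels.astype(np.float64), [ry, rx], order=order,
                           mode="constant", cval=0.0)


def _apply_geometric(image: np.ndarray, mask: np.ndarray, name: str,
                     policy: AugmentationPolicy,
                     rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    if name == "center_crop":
        h, w = image.shape
        ch, cw = max(1, round(h * policy.crop_fraction)), max(1, round(w * policy.crop_fraction))
        y0, x0 = (h - ch) // 2, (w - cw) // 2
        ci, cm = image[y0:y0 + ch, x0:x0 + cw], mask[y0:y0 + ch, x0:x0 + cw]
        ri = sk_resize(ci, (h, w), order=1, preserve_range=True, anti_aliasing=False)
        rm = sk_resize(cm, (h, w), order=0, preserve_range=True, anti_aliasing=False)
        return ri, rm.astype(np.uint8)
    if name in ("rotate_cw", "rotate_ccw"):
        deg = -policy.rotate_degrees if name == "rotate_cw" else policy.rotate_degrees
        ri = sk_rotate(image, deg, order=1, preserve_range=True, mode="constant", cval=0.0)
        rm = sk_rotate(mask.astype(float), deg, order=0, preserve_range=True,
                       mode="constant", cval=0.0)
        return ri, rm.astype(np.uint8)
    if name == "grid_distortion":
        ry, rx = _grid_distortion_coords(image.shape, policy.grid_cells,
                                         policy.grid_magnitude, rng)
        return _warp(image, ry, rx, 1), _warp(mask, ry, rx, 0).astype(np.uint8)
    if name == "vertical_flip":
        return np.flipud(image).copy(), np.flipud(mask).copy()
    raise ValueError(f"unknown geometric transform {name!r}")


def augment_pair(ct: CTSlice, mask: BinaryMask,
                 policy: AugmentationPolicy) -> List[Tuple[CTSlice, BinaryMask]]:
    """Produce the six extra views of a slice/mask pair.

    Geometric transforms (crop, both rotations, grid distortion, vertical
    flip) apply identically to image and mask; the photometric transform
    (random brightness/contrast) alters the image only and returns the mask
    bit-identical.  Deterministic in (policy.seed, patient_id, slice_index).
    """
    policy.validate()
    if ct.pixels.shape != mask.pixels.shape:
        raise ValueError("image and mask dimensions must match")
    rng = keyed_rng(policy.seed, "augment", ct.patient_id, ct.slice_index)
    out: List[Tuple[CTSlice, BinaryMask]] = []
    for name in policy.transforms:
        if name == "random_brightness_contrast":
            b = rng.uniform(-policy.brightness_delta, policy.brightness_delta)
            c = rng.uniform(-policy.contrast_delta, policy.contrast_delta)
            scale = ct.pixels.max() - ct.pixels.min() or 1.0
            img = ct.pixels * (1.0 + c) + b * scale
            if ct.intensity_state == "normalized":
                img = np.clip(img, 0.0, 1.0)
            new_mask = BinaryMask(pixels=mask.pixels.copy(), label_kind=mask.label_kind)
        else:
            img, m = _apply_geometric(ct.pixels, mask.pixels, name, policy, rng)
            if ct.intensity_state == "normalized":
                img = np.clip(img, 0.0, 1.0)
            new_mask = BinaryMask(pixels=m, label_kind=mask.label_kind)
        out.append((CTSlice(pixels=img, patient_id=ct.patient_id,
                            slice_index=ct.slice_index,
                            intensity_state=ct.intensity_state), new_mask))
    return out


def augment_dataset(pairs: Sequence[Tuple[CTSlice, BinaryMask]],
                    policy: AugmentationPolicy) -> List[Tuple[CTSlice, BinaryMask]]:
    """Originals plus six views each: exactly 7x the input cardinality."""
    out = list(pairs)
    for ct, mask in pairs:
        out.extend(augment_pair(ct, mask, policy))
    return out


# ---------------------------------------------------------------------------
# Patient-level splitting
# ---------------------------------------------------------------------------

def split_patients(patient_ids: Sequence[str],
                   spec: SplitSpec) -> Dict[str, Set[str]]:
    """Partition whole patients into train/val/test.

    Test takes ``round(test_fraction * n)`` patients (at least one); of the
    remainder, ``val_fraction`` go to validation (at least one) and the rest
    to training.  Deterministic under ``spec.seed``; the three sets are
    disjoint and exhaustive.
    """
    spec.validate()
    ids = list(dict.fromkeys(patient_ids))
    n = len(ids)
    if n < 3:
        raise ValueError(f"need >= 3 patients to populate train/val/test, got {n}")
    rng = keyed_rng(spec.seed, "split")
    order = list(rng.permutation(ids))
    n_test = max(1, round(spec.test_fraction * n))
    remaining = n - n_test
    n_val = max(1, round(spec.val_fraction * remaining))
    if remaining - n_val < 1:
        raise ValueError(f"too few patients ({n}) to populate a training set")
    return {
        "test": set(order[:n_test]),
        "val": set(order[n_test:n_test + n_val]),
        "train": set(order[n_test + n_val:]),
    }
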