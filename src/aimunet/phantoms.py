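"""Synthetic abdominal-CT phantoms with known liver and tumor masks.

Every other stage of the pipeline is testable against these phantoms without
external data.  A slice shows one bright, roughly elliptical liver (default
60 +/- 10 HU) against a darker cluttered background, optionally containing
hypodense tumor blobs, plus additive Gaussian noise.  Randomness is
counter-based: the stream is keyed by (seed, patient_id, slice_index), so any
slice is reproducible in isolation and generation order never matters.

Geometry model: the liver boundary is an ellipse whose radius is perturbed by
a low-frequency harmonic series r(theta) = 1 + sum_k eps_k cos(k theta + phi_k)
with the total perturbation bounded (|sum eps_k| <= 0.06), keeping the region
connected and its area within analytic bounds of pi*a*b.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np

from ._rand import keyed_rng
from .config import ConfigurationError, PhantomConfig
from .imaging_io import BinaryMask, CTSlice, CTVolume, write_mask_png, write_image

# bound on the total radial perturbation of the liver boundary; area then lies
# in [pi*a*b*(1-RADIAL_PERTURBATION)^2, pi*a*b*(1+RADIAL_PERTURBATION)^2]
RADIAL_PERTURBATION = 0.06


@dataclass
class PhantomSlice:
    image: CTSlice
    liver_mask: BinaryMask
    tumor_mask: BinaryMask
    patient_id: str
    slice_index: int


def _patient_geometry(config: PhantomConfig, patient_id: str) -> dict:
    """Per-patient liver geometry, shared by all slices of a volume."""
    rng = keyed_rng(config.seed, "patient", patient_id)
    lo, hi = config.liver_axes_range
    h, w = config.height, config.width
    n_harmonics = 4
    eps = rng.uniform(0, 1, n_harmonics)
    eps *= RADIAL_PERTURBATION / max(eps.sum(), 1e-9)
    return {
        "center": (h * rng.uniform(0.38, 0.62), w * rng.uniform(0.38, 0.62)),
        "axes": (rng.uniform(lo, hi), rng.uniform(lo, hi)),
        "angle": rng.uniform(0, np.pi),
        "eps": eps,
        "phase": rng.uniform(0, 2 * np.pi, n_harmonics),
        "liver_hu": rng.normal(config.liver_hu_mean, config.liver_hu_sd),
    }


def _liver_mask(config: PhantomConfig, geom: dict, area_scale: float) -> np.ndarray:
    h, w = config.height, config.width
    cy, cx = geom["center"]
    a, b = geom["axes"]
    a, b = a * np.sqrt(area_scale), b * np.sqrt(area_scale)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(geom["angle"]), np.sin(geom["angle"])
    u = (ca * dx + sa * dy) / max(a, 1e-9)
    v = (-sa * dx + ca * dy) / max(b, 1e-9)
    rho = np.sqrt(u * u + v * v)
    theta = np.arctan2(v, u)
    r = np.ones_like(theta)
    for k, (e, p) in enumerate(zip(geom["eps"], geom["phase"]), start=2):
        r += e * np.cos(k * theta + p)
    return (rho <= r).astype(np.uint8)


def generate_slice(config: PhantomConfig, patient_id: str, slice_index: int,
                   area_scale: float = 1.0) -> PhantomSlice:
    """One phantom slice, deterministic in (config.seed, patient_id, slice_index)."""
    config.validate()
    if slice_index < 0:
        raise ValueError(f"slice_index must be >= 0, got {slice_index}")
    geom = _patient_geometry(config, patient_id)
    rng = keyed_rng(config.seed, "slice", patient_id, slice_index)
    h, w = config.height, config.width

    liver = _liver_mask(config, geom, area_scale)

    # background: mean level plus darker elliptical clutter
    image = np.full((h, w), config.background_hu_mean, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(config.clutter_count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ay, ax = rng.uniform(8, h / 6), rng.uniform(8, w / 6)
        hu = rng.uniform(config.background_hu_mean - config.background_hu_sd,
                         min(config.background_hu_mean + config.background_hu_sd, 0.0))
        blob = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        image[blob & (liver == 0)] = hu

    image[liver == 1] = geom["liver_hu"]

    # tumors: hypodense disks fully clipped to the liver
    tumor = np.zeros((h, w), dtype=np.uint8)
    if config.tumor_probability > 0 and rng.uniform() < config.tumor_probability:
        liver_pix = np.argwhere(liver == 1)
        if len(liver_pix):
            n_tumors = int(rng.integers(config.tumor_count_range[0],
                                        config.tumor_count_range[1] + 1))
            for _ in range(n_tumors):
                cy, cx = liver_pix[rng.integers(0, len(liver_pix))]
                radius = rng.uniform(*config.tumor_radius_range)
                blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
                tumor |= (blob & (liver == 1)).astype(np.uint8)
    image[tumor == 1] += config.tumor_hu_offset

    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=(h, w))

    ct = CTSlice(pixels=image, patient_id=patient_id, slice_index=slice_index,
                 intensity_state="raw_hu")
    return PhantomSlice(
        image=ct,
        liver_mask=BinaryMask(pixels=liver, label_kind="liver"),
        tumor_mask=BinaryMask(pixels=tumor, label_kind="tumor"),
        patient_id=patient_id,
        slice_index=slice_index,
    )


def volume_area_profile(n_slices: int) -> np.ndarray:
    """Smooth liver-area scale across a stack: small at the ends, largest mid-volume."""
    if n_slices == 1:
        return np.ones(1)
    t = np.linspace(0.0, 1.0, n_slices)
    return 0.35 + 0.65 * np.sin(np.pi * t) ** 2


def generate_volume(config: PhantomConfig, patient_id: str,
                    n_slices: int) -> Tuple[CTVolume, List[PhantomSlice]]:
    """A patient stack whose liver area follows a smooth axial profile."""
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    profile = volume_area_profile(n_slices)
    slices = [generate_slice(config, patient_id, i, area_scale=float(profile[i]))
              for i in range(n_slices)]
    volume = CTVolume(slices=[s.image for s in slices], patient_id=patient_id)
    return volume, slices


def generate_dataset(config: PhantomConfig, root, n_patients: int,
                     slices_per_patient: Tuple[int, int] = (70, 150),
                     image_format: str = "png") -> dict:
    """Write a labeled phantom dataset to disk in the per-slice file layout.

    Layout: ``<root>/<patient>/images/<idx>.png|jpg`` (3-channel image),
    ``<root>/<patient>/masks_liver/<idx>.png`` and
    ``<root>/<patient>/masks_tumor/<idx>.png`` (single-channel, background 0,
    organ 1).  Returns the manifest (also written as ``manifest.json``).
    """
    config.validate()
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if image_format not in ("png", "jpg"):
        raise ValueError(f"image_format must be png or jpg, got {image_format!r}")
    root = Path(root)
    try:
        root.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create dataset root {root}: {exc}") from exc

    manifest = {"seed": config.seed, "patients": {}}
    for p in range(n_patients):
        patient_id = f"phantom{p:03d}"
        n_rng = keyed_rng(config.seed, "count", patient_id)
        lo, hi = slices_per_patient
        n_slices = int(n_rng.integers(lo, hi + 1))
        _, slices = generate_volume(config, patient_id, n_slices)
        pdir = root / patient_id
        for sub in ("images", "masks_liver", "masks_tumor"):
            (pdir / sub).mkdir(parents=True, exist_ok=True)
        entries = []
        for s in slices:
            img_path = pdir / "images" / f"{s.slice_index:04d}.{image_format}"
            liver_path = pdir / "masks_liver" / f"{s.slice_index:04d}.png"
            tumor_path = pdir / "masks_tumor" / f"{s.slice_index:04d}.png"
            write_image(img_path, s.image)
            write_mask_png(liver_path, s.liver_mask)
            write_mask_png(tumor_path, s.tumor_mask)
            entries.append({
                "slice_index": s.slice_index,
                "image": str(img_path.relative_to(root)),
                "mask_liver": str(liver_path.relative_to(root)),
                "mask_tumor": str(tumor_path.relative_to(root)),
            })
        manifest["patients"][patient_id] = entries
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
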