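"""Readers and writers for the slice/mask formats the tool touches.

Formats: DICOM series (read), NIfTI volumes (read/write via nibabel),
per-slice JPG/PNG image + single-channel PNG mask pairs (read/write).

Conventions (used everywhere): row-major grids, origin top-left, 0-based
slice indices; masks hold only {0, 1} in memory regardless of the on-disk
encoding (any nonzero byte binarizes to 1, since annotation tools commonly
store 0/255); DICOM slices are ordered by axial position with instance
number as tie-break.

The DICOM reader is a minimal explicit-VR little-endian parser covering the
tags a CT series needs (rescale slope/intercept, geometry, pixel data) — the
usual third-party reader is not available in this environment.  A matching
minimal writer is provided so synthetic series can round-trip in tests.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import nibabel as nib
import numpy as np
from PIL import Image

INTENSITY_STATES = ("raw_hu", "windowed", "equalized", "normalized")


class FormatError(ValueError):
    """A file does not satisfy the reader's format expectations."""


class PairingError(ValueError):
    """An image and its mask do not belong together."""


@dataclass
class CTSlice:
    """One 2-D grid of scalar intensities with patient/slice identity."""

    pixels: np.ndarray
    patient_id: str = ""
    slice_index: int = 0
    intensity_state: str = "raw_hu"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise FormatError(f"slice pixels must be a 2-D grid, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("slice contains non-finite pixel values")
        if self.intensity_state not in INTENSITY_STATES:
            raise FormatError(f"unknown intensity_state {self.intensity_state!r}")
        if self.intensity_state == "normalized":
            if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
                raise FormatError("normalized slice must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """Same-shaped {0,1} grid: liver or tumor ground truth / prediction."""

    pixels: np.ndarray
    label_kind: str = "liver"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise FormatError(f"mask must be 2-D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"mask must contain only 0/1, found values {uniq[:10]}")
        self.pixels = arr.astype(np.uint8)
        if self.label_kind not in ("liver", "tumor"):
            raise FormatError(f"label_kind must be liver or tumor, got {self.label_kind!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class CTVolume:
    """Ordered stack of same-shaped slices from one patient."""

    slices: List[CTSlice] = field(default_factory=list)
    patient_id: str = ""

    def __post_init__(self) -> None:
        if not self.slices:
            raise FormatError("volume must contain at least one slice")
        shape = self.slices[0].pixels.shape
        for s in self.slices:
            if s.pixels.shape != shape:
                raise FormatError("all slices in a volume must share dimensions")
        idx = [s.slice_index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise FormatError("slice_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.slices)

    def to_array(self) -> np.ndarray:
        return np.stack([s.pixels for s in self.slices], axis=0)


# ---------------------------------------------------------------------------
# Minimal DICOM (explicit VR, little endian)
# ---------------------------------------------------------------------------

_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

TAG_PATIENT_ID = (0x0010, 0x0020)
TAG_INSTANCE = (0x0020, 0x0013)
TAG_POSITION = (0x0020, 0x0032)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_BITS = (0x0028, 0x0100)
TAG_PIXEL_REP = (0x0028, 0x0103)
TAG_INTERCEPT = (0x0028, 0x1052)
TAG_SLOPE = (0x0028, 0x1053)
TAG_PIXELDATA = (0x7FE0, 0x0010)


def _parse_dicom(path: Path) -> dict:
    data = path.read_bytes()
    if len(data) < 132 or data[128:132] != b"DICM":
        raise FormatError(f"{path}: not a DICOM file (missing DICM marker)")
    pos, elements = 132, {}
    while pos + 8 <= len(data):
        group, elem = struct.unpack_from("<HH", data, pos)
        vr = data[pos + 4:pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", data, pos + 8)
            body = pos + 12
        else:
            (length,) = struct.unpack_from("<H", data, pos + 6)
            body = pos + 8
        if length == 0xFFFFFFFF:
            raise FormatError(f"{path}: undefined-length elements are not supported")
        elements[(group, elem)] = (vr, data[body:body + length])
        pos = body + length
    return elements


def _ascii(elements: dict, tag: Tuple[int, int], default: Optional[str] = None) -> str:
    if tag not in elements:
        if default is not None:
            return default
        raise FormatError(f"missing required DICOM tag {tag[0]:04X},{tag[1]:04X}")
    return elements[tag][1].decode("ascii", "replace").strip("\x00 ")


def _ushort(elements: dict, tag: Tuple[int, int]) -> int:
    if tag not in elements:
        raise FormatError(f"missing required DICOM tag {tag[0]:04X},{tag[1]:04X}")
    return struct.unpack("<H", elements[tag][1])[0]


def read_dicom_file(path) -> Tuple[CTSlice, dict]:
    """One DICOM file -> (slice in HU, metadata)."""
    path = Path(path)
    el = _parse_dicom(path)
    for tag, name in ((TAG_SLOPE, "RescaleSlope"), (TAG_INTERCEPT, "RescaleIntercept")):
        if tag not in el:
            raise FormatError(f"{path}: missing rescale tag {name}")
    slope = float(_ascii(el, TAG_SLOPE))
    intercept = float(_ascii(el, TAG_INTERCEPT))
    rows, cols = _ushort(el, TAG_ROWS), _ushort(el, TAG_COLS)
    bits = _ushort(el, TAG_BITS) if TAG_BITS in el else 16
    signed = (_ushort(el, TAG_PIXEL_REP) == 1) if TAG_PIXEL_REP in el else False
    if TAG_PIXELDATA not in el:
        raise FormatError(f"{path}: missing pixel data")
    dtype = {8: np.int8 if signed else np.uint8,
             16: np.int16 if signed else np.uint16}.get(bits)
    if dtype is None:
        raise FormatError(f"{path}: unsupported bits allocated {bits}")
    raw = np.frombuffer(el[TAG_PIXELDATA][1], dtype=dtype)
    if raw.size != rows * cols:
        raise FormatError(f"{path}: pixel data size does not match Rows x Columns")
    hu = raw.reshape(rows, cols).astype(np.float64) * slope + intercept
    meta = {
        "patient_id": _ascii(el, TAG_PATIENT_ID, default=""),
        "instance": int(_ascii(el, TAG_INSTANCE, default="0") or 0),
        "position": float(_ascii(el, TAG_POSITION, default="0").split("\\")[-1] or 0.0),
    }
    return CTSlice(pixels=hu, patient_id=meta["patient_id"],
                   intensity_state="raw_hu"), meta


def read_dicom_series(directory) -> CTVolume:
    """Read one patient's series; slices ordered by axial position."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"{directory}: no DICOM files found")
    loaded = []
    for f in files:
        ct, meta = read_dicom_file(f)
        loaded.append((meta["position"], meta["instance"], ct, meta))
    patients = {m["patient_id"] for _, _, _, m in loaded}
    if len(patients) > 1:
        raise FormatError(f"{directory}: mixed patients in one series: {sorted(patients)}")
    loaded.sort(key=lambda t: (t[0], t[1]))
    slices = []
    for i, (_, _, ct, _) in enumerate(loaded):
        ct.slice_index = i
        slices.append(ct)
    return CTVolume(slices=slices, patient_id=loaded[0][3]["patient_id"])


def write_dicom(path, pixels: np.ndarray, patient_id: str, instance: int,
                position: float, slope: float = 1.0, intercept: float = -1024.0) -> None:
    """Minimal explicit-VR-LE writer for synthetic series (testing/fixtures).

    ``pixels`` are HU; stored values are ``(HU - intercept) / slope`` as
    unsigned 16-bit.
    """
    stored = np.round((np.asarray(pixels, dtype=np.float64) - intercept) / slope)
    if stored.min() < 0 or stored.max() > 0xFFFF:
        raise ValueError("stored values out of uint16 range for the given rescale")
    stored = stored.astype(np.uint16)
    rows, cols = stored.shape

    def element(tag, vr, value: bytes) -> bytes:
        if len(value) % 2:
            value += b" " if vr in (b"LO", b"DS", b"IS") else b"\x00"
        head = struct.pack("<HH", *tag) + vr
        if vr in _LONG_VRS:
            return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
        return head + struct.pack("<H", len(value)) + value

    body = b"".join([
        element(TAG_PATIENT_ID, b"LO", patient_id.encode()),
        element(TAG_INSTANCE, b"IS", str(instance).encode()),
        element(TAG_POSITION, b"DS", f"0\\0\\{position}".encode()),
        element(TAG_ROWS, b"US", struct.pack("<H", rows)),
        element(TAG_COLS, b"US", struct.pack("<H", cols)),
        element(TAG_BITS, b"US", struct.pack("<H", 16)),
        element(TAG_PIXEL_REP, b"US", struct.pack("<H", 0)),
        element(TAG_INTERCEPT, b"DS", repr(intercept).encode()),
        element(TAG_SLOPE, b"DS", repr(slope).encode()),
        element(TAG_PIXELDATA, b"OW", stored.tobytes()),
    ])
    Path(path).write_bytes(b"\x00" * 128 + b"DICM" + body)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def read_nifti(path, patient_id: str = "") -> CTVolume:
    """3-D NIfTI volume -> one slice per axial plane (last axis), indices 0..N-1."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    if not np.issubdtype(data.dtype, np.number):
        raise FormatError(f"{path}: non-scalar voxel type {data.dtype}")
    data = data.astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: volume contains non-finite voxels")
    slices = [CTSlice(pixels=data[:, :, k], patient_id=patient_id, slice_index=k)
              for k in range(data.shape[2])]
    return CTVolume(slices=slices, patient_id=patient_id)


def write_nifti(path, volume) -> None:
    """Write a CTVolume or (n, h, w) array as a NIfTI file (axial = last axis)."""
    if isinstance(volume, CTVolume):
        arr = np.stack([s.pixels for s in volume.slices], axis=2)
    else:
        arr = np.moveaxis(np.asarray(volume, dtype=np.float64), 0, 2)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


# ---------------------------------------------------------------------------
# Per-slice image / mask files
# ---------------------------------------------------------------------------

EXPORT_WINDOW = (-100.0, 200.0)


def write_image(path, ct: CTSlice) -> None:
    """Export a slice as a 3-channel 8-bit image (identical channels).

    Raw/windowed HU are mapped through the standard export window
    [-100, 200]; normalized slices are scaled from [0, 1].
    """
    px = ct.pixels
    if ct.intensity_state == "normalized":
        scaled = px * 255.0
    else:
        lo, hi = EXPORT_WINDOW
        scaled = (np.clip(px, lo, hi) - lo) / (hi - lo) * 255.0
    arr = np.round(scaled).astype(np.uint8)
    Image.fromarray(np.stack([arr] * 3, axis=-1)).save(str(path))


def write_mask_png(path, mask: BinaryMask) -> None:
    """Single-channel 8-bit PNG storing exactly {0, 1}; lossless round-trip."""
    if Path(path).suffix.lower() != ".png":
        raise ValueError("masks must be written as PNG (lossless)")
    Image.fromarray(mask.pixels, mode="L").save(str(path))


def read_mask_png(path, label_kind: str = "liver") -> BinaryMask:
    arr = np.asarray(Image.open(str(path)))
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask file must be single-channel, got shape {arr.shape}")
    return BinaryMask(pixels=(arr != 0).astype(np.uint8), label_kind=label_kind)


def read_slice_pair(image_path, mask_path, label_kind: str = "liver",
                    patient_id: str = "", slice_index: int = 0) -> Tuple[CTSlice, BinaryMask]:
    """Read a 3-channel image and its single-channel mask.

    Channels are collapsed to one (channels are identical by convention;
    otherwise they are averaged).  The mask is strictly binarized.
    """
    arr = np.asarray(Image.open(str(image_path)), dtype=np.float64)
    if arr.ndim == 3:
        if np.all(arr == arr[..., :1]):
            arr = arr[..., 0]
        else:
            arr = arr.mean(axis=-1)
    mask = read_mask_png(mask_path, label_kind=label_kind)
    if arr.shape != mask.pixels.shape:
        raise PairingError(
            f"image {arr.shape} and mask {mask.pixels.shape} dimensions differ "
            f"({image_path} / {mask_path})"
        )
    ct = CTSlice(pixels=arr, patient_id=patient_id, slice_index=slice_index,
                 intensity_state="raw_hu")
    return ct, mask
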