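"""ROI standardization: locate the tumor, crop at the largest diameter, resize.

Turns a slice + lesion mask + largest-diameter (LD) value into the
227 x 227 patch the feature extractor consumes. The crop side equals the
LD in pixels; callers holding an LD in millimetres convert it using the
pixel spacing from the image header before entering the pipeline.

Conventions (fixed so every step is testable):

* 0-based (row, col) coordinates; crop windows are half-open
  ``[r0, r0+side) x [c0, c0+side)`` with ``r0 = center - side // 2``.
* A window exceeding the slice boundary is shifted inward; a window larger
  than the slice edge-pads the slice symmetrically first. Shifting is
  preferred because it keeps real tissue in frame instead of padding.
* Resizing uses the Keys cubic-convolution kernel (a = -0.5) with
  half-pixel-center grid mapping and no anti-aliasing. Cubic
  interpolation can over/undershoot the input range by a bounded amount
  (<= ~10% of the range for this kernel); downstream scaling is per-image
  min-max, so this is harmless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

ROI_SIDE = 227


@dataclass(frozen=True)
class CropSpec:
    center: tuple[int, int]  # (row, col) in source-pixel coordinates
    side: int  # pixels, = LD

    def __post_init__(self):
        if self.side < 1:
            raise ValueError("crop side must be >= 1")


@dataclass(frozen=True)
class RoiImage:
    pixels: np.ndarray  # (227, 227) float
    patient_id: str
    timepoint: str  # "T1" | "T2"
    provenance: dict  # source, crop rect (row0, col0, side), resize convention

    def __post_init__(self):
        if self.pixels.shape != (ROI_SIDE, ROI_SIDE):
            raise ValueError(f"RoiImage must be {ROI_SIDE}x{ROI_SIDE}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("RoiImage intensities must be finite")


def locate_tumor_center(mask: np.ndarray) -> tuple[int, int]:
    """Centroid of the largest 8-connected foreground component.

    Rounded to the nearest integer with ties toward the lower index.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("no lesion in mask")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    counts = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(counts)) + 1  # ties -> lowest label id
    rows, cols = np.nonzero(labels == largest)
    return (
        int(np.ceil(rows.mean() - 0.5)),
        int(np.ceil(cols.mean() - 0.5)),
    )


def extract_roi(
    slice_: np.ndarray, spec: CropSpec, return_rect: bool = False
) -> np.ndarray | tuple[np.ndarray, tuple[int, int, int]]:
    """Square crop of side ``spec.side`` centered at ``spec.center``.

    The window is shifted inward where it exceeds the slice; if the side
    exceeds a slice dimension the slice is edge-padded symmetrically first.
    With ``return_rect`` also returns ``(row0, col0, side)`` in the
    coordinates of the (possibly padded) slice.
    """
    slice_ = np.asarray(slice_)
    if slice_.ndim != 2:
        raise ValueError("slice must be 2D")
    side = int(spec.side)
    if side < 1:
        raise ValueError("crop side must be >= 1")
    h, w = slice_.shape
    pad_r = max(0, side - h)
    pad_c = max(0, side - w)
    row, col = spec.center
    if pad_r or pad_c:
        before_r, before_c = pad_r // 2, pad_c // 2
        slice_ = np.pad(
            slice_,
            ((before_r, pad_r - before_r), (before_c, pad_c - before_c)),
            mode="edge",
        )
        row += before_r
        col += before_c
        h, w = slice_.shape
    r0 = int(np.clip(row - side // 2, 0, h - side))
    c0 = int(np.clip(col - side // 2, 0, w - side))
    crop = slice_[r0 : r0 + side, c0 : c0 + side].copy()
    if return_rect:
        return crop, (r0, c0, side)
    return crop


def _keys_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    ax = np.abs(x)
    w = np.zeros_like(ax)
    m1 = ax <= 1
    w[m1] = (a + 2) * ax[m1] ** 3 - (a + 3) * ax[m1] ** 2 + 1
    m2 = (ax > 1) & (ax < 2)
    w[m2] = a * ax[m2] ** 3 - 5 * a * ax[m2] ** 2 + 8 * a * ax[m2] - 4 * a
    return w


def _resize_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) Keys cubic interpolation matrix, edge-clamped."""
    scale = n_in / n_out
    x = (np.arange(n_out) + 0.5) * scale - 0.5
    base = np.floor(x).astype(int)
    W = np.zeros((n_out, n_in))
    for m in (-1, 0, 1, 2):
        idx = np.clip(base + m, 0, n_in - 1)
        w = _keys_kernel(x - (base + m))
        np.add.at(W, (np.arange(n_out), idx), w)
    return W


def resize_bicubic(roi: np.ndarray, target: int = ROI_SIDE) -> np.ndarray:
    """Resize a square grid to ``target`` x ``target`` by Keys bicubic
    interpolation (a = -0.5, half-pixel centers, no anti-aliasing)."""
    roi = np.asarray(roi, dtype=np.float64)
    if roi.ndim != 2 or roi.shape[0] != roi.shape[1]:
        raise ValueError("resize_bicubic requires a square 2D input")
    if roi.shape[0] < 4:
        raise ValueError("input side must be >= 4")
    if roi.shape[0] == target:
        return roi.copy()
    W = _resize_weights(roi.shape[0], target)
    return W @ roi @ W.T


def preprocess_roi(
    slice_: np.ndarray,
    mask: np.ndarray,
    ld_pixels: int,
    patient_id: str = "",
    timepoint: str = "T1",
    source: str = "",
) -> RoiImage:
    """locate -> crop at LD -> resize, with provenance recorded."""
    center = locate_tumor_center(mask)
    crop, rect = extract_roi(
        slice_, CropSpec(center=center, side=int(ld_pixels)), return_rect=True
    )
    pixels = resize_bicubic(crop, ROI_SIDE)
    return RoiImage(
        pixels=pixels,
        patient_id=patient_id,
        timepoint=timepoint,
        provenance={
            "source": source,
            "center": list(center),
            "crop_rect": list(rect),
            "resize": f"keys_bicubic_a-0.5_to_{ROI_SIDE}",
        },
    )


def load_slice(path: str | Path) -> np.ndarray:
    """Read a 2D grayscale slice from DICOM (single-frame), PNG or TIFF."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        import pydicom

        arr = pydicom.dcmread(path).pixel_array
    else:
        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse trivial channel axes
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-frame 2D image")
    return arr


def load_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a binary mask from an image file or a polygon CSV.

    A polygon CSV has ``row,col`` columns listing vertices in order;
    ``shape`` is required to rasterize it.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if shape is None:
            raise ValueError("shape is required to rasterize a polygon CSV mask")
        import pandas as pd
        from skimage.draw import polygon

        verts = pd.read_csv(path)
        rr, cc = polygon(
            verts["row"].to_numpy(), verts["col"].to_numpy(), shape=shape
        )
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask
    return load_slice(path) > 0
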