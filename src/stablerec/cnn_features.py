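"""Low-level transfer-learning descriptor: the AlexNET conv1→pool2 chain.

For each 227 x 227 ROI the extractor runs the first two stages of an
AlexNET-style architecture and flattens the second max-pooling output:

    227 --conv1 11x11x96 /4--> 55 --ReLU, LRN, maxpool 3x3 /2--> 27
        --conv2 5x5x256 pad 2--> 27 --ReLU, LRN, maxpool 3x3 /2--> 13

giving 13*13*256 = 43264 non-negative activations per ROI and 86528 per
patient (T1 block then T2 block). Low-level (edge/blob) features are used
deliberately: they respond to local structure of the lesion rather than
global object cues.

Local response normalization uses the original AlexNET constants
(depth 5, alpha = 1e-4, beta = 0.75, k = 2), with alpha applied to the
raw (undivided) window sum of squares.

Backends supply convolution weights behind a common protocol. The
default, fully offline backend draws filters from a seeded Gaussian: it
exercises the identical architecture and satisfies the same contracts
(dimensionality, determinism, non-negativity) without any weight
download, and is what the whole test/selection stack runs on. Grayscale
ROIs are min-max scaled to [0, 255], replicated to three channels, and
centered to [-1, 1] before conv1.

Flattening is channel-major (channel slowest, then row, then col); the
convention is recorded in saved metadata so feature indices stay portable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._rng import STREAM_BACKEND, substream
from .errors import BackendStateError
from .preprocessing import ROI_SIDE, RoiImage

# architecture constants; the dimensional chain is asserted at import time
POOL2_SIDE = 13
POOL2_CHANNELS = 256
CONV2_SIDE = 27
FEATURES_PER_ROI = POOL2_SIDE * POOL2_SIDE * POOL2_CHANNELS  # 43264
FEATURES_PER_PATIENT = 2 * FEATURES_PER_ROI  # 86528

#: (kernel, stride, padding) for conv1, pool1, conv2, pool2
LAYER_CHAIN = ((11, 4, 0), (3, 2, 0), (5, 1, 2), (3, 2, 0))

LRN_DEPTH = 5
LRN_ALPHA = 1e-4
LRN_BETA = 0.75
LRN_K = 2.0


def _out_side(side: int, k: int, s: int, p: int) -> int:
    return (side + 2 * p - k) // s + 1

_side = ROI_SIDE
for _k, _s, _p in LAYER_CHAIN:
    _side = _out_side(_side, _k, _s, _p)
assert _side == POOL2_SIDE, "layer chain does not produce a 13x13 pool2 grid"


class SeededAlexNetBackend:
    """Offline backend: AlexNET conv1/conv2 geometry, seeded Gaussian filters."""

    def __init__(self, seed: int = 0):
        rng = substream(seed, STREAM_BACKEND)
        self.conv1_weights = rng.normal(0.0, 0.01, (96, 11, 11, 3))
        self.conv1_bias = np.zeros(96)
        self.conv2_weights = rng.normal(0.0, 0.01, (256, 5, 5, 96))
        self.conv2_bias = np.zeros(256)
        self.backend_id = f"seeded-test:{seed}"

    def prepare_input(self, roi: np.ndarray) -> np.ndarray:
        """Min-max scale to [0, 255], replicate to 3 channels, center to [-1, 1]."""
        roi = np.asarray(roi, dtype=np.float64)
        lo, hi = roi.min(), roi.max()
        scaled = (roi - lo) * (255.0 / (hi - lo)) if hi > lo else np.zeros_like(roi)
        centered = (scaled - 127.5) / 127.5
        return np.repeat(centered[:, :, None], 3, axis=2)


def _check_backend(backend) -> None:
    for attr in ("conv1_weights", "conv1_bias", "conv2_weights", "conv2_bias"):
        if getattr(backend, attr, None) is None:
            raise BackendStateError(f"backend not initialized: missing {attr}")
    if backend.conv1_weights.shape != (96, 11, 11, 3):
        raise BackendStateError("conv1 weights must have shape (96, 11, 11, 3)")
    if backend.conv2_weights.shape != (256, 5, 5, 96):
        raise BackendStateError("conv2 weights must have shape (256, 5, 5, 96)")


def _conv(x: np.ndarray, weights: np.ndarray, bias: np.ndarray, stride: int,
          pad: int) -> np.ndarray:
    """Valid cross-correlation via im2col; x is (H, W, Cin)."""
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    k = weights.shape[1]
    win = sliding_window_view(x, (k, k, x.shape[2]))[::stride, ::stride, 0]
    n = win.shape[0]
    cols = win.reshape(n * n, -1)
    out = cols @ weights.reshape(weights.shape[0], -1).T + bias
    return out.reshape(n, n, weights.shape[0])


def _lrn(x: np.ndarray) -> np.ndarray:
    """Across-channel local response normalization (AlexNET constants)."""
    sq = x**2
    half = LRN_DEPTH // 2
    padded = np.concatenate(
        [np.zeros(x.shape[:2] + (half,)), sq, np.zeros(x.shape[:2] + (half,))],
        axis=2,
    )
    cs = np.concatenate(
        [np.zeros(x.shape[:2] + (1,)), np.cumsum(padded, axis=2)], axis=2
    )
    window = cs[:, :, LRN_DEPTH:] - cs[:, :, :-LRN_DEPTH]
    return x / (LRN_K + LRN_ALPHA * window) ** LRN_BETA


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2) -> np.ndarray:
    win = sliding_window_view(x, (k, k), axis=(0, 1))[::stride, ::stride]
    return win.max(axis=(-2, -1))


def forward_intermediates(roi: np.ndarray | RoiImage, backend) -> dict[str, np.ndarray]:
    """Run the chain and return every intermediate stage, keyed by name.

    Keys: conv1, relu1, norm1, pool1, conv2, relu2, norm2, pool2.
    """
    _check_backend(backend)
    pixels = roi.pixels if isinstance(roi, RoiImage) else np.asarray(roi)
    if pixels.shape != (ROI_SIDE, ROI_SIDE):
        raise ValueError(f"ROI must be {ROI_SIDE}x{ROI_SIDE}, got {pixels.shape}")
    x = backend.prepare_input(pixels)
    out: dict[str, np.ndarray] = {}
    out["conv1"] = _conv(x, backend.conv1_weights, backend.conv1_bias, 4, 0)
    out["relu1"] = np.maximum(out["conv1"], 0.0)
    out["norm1"] = _lrn(out["relu1"])
    out["pool1"] = _maxpool(out["norm1"])
    out["conv2"] = _conv(out["pool1"], backend.conv2_weights, backend.conv2_bias, 1, 2)
    out["relu2"] = np.maximum(out["conv2"], 0.0)
    out["norm2"] = _lrn(out["relu2"])
    out["pool2"] = _maxpool(out["norm2"])
    return out


def extract_pool2_features(roi: np.ndarray | RoiImage, backend) -> np.ndarray:
    """Flattened pool2 activations of one ROI: a (43264,) non-negative vector.

    Flattening is channel-major: ``flat = channel*169 + row*13 + col``.
    """
    pool2 = forward_intermediates(roi, backend)["pool2"]
    return np.ascontiguousarray(np.transpose(pool2, (2, 0, 1))).ravel()


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated per-patient descriptor: T1 block then T2 block."""

    values: np.ndarray  # (86528,)
    backend_id: str
    layout: str = "t1_then_t2;channel_major"

    def __post_init__(self):
        if self.values.shape != (FEATURES_PER_PATIENT,):
            raise ValueError(f"FeatureVector must have length {FEATURES_PER_PATIENT}")

    @staticmethod
    def timepoint_of(index: int) -> str:
        if not 0 <= index < FEATURES_PER_PATIENT:
            raise ValueError("index out of range")
        return "T1" if index < FEATURES_PER_ROI else "T2"


def concat_patient_features(
    f_t1: np.ndarray, f_t2: np.ndarray, backend_id: str = ""
) -> FeatureVector:
    f_t1 = np.asarray(f_t1)
    f_t2 = np.asarray(f_t2)
    if f_t1.shape != (FEATURES_PER_ROI,) or f_t2.shape != (FEATURES_PER_ROI,):
        raise ValueError(f"each ROI block must have length {FEATURES_PER_ROI}")
    return FeatureVector(
        values=np.concatenate([f_t1, f_t2]), backend_id=backend_id
    )


@dataclass(frozen=True)
class FeatureLocator:
    flat_index: int
    channel: int
    row: int
    col: int
    timepoint: str
    roi_rect: tuple[int, int, int, int]  # (row0, col0, height, width) on the ROI


def receptive_field_params() -> tuple[int, int, int]:
    """(size, jump, start-center offset) of a pool2 unit on the 227 grid,
    by the standard recurrence over the layer chain."""
    r, j, start = 1, 1, 0.0
    for k, s, p in LAYER_CHAIN:
        r += (k - 1) * j
        start += ((k - 1) / 2 - p) * j
        j *= s
    return r, j, int(start)


def locate_feature(flat_index: int, timepoint: str = "T1") -> FeatureLocator:
    """3D position and receptive-field rectangle of a within-ROI feature index."""
    if not 0 <= flat_index < FEATURES_PER_ROI:
        raise ValueError(
            f"flat_index must be in [0, {FEATURES_PER_ROI}), got {flat_index}"
        )
    channel, rem = divmod(int(flat_index), POOL2_SIDE * POOL2_SIDE)
    row, col = divmod(rem, POOL2_SIDE)
    size, jump, start = receptive_field_params()
    half = size // 2

    def _clip_span(unit: int) -> tuple[int, int]:
        center = start + jump * unit
        lo = max(0, center - half)
        hi = min(ROI_SIDE, center + half + 1)
        return lo, hi - lo

    r0, height = _clip_span(row)
    c0, width = _clip_span(col)
    return FeatureLocator(
        flat_index=int(flat_index),
        channel=channel,
        row=row,
        col=col,
        timepoint=timepoint,
        roi_rect=(r0, c0, height, width),
    )


def flatten_index(channel: int, row: int, col: int) -> int:
    """Inverse of :func:`locate_feature`'s flat→3D mapping."""
    return channel * POOL2_SIDE * POOL2_SIDE + row * POOL2_SIDE + col


@dataclass(frozen=True)
class ActivationMap:
    grid: np.ndarray  # (13, 13), non-negative
    channel: int
    timepoint: str

    def __post_init__(self):
        if self.grid.shape != (POOL2_SIDE, POOL2_SIDE):
            raise ValueError("activation map must be 13x13")


def activation_and_convolution_maps(
    roi: np.ndarray | RoiImage, channel: int, backend, timepoint: str = "T1"
) -> tuple[ActivationMap, np.ndarray]:
    """Per-channel 13x13 post-pool activation map and 27x27 convolutional map.

    The convolutional map is the raw conv2 output for the channel; the
    activation map is what remains after ReLU, normalization and max
    pooling.
    """
    if not 0 <= channel < POOL2_CHANNELS:
        raise ValueError(f"channel must be in [0, {POOL2_CHANNELS})")
    inter = forward_intermediates(roi, backend)
    amap = ActivationMap(
        grid=inter["pool2"][:, :, channel].copy(), channel=channel, timepoint=timepoint
    )
    return amap, inter["conv2"][:, :, channel].copy()


def resize_map_to_roi(grid: np.ndarray) -> np.ndarray:
    """Upsample a 13x13 or 27x27 map to ROI size for overlay figures."""
    from .preprocessing import resize_bicubic

    return resize_bicubic(np.asarray(grid, dtype=np.float64), ROI_SIDE)


def export_activation_overlay(
    roi: np.ndarray | RoiImage,
    grid: np.ndarray,
    path,
    rect: tuple[int, int, int, int] | None = None,
) -> None:
    """Write a PNG of the ROI with an activation map blended on top.

    The map (13x13 or 27x27) is upsampled to ROI size and alpha-blended
    into the red channel; ``rect`` optionally outlines a receptive-field
    rectangle (e.g. from :func:`locate_feature`).
    """
    from PIL import Image

    pixels = roi.pixels if isinstance(roi, RoiImage) else np.asarray(roi)

    def _norm(x):
        lo, hi = float(x.min()), float(x.max())
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    base = _norm(pixels.astype(np.float64))
    heat = _norm(resize_map_to_roi(grid))
    rgb = np.stack([base * 0.6 + heat * 0.4, base * 0.6, base * 0.6], axis=2)
    if rect is not None:
        r0, c0, h, w = rect
        rgb[r0 : r0 + h, [c0, min(c0 + w - 1, ROI_SIDE - 1)]] = [1.0, 0.0, 0.0]
        rgb[[r0, min(r0 + h - 1, ROI_SIDE - 1)], c0 : c0 + w] = [1.0, 0.0, 0.0]
    Image.fromarray((np.clip(rgb, 0, 1) * 255).astype(np.uint8)).save(path)


def save_feature_matrix(
    path: str | Path,
    matrix: np.ndarray,
    patient_ids: list[str],
    labels: np.ndarray,
    backend_id: str,
) -> None:
    """Persist a feature matrix as .npy with a CSV sidecar of row metadata."""
    path = Path(path)
    np.save(path, matrix)
    import csv

    with open(path.with_suffix(".csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "label", "backend_id", "layout"])
        for pid, lab in zip(patient_ids, labels):
            writer.writerow([pid, int(lab), backend_id, "t1_then_t2;channel_major"])


def extract_patient_matrix(rois_t1, rois_t2, backend) -> np.ndarray:
    """Stack per-patient concatenated descriptors into an (n, 86528) matrix."""
    rows = []
    for roi1, roi2 in zip(rois_t1, rois_t2):
        f1 = extract_pool2_features(roi1, backend)
        f2 = extract_pool2_features(roi2, backend)
        rows.append(concat_patient_features(f1, f2, backend.backend_id).values)
    return np.asarray(rows)
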