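"""Grid-scan segmentation and train/eval image preprocessing.

Segmentation slides a fixed window over a grid-arranged scan. A
placement must contain enough nuclear-channel (blue) pixels above an
intensity threshold (`min_content_frac` of the window); placements are
ranked by a centre-weighted content score, local maxima are kept, and
greedy non-maximum suppression removes duplicates.

Training augmentation follows the usual recipe for fluorescence crops:
random horizontal/vertical flips (p = 0.5 each), random rotation up to
±30° with bilinear resampling and zero fill, resize to a square target
(default 224), then per-channel ImageNet standardisation. Evaluation
preprocessing applies only the deterministic resize + standardisation.

Standardised outputs are plain float arrays (values leave [0, 1] by
design), ready for the convolutional encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.transform import resize as _sk_resize

from .cohort import CellImage

__all__ = ["SegmentationConfig", "AugmentConfig", "segment_grid",
           "augment", "preprocess_eval", "box_iou"]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_SD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class SegmentationConfig:
    window: int = 64
    stride: int = 16
    content_threshold: float = 0.25
    min_content_frac: float = 0.02
    nms_iou: float = 0.2

    def __post_init__(self):
        if self.stride > self.window:
            raise ValueError("stride must be <= window")
        for name in ("content_threshold", "min_content_frac", "nms_iou"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")


@dataclass(frozen=True)
class AugmentConfig:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    max_rot_deg: float = 30.0
    normalize_mean: tuple = IMAGENET_MEAN
    normalize_sd: tuple = IMAGENET_SD
    out_size: int = 224

    def __post_init__(self):
        if not (0 <= self.p_hflip <= 1 and 0 <= self.p_vflip <= 1):
            raise ValueError("flip probabilities must be in [0,1]")
        if self.max_rot_deg < 0:
            raise ValueError("max_rot_deg must be >= 0")


def box_iou(a: tuple, b: tuple) -> float:
    """IoU of two (row, col, h, w) half-open boxes."""
    r0 = max(a[0], b[0])
    c0 = max(a[1], b[1])
    r1 = min(a[0] + a[2], b[0] + b[2])
    c1 = min(a[1] + a[3], b[1] + b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


def segment_grid(image: np.ndarray, cfg: SegmentationConfig) -> list:
    """Detect cell crops in a grid-arranged scan.

    Returns a list of ((row, col, h, w), CellImage) pairs, boxes 0-based
    and half-open, ordered by decreasing content score.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape[:2]
    win, stride = cfg.window, cfg.stride
    if win > H or win > W:
        raise ValueError(f"window {win} larger than image {H}x{W}")

    # integral image of the blue-channel content indicator → O(1) window sums
    content = (image[:, :, 2] > cfg.content_threshold).astype(float)
    ii = np.pad(content.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    rows = np.arange(0, H - win + 1, stride)
    cols = np.arange(0, W - win + 1, stride)
    frac = (ii[np.ix_(rows + win, cols + win)]
            - ii[np.ix_(rows + win, cols)]
            - ii[np.ix_(rows, cols + win)]
            + ii[np.ix_(rows, cols)]) / (win * win)

    # ranking score: centre-weighted (triangular window) content, so the
    # placement best centred on a cell wins strictly (no plateaus)
    tri = 1.0 - np.abs(2.0 * np.arange(win) / (win - 1) - 1.0)
    by_rows = signal.correlate(content, tri[:, None], mode="valid")
    weighted = signal.correlate(by_rows, tri[None, :], mode="valid")
    scores = weighted[np.ix_(rows, cols)] / tri.sum() ** 2

    # local maxima (non-strict, 8-neighbourhood on the placement grid)
    padded = np.pad(scores, 1, constant_values=-1.0)
    is_max = np.ones_like(scores, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            is_max &= scores >= padded[1 + dr:1 + dr + scores.shape[0],
                                       1 + dc:1 + dc + scores.shape[1]]
    keep = is_max & (frac >= cfg.min_content_frac)

    cand = [(scores[i, j], (int(rows[i]), int(cols[j]), win, win))
            for i, j in zip(*np.nonzero(keep))]
    cand.sort(key=lambda t: (-t[0], t[1]))

    out = []
    kept_boxes: list = []
    for score, box in cand:
        if any(box_iou(box, kb) > cfg.nms_iou for kb in kept_boxes):
            continue
        kept_boxes.append(box)
        r, c, h, w = box
        crop = np.clip(image[r:r + h, c:c + w], 0.0, 1.0)
        out.append((box, CellImage(pixels=crop)))
    return out


def _resize(px: np.ndarray, out_size: int) -> np.ndarray:
    if px.shape[0] == out_size and px.shape[1] == out_size:
        return px
    return _sk_resize(px, (out_size, out_size), order=1, mode="constant",
                      cval=0.0, anti_aliasing=False, preserve_range=True)


def _standardize(px: np.ndarray, mean, sd) -> np.ndarray:
    return (px - np.asarray(mean)) / np.asarray(sd)


def augment(img: CellImage, cfg: AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Stochastic training transform; returns a standardised float array.

    Order: flip → rotate → resize → per-channel standardisation.
    """
    px = img.pixels
    if rng.random() < cfg.p_hflip:
        px = px[:, ::-1]
    if rng.random() < cfg.p_vflip:
        px = px[::-1, :]
    if cfg.max_rot_deg > 0:
        angle = rng.uniform(-cfg.max_rot_deg, cfg.max_rot_deg)
        px = ndimage.rotate(px, angle, axes=(1, 0), reshape=False,
                            order=1, mode="constant", cval=0.0)
        px = np.clip(px, 0.0, 1.0)
    px = _resize(np.ascontiguousarray(px), cfg.out_size)
    return _standardize(px, cfg.normalize_mean, cfg.normalize_sd)


def preprocess_eval(img: CellImage, cfg: AugmentConfig) -> np.ndarray:
    """Deterministic eval transform: resize + standardisation only."""
    px = _resize(img.pixels, cfg.out_size)
    return _standardize(px, cfg.normalize_mean, cfg.normalize_sd)
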