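"""Multi-class label images, per-class IoU evaluation and a baseline segmenter.

Label convention: 8-bit integer images with background=0, ooplasm=1, PVS=2,
ZP=3.  IoU is computed on the exact annular label classes (the PVS and ZP
classes are rings, not filled disks), because that is what the ground-truth
annotation encodes; per-class IoU of the 4-class problem then coincides with
the IoU of the corresponding one-vs-rest binary problems.

The baseline segmenter is a classical intensity-band pipeline (smoothing,
nearest-level classification, topological repair) adequate for phantom
images whose regions are intensity-banded by construction.  It is a
desk-scale segmenter with the same output contract as a learned multi-class
model: one connected region per class, holes filled, nesting enforced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

__all__ = [
    "LABEL_CODES",
    "CLASS_NAMES",
    "SegmentationError",
    "UndefinedIoUError",
    "SegmentationReport",
    "validate_label_image",
    "iou",
    "evaluate_segmentation",
    "segment_baseline",
]

logger = logging.getLogger(__name__)

LABEL_CODES = {"background": 0, "ooplasm": 1, "pvs": 2, "zp": 3}
CLASS_NAMES = {v: k for k, v in LABEL_CODES.items()}

#: minimum pixels per oocyte class for a segmentation to count as valid
_MIN_CLASS_PIXELS = 20


class SegmentationError(RuntimeError):
    """The segmenter could not produce a valid 4-class labeling."""


class UndefinedIoUError(ValueError):
    """IoU requested for a class absent from both label images."""


def validate_label_image(labels: np.ndarray) -> np.ndarray:
    """Check dtype/shape/codes of a label image; returns it as uint8."""
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ValueError("label image must be 2-D")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("label image must be integer-typed")
    bad = np.setdiff1d(np.unique(arr), [0, 1, 2, 3])
    if bad.size:
        raise ValueError(f"label image contains undefined codes {bad.tolist()}")
    return arr.astype(np.uint8)


def iou(y_label: np.ndarray, y_pred: np.ndarray, class_code: int) -> float:
    """Per-class intersection over union, TP / (TP + FP + FN).

    Symmetric in its two arguments.  Raises :class:`UndefinedIoUError` when
    the class occurs in neither image (0/0 is undefined, never silently 0).
    """
    a = np.asarray(y_label)
    b = np.asarray(y_pred)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if class_code not in (1, 2, 3):
        raise ValueError("class_code must be one of 1 (ooplasm), 2 (PVS), 3 (ZP)")
    ma, mb = a == class_code, b == class_code
    union = np.count_nonzero(ma | mb)
    if union == 0:
        raise UndefinedIoUError(
            f"class {class_code} absent from both images; IoU undefined")
    return np.count_nonzero(ma & mb) / union


@dataclass
class SegmentationReport:
    """Per-class IoU across an image set, with mean and sd per class."""

    per_image: dict[str, list[float]] = field(default_factory=dict)

    def mean(self, region: str) -> float:
        vals = self.per_image[region]
        return float(np.mean(vals)) if vals else float("nan")

    def sd(self, region: str) -> float:
        vals = self.per_image[region]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, dict[str, float]]:
        return {r: {"mean_iou": self.mean(r), "sd_iou": self.sd(r),
                    "n": len(v)}
                for r, v in self.per_image.items()}


def evaluate_segmentation(pairs) -> SegmentationReport:
    """Per-class IoU of (ground truth, prediction) pairs, averaged over images.

    Images where a class is absent from the ground truth are excluded from
    that class's average with a logged warning (valid MII oocytes carry all
    three regions, so absence marks a degenerate ground truth, not a miss).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty evaluation set")
    report = SegmentationReport(per_image={r: [] for r in ("ooplasm", "pvs", "zp")})
    for idx, (y_label, y_pred) in enumerate(pairs):
        if np.asarray(y_label).shape != np.asarray(y_pred).shape:
            raise ValueError(f"shape mismatch in pair {idx}")
        for region, code in (("ooplasm", 1), ("pvs", 2), ("zp", 3)):
            if not np.any(np.asarray(y_label) == code):
                logger.warning("pair %d: class %s absent from ground truth; "
                               "excluded from its mean", idx, region)
                continue
            report.per_image[region].append(iou(y_label, y_pred, code))
    return report


def _largest_filled(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def segment_baseline(image: np.ndarray,
                     intensity_levels: dict[str, float] | None = None,
                     smooth_sigma: float = 0.5) -> np.ndarray:
    """Segment a single-oocyte grayscale image into the four classes.

    The image is Gaussian-smoothed and each pixel assigned to the nearest
    intensity level.  When ``intensity_levels`` is None the four levels are
    estimated with multi-Otsu thresholding and mapped to classes under the
    brightfield-phantom brightness ordering ooplasm < ZP < background < PVS.
    Topological repair then enforces one region per class and proper
    nesting: the oocyte is the largest connected non-background component
    with holes filled, the ooplasm the largest filled ooplasm component
    inside it, and PVS/ZP are rebuilt as the annuli between the filled
    boundaries (so e.g. a stray PVS pixel inside the ooplasm is reassigned).

    Raises
    ------
    SegmentationError
        If fewer than four intensity modes are distinguishable or any
        repaired class ends up empty (e.g. a blank image).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    smoothed = ndimage.gaussian_filter(img, smooth_sigma)

    if intensity_levels is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cuts = threshold_multiotsu(smoothed, classes=4)
            except ValueError as exc:
                raise SegmentationError(
                    "fewer than 4 distinguishable intensity modes") from exc
        bins = np.digitize(smoothed, cuts)
        centers = [smoothed[bins == k].mean() if np.any(bins == k) else np.nan
                   for k in range(4)]
        if np.any(np.isnan(centers)) or np.min(np.diff(sorted(centers))) < 5.0:
            raise SegmentationError("fewer than 4 distinguishable intensity modes")
        # brightness ordering of the four phantom bands, darkest first
        order = ("ooplasm", "zp", "background", "pvs")
        levels = dict(zip(order, sorted(centers)))
    else:
        levels = dict(intensity_levels)
        if set(levels) != set(LABEL_CODES):
            raise ValueError("intensity_levels must name all four classes")

    if not (levels["ooplasm"] < levels["zp"] < levels["background"] < levels["pvs"]):
        raise SegmentationError(
            "intensity bands do not follow the ooplasm < ZP < background < PVS "
            "brightness ordering this segmenter assumes")

    # nearest-level classification on the raw image: band levels are far
    # apart relative to the noise, and classifying unsmoothed pixels keeps
    # single-pixel PVS bands and exact region edges (smoothing would blend
    # boundary pixels into the wrong band)
    names = ("background", "ooplasm", "pvs", "zp")
    lut = np.array([levels[n] for n in names])
    nearest = np.argmin(np.abs(img[..., None] - lut), axis=-1)
    cls = np.zeros(img.shape, dtype=np.uint8)
    for i, n in enumerate(names):
        cls[nearest == i] = LABEL_CODES[n]

    # topological repair: one oocyte (largest non-background component,
    # holes filled), one filled ooplasm inside it; the ZP is the remaining
    # shell and the PVS band keeps only pixels between ooplasm and ZP, so
    # any PVS pixel inside the ooplasm is reassigned
    oocyte = _largest_filled(cls > 0)
    ooplasm = _largest_filled((cls == 1) & oocyte)
    if not oocyte.any() or not ooplasm.any():
        raise SegmentationError("segmentation failure: no oocyte found")
    inner = ndimage.binary_fill_holes(ooplasm | ((cls == 2) & oocyte))
    labels = np.zeros(img.shape, dtype=np.uint8)
    labels[oocyte] = 3
    labels[inner] = 2
    labels[ooplasm] = 1
    for region, code in (("ooplasm", 1), ("pvs", 2), ("zp", 3)):
        if np.count_nonzero(labels == code) < _MIN_CLASS_PIXELS:
            raise SegmentationError(
                f"segmentation failure: class {region!r} empty or degenerate")
    return labels
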