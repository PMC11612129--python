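"""ROI detection and standardization.

Detection is pluggable: an adapter protocol for any external one-stage
detector, a built-in intensity-deviation blob detector good enough for clean
phantoms, and an oracle that reads ground-truth boxes from a manifest (used in
tests).  Detected crops are standardized the way the descriptor network
expects: rescaled only when a side exceeds the target (preserving the
width-height ratio, which carries the orientation descriptor) and zero-padded
to ``target x target`` with the content at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label
from skimage.transform import resize

from .errors import ConfigurationError, GeometryError, InputError
from .roi_types import BoundingBox

DEFAULT_TARGET = 450


@dataclass(frozen=True)
class StandardROI:
    """A ``target x target`` network input with its inverse-mapping metadata.

    ``scale_factor`` is the crop-to-ROI scaling (1.0 when no side exceeded the
    target); ``pad_offsets`` is the (x, y) position of the content inside the
    padded square (top-left placement, hence (0, 0)); ``content_shape`` is the
    (height, width) of the scaled content.  Together they invert attention
    maps and ROI coordinates back to the source image.
    """

    pixels: np.ndarray
    scale_factor: float
    pad_offsets: tuple[int, int]
    content_shape: tuple[int, int]
    source_box: BoundingBox

    @property
    def target(self) -> int:
        return self.pixels.shape[0]

    def to_image_coords(self, x: float, y: float) -> tuple[float, float]:
        """Map ROI-space coordinates back onto the source image."""
        ox, oy = self.pad_offsets
        return (
            (x - ox) / self.scale_factor + self.source_box.x0,
            (y - oy) / self.scale_factor + self.source_box.y0,
        )


class Detector(Protocol):
    """Adapter interface for any detector returning (box, confidence) lists."""

    def propose(self, image: np.ndarray) -> list[BoundingBox]:
        ...


class OracleDetector:
    """Returns ground-truth boxes recorded in a manifest (test double)."""

    def __init__(self, manifest: dict):
        self._boxes = {
            r["image_id"]: BoundingBox(*r["box"], confidence=1.0)
            for r in manifest["records"]
        }
        self._by_checksum: dict[bytes, str] = {}

    def boxes_for(self, image_id: str) -> list[BoundingBox]:
        return [self._boxes[image_id]]

    def propose(self, image: np.ndarray) -> list[BoundingBox]:  # pragma: no cover
        raise InputError("OracleDetector needs an image_id; use boxes_for()")


class BlobDetector:
    """Built-in fallback: intensity-deviation thresholding + components.

    Pixels deviating from the background median (after smoothing) are
    thresholded, connected components above a minimum area become candidate
    nodules, and each box is expanded downward to include the posterior
    column.  Confidence is the component's mean absolute deviation rescaled
    to [0, 1] — crude, but monotone in lesion contrast.
    """

    def __init__(self, smooth_sigma: float = 2.5, dev_threshold: float = 0.22,
                 min_area_fraction: float = 0.004, posterior_factor: float = 1.1):
        self.smooth_sigma = smooth_sigma
        self.dev_threshold = dev_threshold
        self.min_area_fraction = min_area_fraction
        self.posterior_factor = posterior_factor

    def propose(self, image: np.ndarray) -> list[BoundingBox]:
        img = np.asarray(image, dtype=np.float64)
        sm = gaussian_filter(img, self.smooth_sigma)
        bg = np.median(sm)
        dev = np.abs(sm - bg) / max(bg, 1.0)
        blobs = cc_label(dev > self.dev_threshold)
        h, w = img.shape
        min_area = self.min_area_fraction * h * w
        comps = []  # [x0, y0, x1, y1, score, nodule_height]
        for lab in range(1, blobs.max() + 1):
            ys, xs = np.where(blobs == lab)
            if len(ys) < min_area:
                continue
            y0, y1 = int(ys.min()), int(ys.max()) + 1
            x0, x1 = int(xs.min()), int(xs.max()) + 1
            score = float(np.clip(dev[ys, xs].mean() / 0.9, 0.05, 1.0))
            comps.append([x0, y0, x1, y1, score, y1 - y0])
        # Merge a nodule with the bright/dark posterior column it casts:
        # components with strong horizontal overlap and a small vertical gap.
        merged = True
        while merged:
            merged = False
            for i in range(len(comps)):
                for j in range(i + 1, len(comps)):
                    a, b = comps[i], comps[j]
                    overlap = min(a[2], b[2]) - max(a[0], b[0])
                    min_w = min(a[2] - a[0], b[2] - b[0])
                    gap = max(a[1], b[1]) - min(a[3], b[3])
                    if overlap >= 0.5 * min_w and gap <= 0.15 * h:
                        top = a if a[1] <= b[1] else b
                        comps[i] = [min(a[0], b[0]), min(a[1], b[1]),
                                    max(a[2], b[2]), max(a[3], b[3]),
                                    max(a[4], b[4]), top[5]]
                        comps.pop(j)
                        merged = True
                        break
                if merged:
                    break
        out = []
        for x0, y0, x1, y1, score, nod_h in comps:
            # include the posterior column below the nodule
            y1 = max(y1, y0 + int(round((1.0 + self.posterior_factor) * nod_h)))
            out.append(BoundingBox(x0, y0, x1, min(h, y1), confidence=score))
        return out


def detect(image: np.ndarray, conf_threshold: float = 0.25,
           detector: Detector | None = None) -> list[BoundingBox]:
    """Run a detector and keep boxes with confidence >= threshold.

    Results are sorted by confidence descending; lowering the threshold can
    only add boxes, never remove one (monotone filter).
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ConfigurationError(f"conf_threshold {conf_threshold} outside [0, 1]")
    image = np.asarray(image)
    if image.size == 0:
        raise InputError("empty image")
    if image.ndim != 2:
        raise InputError("detector expects a single-channel grayscale image")
    detector = detector or BlobDetector()
    boxes = [b for b in detector.propose(image) if b.confidence >= conf_threshold]
    return sorted(boxes, key=lambda b: -b.confidence)


def standardize_roi(image: np.ndarray, box: BoundingBox,
                    target: int = DEFAULT_TARGET) -> StandardROI:
    """Crop, conditionally rescale, and zero-pad a box to ``target x target``.

    The crop is rescaled by ``target / max(width, height)`` only when a side
    exceeds the target, preserving the aspect ratio; it is then placed at the
    top-left of a zero square.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if box.x0 < 0 or box.y0 < 0 or box.x1 > w or box.y1 > h:
        raise GeometryError(f"box {box} exceeds image bounds {w}x{h}")
    crop = image[box.y0:box.y1, box.x0:box.x1].astype(np.float32)
    ch, cw = crop.shape
    if max(ch, cw) > target:
        scale = target / max(ch, cw)
        nh = min(target, max(1, int(round(ch * scale))))
        nw = min(target, max(1, int(round(cw * scale))))
        crop = resize(crop, (nh, nw), anti_aliasing=True, preserve_range=True
                      ).astype(np.float32)
    else:
        scale = 1.0
        nh, nw = ch, cw
    out = np.zeros((target, target), dtype=np.float32)
    out[:nh, :nw] = crop
    return StandardROI(pixels=out, scale_factor=scale, pad_offsets=(0, 0),
                       content_shape=(nh, nw), source_box=box)


def evaluate_detection(
    predictions: dict[str, list[BoundingBox]],
    truths: dict[str, list[BoundingBox]],
    iou_threshold: float = 0.5,
) -> tuple[float, float, float]:
    """Precision, recall and interpolated average precision over a dataset.

    Predictions are matched greedily in descending confidence, each to the
    highest-IoU unmatched truth of its image (IoU >= threshold).  AP is the
    area under the interpolated precision-recall curve; with no predictions,
    precision is reported as 0 by convention.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ConfigurationError(f"iou_threshold {iou_threshold} outside (0, 1]")
    n_truth = sum(len(v) for v in truths.values())
    flat = [(img, b) for img, boxes in predictions.items() for b in boxes]
    flat.sort(key=lambda t: -t[1].confidence)
    matched: dict[str, set[int]] = {img: set() for img in truths}
    tp_flags = []
    for img, pred in flat:
        gts = truths.get(img, [])
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if j in matched.setdefault(img, set()):
                continue
            i = pred.iou(gt)
            if i > best_iou:
                best_iou, best_j = i, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[img].add(best_j)
            tp_flags.append(1)
        else:
            tp_flags.append(0)
    if not tp_flags:
        return 0.0, 0.0, 0.0
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(1 - np.asarray(tp_flags))
    recall = tp / max(n_truth, 1)
    precision = tp / (tp + fp)
    final_p = float(precision[-1])
    final_r = float(recall[-1])
    # Interpolated PR curve: precision envelope from the right.
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    ap = float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    return final_p, final_r, ap
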