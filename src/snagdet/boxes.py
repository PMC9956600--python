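"""Axis-aligned box utilities (pure numpy).

All boxes are (x_min, y_min, x_max, y_max), 0-based, half-open in pixel
units, so a box's area is (x_max−x_min)·(y_max−y_min).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "box_area", "compute_iou", "iou_matrix", "clip_boxes",
    "encode_boxes", "decode_boxes", "nms",
]


def box_area(boxes: np.ndarray) -> np.ndarray:
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    return (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])


def compute_iou(box_a, box_b) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint or degenerate."""
    a = np.asarray(box_a, dtype=np.float64)
    b = np.asarray(box_b, dtype=np.float64)
    area_a = max(a[2] - a[0], 0.0) * max(a[3] - a[1], 0.0)
    area_b = max(b[2] - b[0], 0.0) * max(b[3] - b[1], 0.0)
    if area_a <= 0.0 or area_b <= 0.0:
        warnings.warn("degenerate box in IoU computation; returning 0")
        return 0.0
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return float(inter / (area_a + area_b - inter))


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """(N, M) IoU matrix; degenerate boxes yield 0 rows/columns."""
    a = np.atleast_2d(np.asarray(boxes_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(boxes_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    area_a = box_area(a)[:, None]
    area_b = box_area(b)[None, :]
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    union = area_a + area_b - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def clip_boxes(boxes: np.ndarray, height: int, width: int) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64).copy()
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, width)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, height)
    return boxes


def _to_cwh(boxes: np.ndarray):
    w = boxes[:, 2] - boxes[:, 0]
    h = boxes[:, 3] - boxes[:, 1]
    cx = boxes[:, 0] + 0.5 * w
    cy = boxes[:, 1] + 0.5 * h
    return cx, cy, w, h


def encode_boxes(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Parameterise ``boxes`` relative to ``anchors`` as (tx, ty, tw, th)."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    anchors = np.atleast_2d(np.asarray(anchors, dtype=np.float64))
    bx, by, bw, bh = _to_cwh(boxes)
    ax, ay, aw, ah = _to_cwh(anchors)
    return np.stack([(bx - ax) / aw, (by - ay) / ah,
                     np.log(bw / aw), np.log(bh / ah)], axis=1)


def decode_boxes(deltas: np.ndarray, anchors: np.ndarray,
                 clip_exp: float = 4.0) -> np.ndarray:
    """Inverse of :func:`encode_boxes`; log-scales clipped for stability."""
    deltas = np.atleast_2d(np.asarray(deltas, dtype=np.float64))
    anchors = np.atleast_2d(np.asarray(anchors, dtype=np.float64))
    ax, ay, aw, ah = _to_cwh(anchors)
    cx = deltas[:, 0] * aw + ax
    cy = deltas[:, 1] * ah + ay
    w = aw * np.exp(np.clip(deltas[:, 2], -clip_exp, clip_exp))
    h = ah * np.exp(np.clip(deltas[:, 3], -clip_exp, clip_exp))
    return np.stack([cx - 0.5 * w, cy - 0.5 * h, cx + 0.5 * w, cy + 0.5 * h], axis=1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score-ordered."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    scores = np.asarray(scores, dtype=np.float64)
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    suppressed = np.zeros(len(scores), dtype=bool)
    ious = iou_matrix(boxes, boxes)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        suppressed |= ious[i] > iou_thr
    return np.asarray(keep, dtype=np.int64)
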