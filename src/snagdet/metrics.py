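"""Detection metrics: IoU matching, precision/recall/F1, P-R curves, AP.

Matching is greedy at a fixed IoU threshold: detections are visited in
descending score order and matched to the unmatched ground-truth box of
highest IoU ≥ threshold; each ground truth matches at most once, so a
single box covering two true crowns scores one TP and one FN.  AP is the
area under the monotone (precision-envelope) interpolated P-R curve,
evaluated COCO-style at 101 equally spaced recall points; the all-point
continuous integral is available behind a flag.  Size-stratified AP uses
the 32² / 96² box-area classes, with the small-object AP averaged over IoU
thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import box_area, compute_iou, iou_matrix

RECALL_POINTS = np.linspace(0.0, 1.0, 101)
COCO_IOU_RANGE = np.arange(0.5, 0.96, 0.05)


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    det_matched: list[bool] = field(default_factory=list)  # score-ordered
    matched_gt: list[int] = field(default_factory=list)    # gt index or -1

    def counts(self) -> tuple[int, int, int]:
        return self.tp, self.fp, self.fn


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    scores: np.ndarray
    ap: float


@dataclass
class EvalReport:
    ap50: float                        # percent
    recall50: float                    # percent, at the operating threshold
    precision50: float                 # percent, at the operating threshold
    f1: float                          # percent
    operating_threshold: float
    ap_small: float | None             # percent, IoU 0.50:0.95, area < 32²
    ap_by_size: dict[str, float | None]
    counts: dict[str, int]
    pr_curve: PRCurve | None = None

    def as_dict(self) -> dict:
        return {
            "ap50": self.ap50, "recall50": self.recall50,
            "precision50": self.precision50, "f1": self.f1,
            "operating_threshold": self.operating_threshold,
            "ap_small": self.ap_small,
            "ap_by_size": self.ap_by_size, "counts": self.counts,
        }


# ---------------------------------------------------------------------------
# matching and scalar metrics
# ---------------------------------------------------------------------------

def match_detections(detections: list[tuple[np.ndarray, float]],
                     gt_boxes: np.ndarray, iou_thr: float = 0.5) -> MatchResult:
    """Greedy match of scored detections against ground truth.

    ``detections`` is a list of (box, score); order of the input does not
    matter — matching always proceeds by descending score.
    """
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    order = sorted(range(len(detections)),
                   key=lambda i: -float(detections[i][1]))
    taken = np.zeros(len(gt_boxes), dtype=bool)
    det_matched, matched_gt = [], []
    for i in order:
        box = np.asarray(detections[i][0], dtype=np.float64)
        best_j, best_iou = -1, iou_thr
        for j in range(len(gt_boxes)):
            if taken[j]:
                continue
            iou = compute_iou(box, gt_boxes[j])
            if iou >= best_iou and iou > 0:
                best_iou, best_j = iou, j
        if best_j >= 0:
            taken[best_j] = True
        det_matched.append(best_j >= 0)
        matched_gt.append(best_j)
    tp = int(sum(det_matched))
    return MatchResult(tp=tp, fp=len(detections) - tp,
                       fn=int(len(gt_boxes) - tp),
                       det_matched=det_matched, matched_gt=matched_gt)


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(P, R, F1) in percent; zero-denominator cases return 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall given directly in percent."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


# ---------------------------------------------------------------------------
# P-R curve and AP
# ---------------------------------------------------------------------------

def _dataset_match_flags(detections_by_image: dict, gt_by_image: dict,
                         iou_thr: float,
                         gt_filter=None) -> tuple[np.ndarray, np.ndarray, int]:
    """Pool per-image greedy matches into score-sorted TP flags.

    ``gt_filter`` optionally restricts ground truth (and detections matched
    to excluded ground truth are dropped rather than counted as FP, the
    standard size-stratified protocol).
    """
    scores, flags, drop = [], [], []
    n_gt = 0
    for img_id, gts in gt_by_image.items():
        gts = np.asarray(gts, dtype=np.float64).reshape(-1, 4)
        keep_mask = np.ones(len(gts), dtype=bool)
        if gt_filter is not None and len(gts):
            keep_mask = np.array([gt_filter(b) for b in gts], dtype=bool)
        dets = detections_by_image.get(img_id, [])
        res = match_detections(dets, gts, iou_thr)
        order = sorted(range(len(dets)), key=lambda i: -float(dets[i][1]))
        n_gt += int(keep_mask.sum())
        for rank, i in enumerate(order):
            j = res.matched_gt[rank]
            if j >= 0 and not keep_mask[j]:
                drop.append(True)      # matched an excluded GT: ignore
            else:
                drop.append(False)
            scores.append(float(dets[i][1]))
            flags.append(j >= 0 and keep_mask[j])
    scores = np.asarray(scores)
    flags = np.asarray(flags, dtype=bool)
    drop = np.asarray(drop, dtype=bool)
    if len(scores):
        scores, flags = scores[~drop], flags[~drop]
    return scores, flags, n_gt


def pr_curve_and_ap(detections_by_image: dict, gt_by_image: dict,
                    iou_thr: float = 0.5, interpolation: str = "coco101",
                    gt_filter=None) -> PRCurve | None:
    """Dataset-pooled P-R curve and AP at one IoU threshold.

    Returns ``None`` (undefined) when the filtered ground truth is empty.
    ``interpolation`` is ``"coco101"`` (precision envelope sampled at 101
    recall points) or ``"allpoint"`` (exact area under the envelope).
    """
    scores, flags, n_gt = _dataset_match_flags(
        detections_by_image, gt_by_image, iou_thr, gt_filter)
    if n_gt == 0:
        return None
    order = np.argsort(-scores, kind="stable")
    flags = flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # monotone precision envelope (from the right)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "coco101":
        idx = np.searchsorted(recall, RECALL_POINTS, side="left")
        interp = np.where(idx < len(envelope), envelope[np.minimum(idx, max(len(envelope) - 1, 0))], 0.0)
        ap = float(interp.mean()) if len(envelope) else 0.0
    elif interpolation == "allpoint":
        r_prev = np.concatenate([[0.0], recall[:-1]])
        ap = float(np.sum((recall - r_prev) * envelope)) if len(envelope) else 0.0
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return PRCurve(recall=recall, precision=precision,
                   scores=scores[order], ap=ap)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def _size_filter(lo: float | None, hi: float | None):
    def ok(box):
        a = float(box_area(box[None])[0])
        return (lo is None or a >= lo) and (hi is None or a < hi)
    return ok


def evaluate_dataset(detections_by_image: dict, gt_by_image: dict,
                     iou_thr: float = 0.5, interpolation: str = "coco101",
                     operating_threshold: float | None = None,
                     with_curve: bool = True) -> EvalReport:
    """Full metric suite over a dataset.

    ``detections_by_image`` and ``gt_by_image`` map image id → list of
    (box, score) / (N, 4) array.  The operating score threshold for the
    reported precision/recall/F1 defaults to the threshold maximising F1
    along the score sweep (it is returned in the report).
    """
    missing = set(detections_by_image) - set(gt_by_image)
    if missing:
        raise ValueError(f"detections reference unknown image ids: {sorted(missing)}")
    curve = pr_curve_and_ap(detections_by_image, gt_by_image, iou_thr,
                            interpolation)
    if curve is None:
        raise ValueError("no ground truth boxes; evaluation undefined")

    # choose operating point
    if operating_threshold is None:
        p = curve.precision * 100
        r = curve.recall * 100
        f1s = np.where(p + r > 0, 2 * p * r / np.maximum(p + r, 1e-9), 0.0)
        best = int(np.argmax(f1s)) if len(f1s) else 0
        operating_threshold = float(curve.scores[best]) if len(f1s) else 0.5

    tp = fp = fn = 0
    for img_id, gts in gt_by_image.items():
        dets = [d for d in detections_by_image.get(img_id, [])
                if float(d[1]) >= operating_threshold]
        res = match_detections(dets, gts, iou_thr)
        tp += res.tp
        fp += res.fp
        fn += res.fn
    p_pct, r_pct, f1_pct = precision_recall_f1(tp, fp, fn)

    size_bounds = {"small": (None, SMALL := 32 * 32),
                   "medium": (SMALL, LARGE := 96 * 96),
                   "large": (LARGE, None)}
    ap_by_size: dict[str, float | None] = {}
    for name, (lo, hi) in size_bounds.items():
        aps = []
        for t in COCO_IOU_RANGE:
            c = pr_curve_and_ap(detections_by_image, gt_by_image, float(t),
                                interpolation, gt_filter=_size_filter(lo, hi))
            if c is not None:
                aps.append(c.ap)
        ap_by_size[name] = 100.0 * float(np.mean(aps)) if aps else None

    return EvalReport(
        ap50=100.0 * curve.ap,
        recall50=r_pct, precision50=p_pct, f1=f1_pct,
        operating_threshold=float(operating_threshold),
        ap_small=ap_by_size["small"],
        ap_by_size=ap_by_size,
        counts={"tp": tp, "fp": fp, "fn": fn,
                "n_gt": int(sum(np.asarray(g).reshape(-1, 4).shape[0]
                                for g in gt_by_image.values())),
                "n_det": int(sum(len(d) for d in detections_by_image.values()))},
        pr_curve=curve if with_curve else None,
    )


def write_pr_curve_csv(path, curve: PRCurve) -> None:
    rows = ["score,recall,precision"]
    rows += [f"{s:.6f},{r:.6f},{p:.6f}"
             for s, r, p in zip(curve.scores, curve.recall, curve.precision)]
    from pathlib import Path
    Path(path).write_text("\n".join(rows) + "\n")


def plot_pr_curve(path, curve: PRCurve, title: str = "P-R curve") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.recall, curve.precision, lw=1.5)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{title} (AP={curve.ap:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
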