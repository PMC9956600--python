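"""Two-stage detection head: region proposals, RoI pooling, dynamic training.

The region-proposal network (RPN) slides a small convolutional head over
every pyramid level, predicting an objectness score and box deltas for 3
anchors per position (one scale per level, aspect ratios 0.5/1/2).  Decoded,
clipped and NMS-filtered proposals are pooled with RoI-Align into fixed
7×7 patches and classified/regressed by a two-layer fully connected head.

Training follows the dynamic scheme: the IoU threshold T_now separating
positive from negative RoIs starts at 0.5 and is periodically updated to
the mean of the recorded per-iteration K_I-th-largest proposal IoU, and the
Smooth-L1 transition point β_now starts at 1 and is updated to the median
of the recorded per-iteration K_β-th-smallest regression errors (center
coordinates summarised by their mean absolute value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import boxes as B
from .backbone import FeatureMap, SwinBackbone, SwinConfig
from .neck import PyramidNeck, STRIDES
from .nn import Linear, Module, Tensor, concat, where

IMG_MEAN, IMG_STD = 0.5, 0.25  # applied after scaling pixels to [0, 1]


# ---------------------------------------------------------------------------
# configuration & simple types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorConfig:
    scale_factor: float = 8.0          # anchor side = scale_factor × stride
    ratios: tuple[float, ...] = (0.5, 1.0, 2.0)

    @property
    def anchors_per_position(self) -> int:
        return len(self.ratios)


@dataclass(frozen=True)
class RoIConfig:
    output_size: int = 7
    sampling_points: int = 2           # sub-bin sample grid per axis
    fc_dim: int = 1024
    canonical_size: float = 64.0       # sqrt(area) mapped to level 2 (P3)


@dataclass
class Proposal:
    box: np.ndarray                    # (4,) x_min, y_min, x_max, y_max
    objectness: float
    level: str


@dataclass
class Detection:
    box: np.ndarray
    score: float
    category: str = "sdt"


@dataclass
class DynamicTrainState:
    """Evolving assignment threshold and loss shape of dynamic training."""

    t_now: float = 0.5
    beta_now: float = 1.0
    k_i_quantile: float = 0.75         # records the K_I-th largest IoU
    k_beta: int = 10                   # records the K_β-th smallest error
    update_interval: int = 100
    t_clamp: tuple[float, float] = (0.4, 0.9)
    beta_clamp: tuple[float, float] = (0.02, 1.0)
    iou_record: list[float] = field(default_factory=list)
    error_record: list[float] = field(default_factory=list)
    iterations_seen: int = 0

    def record_iteration(self, proposal_ious: np.ndarray,
                         regression_errors: np.ndarray) -> None:
        """Store this iteration's rank statistics."""
        self.iterations_seen += 1
        ious = np.sort(np.asarray(proposal_ious, dtype=np.float64))[::-1]
        if ious.size:
            k = max(int(round((1.0 - self.k_i_quantile) * ious.size)), 1)
            self.iou_record.append(float(ious[min(k, ious.size) - 1]))
        errs = np.sort(np.asarray(regression_errors, dtype=np.float64))
        if errs.size:
            self.error_record.append(float(errs[min(self.k_beta, errs.size) - 1]))

    def at_boundary(self) -> bool:
        return self.iterations_seen > 0 and \
            self.iterations_seen % self.update_interval == 0


def update_dynamic_state(state: DynamicTrainState) -> DynamicTrainState:
    """Apply the periodic update: T_now ← mean of recorded IoU statistics,
    β_now ← median of recorded error statistics; records are cleared."""
    if not state.iou_record and not state.error_record:
        warnings.warn("dynamic update with empty records; state unchanged")
        return state
    if state.iou_record:
        state.t_now = float(np.clip(np.mean(state.iou_record), *state.t_clamp))
    if state.error_record:
        state.beta_now = float(np.clip(np.median(state.error_record),
                                       *state.beta_clamp))
    state.iou_record = []
    state.error_record = []
    return state


def assign_training_labels(proposals: np.ndarray, gt_boxes: np.ndarray,
                           state: DynamicTrainState) -> np.ndarray:
    """1 where max IoU against any ground truth ≥ T_now (ties positive), else 0."""
    proposals = np.atleast_2d(np.asarray(proposals, dtype=np.float64))
    if gt_boxes is None or np.size(gt_boxes) == 0:
        return np.zeros(proposals.shape[0], dtype=np.int64)
    max_iou = B.iou_matrix(proposals, gt_boxes).max(axis=1)
    return (max_iou >= state.t_now).astype(np.int64)


def smooth_l1(x, beta: float):
    """Piecewise loss 0.5|x|²/β for |x|<β, |x|−0.5β otherwise (elementwise)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if isinstance(x, Tensor):
        a = x.abs()
        return where(a.numpy() < beta, a * a * (0.5 / beta), a - 0.5 * beta)
    a = np.abs(np.asarray(x, dtype=np.float64))
    out = np.where(a < beta, 0.5 * a * a / beta, a - 0.5 * beta)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def generate_level_anchors(h: int, w: int, stride: int,
                           cfg: AnchorConfig) -> np.ndarray:
    """All anchors of one pyramid level, shape (h·w·A, 4), row-major."""
    side = cfg.scale_factor * stride
    shapes = []
    for r in cfg.ratios:
        aw = side / np.sqrt(r)
        ah = side * np.sqrt(r)
        shapes.append((aw, ah))
    cy, cx = np.meshgrid((np.arange(h) + 0.5) * stride,
                         (np.arange(w) + 0.5) * stride, indexing="ij")
    out = np.empty((h, w, len(shapes), 4))
    for a, (aw, ah) in enumerate(shapes):
        out[:, :, a, 0] = cx - aw / 2
        out[:, :, a, 1] = cy - ah / 2
        out[:, :, a, 2] = cx + aw / 2
        out[:, :, a, 3] = cy + ah / 2
    return out.reshape(-1, 4)


# ---------------------------------------------------------------------------
# RoI Align
# ---------------------------------------------------------------------------

def roi_align_pool(level_map: Tensor | FeatureMap, box: np.ndarray,
                   output_size: int, sampling_points: int = 2) -> Tensor:
    """RoI-Align a single box (level coordinates) to output_size²×c."""
    fm = level_map.values if isinstance(level_map, FeatureMap) else level_map
    pooled = roi_align_batch(fm, np.asarray(box, dtype=np.float64)[None],
                             output_size, sampling_points)
    return pooled[0]


def roi_align_batch(fm: Tensor, rois: np.ndarray, output_size: int,
                    sampling_points: int = 2) -> Tensor:
    """RoI-Align N boxes on one (h, w, c) map → (N, out, out, c).

    Boxes are in the level's coordinate frame.  Each output bin averages a
    ``sampling_points``² grid of bilinear samples; feature pixel (r, c) has
    its center at continuous coordinate (r+0.5, c+0.5).
    """
    h, w, c = fm.shape
    rois = np.atleast_2d(np.asarray(rois, dtype=np.float64))
    if np.any((rois[:, 2] - rois[:, 0]) <= 0) or np.any((rois[:, 3] - rois[:, 1]) <= 0):
        raise ValueError("degenerate (zero-area) box passed to RoI-Align")
    n = rois.shape[0]
    P = output_size * sampling_points

    def axis_samples(lo, hi, size):
        step = (hi - lo) / P                       # (n,)
        pts = lo[:, None] + (np.arange(P) + 0.5) * step[:, None]   # (n, P)
        u = np.clip(pts - 0.5, 0.0, size - 1.0)
        i0 = np.floor(u).astype(np.int64)
        i1 = np.minimum(i0 + 1, size - 1)
        frac = u - i0
        return i0, i1, frac

    y0, y1, fy = axis_samples(rois[:, 1], rois[:, 3], h)
    x0, x1, fx = axis_samples(rois[:, 0], rois[:, 2], w)

    iy0, iy1 = y0[:, :, None], y1[:, :, None]      # (n, P, 1)
    ix0, ix1 = x0[:, None, :], x1[:, None, :]      # (n, 1, P)
    wy0, wy1 = (1 - fy)[:, :, None, None], fy[:, :, None, None]
    wx0, wx1 = (1 - fx)[:, None, :, None], fx[:, None, :, None]

    def gather(iy, ix):
        yy = np.broadcast_to(iy, (n, P, P))
        xx = np.broadcast_to(ix, (n, P, P))
        return fm[(yy, xx)]                        # (n, P, P, c)

    val = (gather(iy0, ix0) * (wy0 * wx0) + gather(iy0, ix1) * (wy0 * wx1)
           + gather(iy1, ix0) * (wy1 * wx0) + gather(iy1, ix1) * (wy1 * wx1))
    s = sampling_points
    val = val.reshape(n, output_size, s, output_size, s, c)
    return val.mean(axis=(2, 4))


# ---------------------------------------------------------------------------
# network heads
# ---------------------------------------------------------------------------

def conv3x3(x: Tensor, lin: Linear) -> Tensor:
    """3×3 same-padding convolution expressed as shift-concat + linear."""
    h, w, c = x.shape
    xp = x.pad(((1, 1), (1, 1), (0, 0)))
    shifts = [xp[di:di + h, dj:dj + w, :] for di in range(3) for dj in range(3)]
    return lin(concat(shifts, axis=-1))


class RPNHead(Module):
    """Shared proposal head: 3×3 conv + ReLU, then 1×1 objectness/delta maps."""

    def __init__(self, in_channels: int, anchors_per_pos: int,
                 rng: np.random.Generator):
        self.hidden = Linear(9 * in_channels, in_channels, rng)
        self.cls = Linear(in_channels, anchors_per_pos, rng, scale=1e-2)
        self.reg = Linear(in_channels, 4 * anchors_per_pos, rng, scale=1e-2)
        self.A = anchors_per_pos

    def forward(self, fm: Tensor) -> tuple[Tensor, Tensor]:
        h, w, _ = fm.shape
        hid = conv3x3(fm, self.hidden).relu()
        logits = self.cls(hid).reshape(h * w * self.A)
        deltas = self.reg(hid).reshape(h * w * self.A, 4)
        return logits, deltas


class RoIHead(Module):
    """Two-FC head over pooled RoI features → class logits + box deltas."""

    def __init__(self, in_channels: int, cfg: RoIConfig, rng: np.random.Generator):
        flat = cfg.output_size * cfg.output_size * in_channels
        self.fc1 = Linear(flat, cfg.fc_dim, rng)
        self.fc2 = Linear(cfg.fc_dim, cfg.fc_dim, rng)
        self.cls = Linear(cfg.fc_dim, 2, rng, scale=1e-2)     # background, sdt
        self.reg = Linear(cfg.fc_dim, 4, rng, scale=1e-2)

    def forward(self, pooled: Tensor) -> tuple[Tensor, Tensor]:
        n = pooled.shape[0]
        x = pooled.reshape(n, -1) if pooled.ndim > 2 else pooled
        x = self.fc2(self.fc1(x).relu()).relu()
        return self.cls(x), self.reg(x)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    swin: SwinConfig = field(default_factory=SwinConfig)
    neck_channels: int = 256
    anchors: AnchorConfig = field(default_factory=AnchorConfig)
    roi: RoIConfig = field(default_factory=RoIConfig)
    rpn_pre_nms: int = 2000
    rpn_post_nms_train: int = 1000
    rpn_post_nms_test: int = 300
    rpn_nms_thr: float = 0.7
    roi_batch_size: int = 256
    roi_pos_fraction: float = 0.25     # 1:3 positive:negative sampling
    rpn_batch_size: int = 128
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    score_thr: float = 0.05
    nms_thr: float = 0.5
    seed: int = 0

    @classmethod
    def tiny_test(cls, seed: int = 0) -> "ModelConfig":
        return cls(swin=SwinConfig.tiny_test(seed=seed), neck_channels=32,
                   roi=RoIConfig(fc_dim=128, canonical_size=32.0),
                   rpn_pre_nms=600, rpn_post_nms_train=200, rpn_post_nms_test=100,
                   roi_batch_size=64, rpn_batch_size=64, seed=seed)


class SnagDetector(Module):
    """Backbone → balanced pyramid → RPN → RoI head, end to end."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = SwinBackbone(config.swin)
        self.neck = PyramidNeck(config.swin, out_channels=config.neck_channels,
                                seed=config.seed + 1)
        self.rpn = RPNHead(config.neck_channels,
                           config.anchors.anchors_per_position, rng)
        self.roi_head = RoIHead(config.neck_channels, config.roi, rng)

    # -- shared forward pieces --------------------------------------------
    @staticmethod
    def normalize(image: np.ndarray) -> np.ndarray:
        return (np.asarray(image, dtype=np.float64) / 255.0 - IMG_MEAN) / IMG_STD

    def pyramid(self, image: np.ndarray) -> dict[str, FeatureMap]:
        U = self.backbone(self.normalize(image))
        return self.neck(U)

    def _rpn_all_levels(self, P: dict[str, FeatureMap]):
        logits, deltas, anchors, tags = [], [], [], []
        for i in range(4):
            fm = P[f"P{i + 1}"]
            lg, dl = self.rpn(fm.values)
            h, w, _ = fm.shape
            anc = generate_level_anchors(h, w, fm.stride, self.config.anchors)
            logits.append(lg)
            deltas.append(dl)
            anchors.append(anc)
            tags += [f"P{i + 1}"] * len(anc)
        return concat(logits), concat(deltas), np.concatenate(anchors), np.array(tags)

    def generate_proposals(self, P: dict[str, FeatureMap],
                           image_hw: tuple[int, int],
                           training: bool = False) -> list[Proposal]:
        """Decoded, clipped, NMS-filtered region proposals (no gradients)."""
        logits, deltas, anchors, tags = self._rpn_all_levels(P)
        scores = 1.0 / (1.0 + np.exp(-logits.numpy()))
        boxes = B.decode_boxes(deltas.numpy(), anchors)
        boxes = B.clip_boxes(boxes, *image_hw)
        valid = B.box_area(boxes) > 1.0
        boxes, scores, tags = boxes[valid], scores[valid], tags[valid]
        order = np.argsort(-scores, kind="stable")[: self.config.rpn_pre_nms]
        boxes, scores, tags = boxes[order], scores[order], tags[order]
        keep = B.nms(boxes, scores, self.config.rpn_nms_thr)
        post = (self.config.rpn_post_nms_train if training
                else self.config.rpn_post_nms_test)
        keep = keep[:post]
        return [Proposal(box=boxes[k], objectness=float(scores[k]), level=tags[k])
                for k in keep]

    def _assign_roi_levels(self, rois: np.ndarray) -> np.ndarray:
        """Area-based pyramid-level index (0..3) for each RoI."""
        size = np.sqrt(np.clip(B.box_area(rois), 1e-6, None))
        lvl = np.floor(2 + np.log2(size / self.config.roi.canonical_size))
        return np.clip(lvl, 0, 3).astype(np.int64)

    def pool_rois(self, P: dict[str, FeatureMap], rois: np.ndarray) -> Tensor:
        """RoI-Align each box on its assigned level; (N, out, out, D)."""
        from .nn import stack as _stack
        levels = self._assign_roi_levels(rois)
        cfg = self.config.roi
        pooled: list = [None] * len(rois)
        for li in range(4):
            sel = np.nonzero(levels == li)[0]
            if sel.size == 0:
                continue
            fm = P[f"P{li + 1}"]
            scaled = rois[sel] / fm.stride
            patch = roi_align_batch(fm.values, scaled, cfg.output_size,
                                    cfg.sampling_points)
            for j, idx in enumerate(sel):
                pooled[idx] = patch[j]
        return _stack(pooled, axis=0)

    # -- training losses ----------------------------------------------------
    def _rpn_loss(self, logits: Tensor, deltas: Tensor, anchors: np.ndarray,
                  gt: np.ndarray, rng: np.random.Generator):
        cfg = self.config
        n_anchor = anchors.shape[0]
        labels = np.full(n_anchor, -1, dtype=np.int64)   # -1 = ignore
        if gt.size:
            iou = B.iou_matrix(anchors, gt)
            max_iou = iou.max(axis=1)
            labels[max_iou < cfg.rpn_neg_iou] = 0
            labels[max_iou >= cfg.rpn_pos_iou] = 1
            labels[iou.argmax(axis=0)] = 1               # best anchor per GT
            argmax_gt = iou.argmax(axis=1)
        else:
            labels[:] = 0
        pos = np.nonzero(labels == 1)[0]
        neg = np.nonzero(labels == 0)[0]
        n_pos = min(len(pos), cfg.rpn_batch_size // 2)
        pos = rng.choice(pos, n_pos, replace=False) if len(pos) > n_pos else pos
        n_neg = min(len(neg), cfg.rpn_batch_size - len(pos))
        neg = rng.choice(neg, n_neg, replace=False)
        sel = np.concatenate([pos, neg])
        target = (labels[sel] == 1).astype(np.float64)
        x = logits[sel]
        cls_loss = (x.relu() - x * Tensor(target)
                    + ((-x.abs()).exp() + 1.0).log()).mean()
        if len(pos):
            t = B.encode_boxes(gt[argmax_gt[pos]], anchors[pos])
            reg_loss = smooth_l1(deltas[pos] - Tensor(t), 1.0).sum() \
                * (1.0 / max(len(sel), 1))
        else:
            reg_loss = Tensor(0.0)
        return cls_loss, reg_loss

    def _roi_loss(self, P: dict[str, FeatureMap], proposals: list[Proposal],
                  gt: np.ndarray, state: DynamicTrainState,
                  rng: np.random.Generator, record_stats: bool = True):
        cfg = self.config
        rois = np.array([p.box for p in proposals]).reshape(-1, 4)
        if gt.size:
            rois = np.concatenate([rois, gt]) if rois.size else gt.copy()
        labels = assign_training_labels(rois, gt, state)
        # dynamic-training statistics, recorded every iteration
        if not record_stats:
            pass
        elif gt.size and rois.size:
            max_iou = B.iou_matrix(rois, gt).max(axis=1)
            match = B.iou_matrix(rois, gt).argmax(axis=1)
            t_all = B.encode_boxes(gt[match], rois)
            center_err = np.abs(t_all[:, :2]).mean(axis=1)
            state.record_iteration(max_iou, center_err[labels == 1])
        else:
            state.record_iteration(np.array([]), np.array([]))
        pos = np.nonzero(labels == 1)[0]
        neg = np.nonzero(labels == 0)[0]
        n_pos = min(len(pos), int(cfg.roi_batch_size * cfg.roi_pos_fraction))
        pos = rng.choice(pos, n_pos, replace=False) if len(pos) > n_pos else pos
        n_neg = min(len(neg), cfg.roi_batch_size - len(pos))
        neg = rng.choice(neg, n_neg, replace=False) if len(neg) > n_neg else neg
        sel = np.concatenate([pos, neg]).astype(np.int64)
        if sel.size == 0:
            return Tensor(0.0), Tensor(0.0)
        pooled = self.pool_rois(P, rois[sel])
        cls_logits, reg = self.roi_head(pooled)
        target = (labels[sel] == 1).astype(np.int64)
        logp = cls_logits.log_softmax(axis=-1)
        cls_loss = -(logp[np.arange(len(sel)), target]).mean()
        if len(pos):
            match = B.iou_matrix(rois[pos], gt).argmax(axis=1)
            t = B.encode_boxes(gt[match], rois[pos])
            reg_loss = smooth_l1(reg[: len(pos)] - Tensor(t),
                                 state.beta_now).sum() * (1.0 / len(sel))
        else:
            reg_loss = Tensor(0.0)
        return cls_loss, reg_loss

    def training_losses(self, image: np.ndarray, gt_boxes: np.ndarray,
                        state: DynamicTrainState, rng: np.random.Generator,
                        record_stats: bool = True) -> dict[str, Tensor]:
        """All four loss terms for one image."""
        gt = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
        P = self.pyramid(image)
        logits, deltas, anchors, _ = self._rpn_all_levels(P)
        rpn_cls, rpn_reg = self._rpn_loss(logits, deltas, anchors, gt, rng)
        proposals = self.generate_proposals(P, image.shape[:2], training=True)
        roi_cls, roi_reg = self._roi_loss(P, proposals, gt, state, rng,
                                          record_stats=record_stats)
        return {"rpn_cls": rpn_cls, "rpn_reg": rpn_reg,
                "roi_cls": roi_cls, "roi_reg": roi_reg}

    # -- inference -----------------------------------------------------------
    def detect(self, image: np.ndarray, score_thr: float | None = None,
               nms_thr: float | None = None, max_det: int = 100) -> list[Detection]:
        score_thr = self.config.score_thr if score_thr is None else score_thr
        nms_thr = self.config.nms_thr if nms_thr is None else nms_thr
        h, w = image.shape[:2]
        P = self.pyramid(image)
        proposals = self.generate_proposals(P, (h, w), training=False)
        if not proposals:
            return []
        rois = np.array([p.box for p in proposals])
        pooled = self.pool_rois(P, rois)
        cls_logits, reg = self.roi_head(pooled)
        probs = cls_logits.softmax(axis=-1).numpy()[:, 1]
        boxes = B.decode_boxes(reg.numpy(), rois)
        boxes = B.clip_boxes(boxes, h, w)
        ok = (probs >= score_thr) & (B.box_area(boxes) > 0)
        boxes, probs = boxes[ok], probs[ok]
        if len(boxes) == 0:
            return []
        keep = B.nms(boxes, probs, nms_thr)[:max_det]
        return [Detection(box=boxes[k], score=float(probs[k])) for k in keep]
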