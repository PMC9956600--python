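"""Training loop: AdamW, linear LR decay, early stopping, dynamic updates.

The loss is the sum of four terms — RPN objectness, RPN box regression,
RoI classification and RoI box regression — where the RoI regression uses
the dynamically updated Smooth-L1 transition β_now and RoI label assignment
uses the dynamically updated IoU threshold T_now.  Defaults follow the
reported setup: AdamW, initial learning rate 1e-4, batch size 4, linearly
decayed over 100 epochs, early stop when the validation loss has not
improved for 20 epochs.  Batches are processed by gradient accumulation
over single images, so runs are reproducible in single-threaded mode.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .detector import (DynamicTrainState, ModelConfig, SnagDetector,
                       update_dynamic_state)
from .nn import AdamW, linear_decay

Sample = tuple[np.ndarray, np.ndarray]  # (H×W×3 image, (N,4) gt boxes)


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 4
    epochs: int = 100
    patience: int = 20
    weight_decay: float = 1e-4
    grad_clip: float = 10.0
    lr_floor_fraction: float = 0.01    # final LR as a fraction of initial
    seed: int = 0
    dynamic_update_interval: int = 100
    dynamic_k_i_quantile: float = 0.75
    dynamic_k_beta: int = 10


@dataclass
class TrainResult:
    log: list[dict] = field(default_factory=list)
    state: DynamicTrainState = field(default_factory=DynamicTrainState)
    best_val_loss: float = float("inf")
    stopped_early: bool = False
    epochs_run: int = 0


def _total(losses) -> float:
    return float(sum(v.numpy() for v in losses.values()))


def validation_loss(model: SnagDetector, val_set: list[Sample],
                    state: DynamicTrainState, seed: int = 0) -> float:
    """Mean total loss over a validation set (no recording, no updates)."""
    rng = np.random.default_rng(seed)
    vals = []
    for image, gt in val_set:
        losses = model.training_losses(image, gt, state, rng, record_stats=False)
        vals.append(_total(losses))
    return float(np.mean(vals)) if vals else float("nan")


def train(model: SnagDetector, train_set: list[Sample],
          val_set: list[Sample] | None, config: TrainConfig,
          log_path: str | Path | None = None,
          callback=None) -> TrainResult:
    """Train in place; returns the dynamic state and a per-iteration log."""
    if not train_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.parameters(), lr=config.lr,
                weight_decay=config.weight_decay)
    state = DynamicTrainState(update_interval=config.dynamic_update_interval,
                              k_i_quantile=config.dynamic_k_i_quantile,
                              k_beta=config.dynamic_k_beta)
    result = TrainResult(state=state)
    iters_per_epoch = max(len(train_set) // config.batch_size, 1)
    total_steps = config.epochs * iters_per_epoch
    log_file = open(log_path, "a") if log_path else None
    bad_epochs = 0
    step = 0
    try:
        for epoch in range(config.epochs):
            order = rng.permutation(len(train_set))
            for it in range(iters_per_epoch):
                idx = order[it * config.batch_size:(it + 1) * config.batch_size]
                if idx.size == 0:
                    continue
                opt.lr = linear_decay(config.lr, step, total_steps,
                                      floor=config.lr * config.lr_floor_fraction)
                opt.zero_grad()
                terms = {"rpn_cls": 0.0, "rpn_reg": 0.0,
                         "roi_cls": 0.0, "roi_reg": 0.0}
                for i in idx:
                    image, gt = train_set[i]
                    losses = model.training_losses(image, gt, state, rng)
                    batch_loss = None
                    for name, v in losses.items():
                        terms[name] += float(v.numpy()) / idx.size
                        batch_loss = v if batch_loss is None else batch_loss + v
                    (batch_loss * (1.0 / idx.size)).backward()
                opt.step(grad_clip=config.grad_clip)
                step += 1
                if state.at_boundary():
                    update_dynamic_state(state)
                entry = {"epoch": epoch, "iteration": step, "lr": opt.lr,
                         "t_now": state.t_now, "beta_now": state.beta_now,
                         "loss": sum(terms.values()), **terms,
                         "time": time.time()}
                result.log.append(entry)
                if log_file:
                    log_file.write(json.dumps(entry) + "\n")
            result.epochs_run = epoch + 1
            if val_set:
                vl = validation_loss(model, val_set, state, seed=config.seed)
                result.log[-1]["val_loss"] = vl
                if vl < result.best_val_loss - 1e-6:
                    result.best_val_loss = vl
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                if bad_epochs >= config.patience:
                    result.stopped_early = True
                    break
            if callback is not None and callback(epoch, result) is False:
                break
    finally:
        if log_file:
            log_file.close()
    return result


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | Path, model: SnagDetector,
                    state: DynamicTrainState | None = None,
                    extra: dict | None = None) -> None:
    """Single-file archive: version tag, config snapshot, parameters, state."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "model_config": asdict(model.config),
        "dynamic_state": {"t_now": state.t_now, "beta_now": state.beta_now,
                          "iterations_seen": state.iterations_seen}
        if state else None,
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[SnagDetector, DynamicTrainState, dict]:
    from .backbone import SwinConfig
    from .detector import AnchorConfig, RoIConfig

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        mc = dict(meta["model_config"])
        mc["swin"] = SwinConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in mc["swin"].items()})
        mc["anchors"] = AnchorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in mc["anchors"].items()})
        mc["roi"] = RoIConfig(**mc["roi"])
        model = SnagDetector(ModelConfig(**mc))
        model.load_state_dict(
            {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")})
    ds = meta.get("dynamic_state") or {}
    state = DynamicTrainState(t_now=ds.get("t_now", 0.5),
                              beta_now=ds.get("beta_now", 1.0),
                              iterations_seen=ds.get("iterations_seen", 0))
    return model, state, meta.get("extra", {})
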