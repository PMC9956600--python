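"""Run configuration: schema-validated YAML with dotted-path overrides.

One master seed fans out deterministically to the per-module seeds (data
splitting, scene synthesis, weight initialisation, training sampling).
Unknown keys anywhere in the document are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .backbone import SwinConfig
from .detector import AnchorConfig, ModelConfig, RoIConfig
from .synth import SceneConfig
from .training import TrainConfig


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataBlock(_Block):
    mosaic_paths: list[str] = Field(default_factory=list)
    image_dir: str | None = None
    labelme_dir: str | None = None
    tile_size: int = 512
    augment_ops: list[Literal["hflip", "vflip", "rot90k"]] = \
        Field(default_factory=lambda: ["hflip", "vflip", "rot90k"])
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)


class SynthBlock(_Block):
    image_size: int = 512
    n_scenes: int = 20
    n_dead: tuple[int, int] = (1, 3)
    n_live: tuple[int, int] = (10, 22)
    crown_radius_small: tuple[float, float] = (4.0, 8.0)
    crown_radius_large: tuple[float, float] = (52.0, 68.0)
    small_fraction: float = 0.5
    confuser_rate: float = 0.15
    overlap_prob: float = 0.3
    texture_noise: float = 8.0

    def scene_config(self, seed: int) -> SceneConfig:
        return SceneConfig(
            image_size=self.image_size, n_dead=self.n_dead, n_live=self.n_live,
            crown_radius_small=self.crown_radius_small,
            crown_radius_large=self.crown_radius_large,
            small_fraction=self.small_fraction,
            confuser_rate=self.confuser_rate, overlap_prob=self.overlap_prob,
            texture_noise=self.texture_noise, seed=seed)


class ModelBlock(_Block):
    profile: Literal["full", "tiny"] = "full"
    patch_size: int = 4
    base_channels: int = 96
    depths: tuple[int, int, int, int] = (2, 2, 6, 2)
    window_size: int = 7
    heads: tuple[int, int, int, int] = (3, 6, 12, 24)
    mlp_ratio: float = 4.0
    neck_channels: int = 256
    anchor_scale: float = 8.0
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    roi_output_size: int = 7
    roi_fc_dim: int = 1024
    score_thr: float = 0.05
    nms_thr: float = 0.5

    def model_config_obj(self, seed: int) -> ModelConfig:
        if self.profile == "tiny":
            return ModelConfig.tiny_test(seed=seed)
        return ModelConfig(
            swin=SwinConfig(patch_size=self.patch_size,
                            base_channels=self.base_channels,
                            depths=self.depths, window_size=self.window_size,
                            heads=self.heads, mlp_ratio=self.mlp_ratio,
                            seed=seed),
            neck_channels=self.neck_channels,
            anchors=AnchorConfig(scale_factor=self.anchor_scale,
                                 ratios=self.anchor_ratios),
            roi=RoIConfig(output_size=self.roi_output_size,
                          fc_dim=self.roi_fc_dim),
            score_thr=self.score_thr, nms_thr=self.nms_thr, seed=seed)


class TrainBlock(_Block):
    lr: float = 1e-4
    batch_size: int = 4
    epochs: int = 100
    patience: int = 20
    weight_decay: float = 1e-4
    grad_clip: float = 10.0
    dynamic_update_interval: int = 100
    dynamic_k_i_quantile: float = 0.75
    dynamic_k_beta: int = 10

    def train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(lr=self.lr, batch_size=self.batch_size,
                           epochs=self.epochs, patience=self.patience,
                           weight_decay=self.weight_decay,
                           grad_clip=self.grad_clip, seed=seed,
                           dynamic_update_interval=self.dynamic_update_interval,
                           dynamic_k_i_quantile=self.dynamic_k_i_quantile,
                           dynamic_k_beta=self.dynamic_k_beta)


class EvalBlock(_Block):
    iou_thr: float = 0.5
    interpolation: Literal["coco101", "allpoint"] = "coco101"
    score_thr: float | None = None     # None: maximise F1 along the sweep


class RunConfig(_Block):
    seed: int = 0
    out_dir: str = "runs"
    data: DataBlock = Field(default_factory=DataBlock)
    synth: SynthBlock = Field(default_factory=SynthBlock)
    model: ModelBlock = Field(default_factory=ModelBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    eval: EvalBlock = Field(default_factory=EvalBlock)

    def module_seed(self, name: str) -> int:
        """Deterministic per-module seed derived from the master seed."""
        import zlib
        ss = np.random.SeedSequence([self.seed, zlib.crc32(name.encode())])
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def _set_dotted(tree: dict, dotted: str, value):
    keys = dotted.split(".")
    node = tree
    for k in keys[:-1]:
        node = node.setdefault(k, {})
    node[keys[-1]] = yaml.safe_load(value) if isinstance(value, str) else value


def load_config(path: str | Path | None = None,
                overrides: list[str] | None = None) -> RunConfig:
    """Load YAML config, apply ``key.path=value`` overrides, validate."""
    tree: dict = {}
    if path is not None:
        tree = yaml.safe_load(Path(path).read_text()) or {}
    for ov in overrides or []:
        if "=" not in ov:
            raise ValueError(f"override {ov!r} is not of the form key=value")
        key, val = ov.split("=", 1)
        _set_dotted(tree, key.strip(), val.strip())
    return RunConfig.model_validate(tree)
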