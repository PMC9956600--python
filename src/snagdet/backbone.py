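"""Hierarchical shifted-window transformer backbone.

The feature extractor partitions the input image into 4×4 patches, embeds
them linearly, and processes tokens through four stages of windowed
multi-head self-attention blocks with depths (2, 2, 6, 2) by default.  A
patch-merging step (ST-M) between stages halves resolution and doubles
channels, so the four stage outputs U1..U4 have shapes

    H/4×W/4×C,  H/8×W/8×2C,  H/16×W/16×4C,  H/32×W/32×8C.

Attention alternates between regular window partitioning (W-MSA) and a
cyclically shifted partitioning (SW-MSA) that lets information cross window
boundaries; shifted windows use an additive mask so tokens only attend to
tokens that were contiguous before the shift.  A learned relative-position
bias table of (2M−1)² entries per head is added to every attention logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import LayerNorm, Linear, Mlp, Module, Parameter, Tensor

NEG_INF = -1e9


@dataclass(frozen=True)
class SwinConfig:
    """Backbone hyperparameters.

    ``base_channels`` is the embedding width C of stage 1; stage i uses
    2^(i-1)·C channels.  ``window_size`` M is the side of the attention
    window in tokens.  Per-head dimension is ``channels / heads``.
    """

    patch_size: int = 4
    base_channels: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    window_size: int = 7
    heads: tuple[int, ...] = (3, 6, 12, 24)
    mlp_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if len(self.depths) != 4 or len(self.heads) != 4:
            raise ValueError("expect 4 stages")
        for i, h in enumerate(self.heads):
            if (self.base_channels * 2**i) % h:
                raise ValueError(f"stage {i} channels not divisible by {h} heads")

    @property
    def stage_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**i for i in range(4))

    @classmethod
    def tiny_test(cls, seed: int = 0) -> "SwinConfig":
        """A CPU-sized profile for tests and desk experiments."""
        return cls(base_channels=24, depths=(1, 1, 2, 1), window_size=4,
                   heads=(1, 2, 4, 8), mlp_ratio=2.0, seed=seed)


@dataclass
class FeatureMap:
    """A rank-3 (h × w × c) feature array with stride/stage provenance."""

    values: Tensor
    stride: int
    stage_tag: str = "intermediate"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def numpy(self) -> np.ndarray:
        return self.values.numpy()


# ---------------------------------------------------------------------------
# patch-level operators
# ---------------------------------------------------------------------------

def patch_partition(image: np.ndarray, patch_size: int = 4) -> FeatureMap:
    """Split an H×W×3 image into non-overlapping patches of flattened pixels.

    Output is (H/p) × (W/p) × (3p²); for p=4 each token is 48-dimensional.
    The image is zero-padded to a multiple of ``patch_size`` if needed.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("patch_partition expects an H×W×3 image")
    H, W, _ = image.shape
    p = patch_size
    ph, pw = (-H) % p, (-W) % p
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)))
        H, W = image.shape[:2]
    tok = image.reshape(H // p, p, W // p, p, 3)
    tok = tok.transpose(0, 2, 1, 3, 4).reshape(H // p, W // p, p * p * 3)
    return FeatureMap(Tensor(tok), stride=p, stage_tag="intermediate")


class PatchEmbed(Module):
    """Linear embedding of raw patch vectors to C channels, then LayerNorm."""

    def __init__(self, patch_size: int, out_channels: int, rng: np.random.Generator):
        self.patch_size = patch_size
        self.proj = Linear(patch_size * patch_size * 3, out_channels, rng)
        self.norm = LayerNorm(out_channels)

    def forward(self, image: np.ndarray) -> FeatureMap:
        fm = patch_partition(image, self.patch_size)
        return FeatureMap(self.norm(self.proj(fm.values)), stride=self.patch_size)


class PatchMerge(Module):
    """ST-M: gather 2×2 token neighbourhoods → LayerNorm → linear 4c→2c.

    Halves resolution, doubles channels.  Odd inputs are zero-padded.
    """

    def __init__(self, in_channels: int, rng: np.random.Generator):
        self.norm = LayerNorm(4 * in_channels)
        self.reduce = Linear(4 * in_channels, 2 * in_channels, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        h, w, c = x.shape
        if h % 2 or w % 2:
            x = x.pad(((0, h % 2), (0, w % 2), (0, 0)))
            h, w, c = x.shape
        # order: (row 0 col 0, row 1 col 0, row 0 col 1, row 1 col 1) per Swin
        x = x.reshape(h // 2, 2, w // 2, 2, c).transpose(0, 2, 3, 1, 4)
        x = x.reshape(h // 2, w // 2, 4 * c)
        return self.reduce(self.norm(x))


class PatchExpand(Module):
    """ST-P: linear c→2c, then rearrange channels into a 2×2 spatial block.

    Doubles resolution; output channels are 2c/4 = c/2.  The 2c vector is
    read as (2 rows × 2 cols × c/2 channels), row-major.
    """

    def __init__(self, in_channels: int, rng: np.random.Generator):
        if in_channels % 2:
            raise ValueError("patch expansion needs an even channel count")
        self.expand = Linear(in_channels, 2 * in_channels, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        h, w, c = x.shape
        y = self.expand(x)                                     # (h, w, 2c)
        y = y.reshape(h, w, 2, 2, c // 2).transpose(0, 2, 1, 3, 4)
        return y.reshape(2 * h, 2 * w, c // 2)


# ---------------------------------------------------------------------------
# window attention
# ---------------------------------------------------------------------------

def _relative_index(M: int) -> np.ndarray:
    """(M², M²) table of flattened relative-coordinate indices in [0, (2M−1)²)."""
    coords = np.stack(np.meshgrid(np.arange(M), np.arange(M), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]          # (2, M², M²)
    rel = rel + (M - 1)                                # shift to [0, 2M-2]
    return rel[0] * (2 * M - 1) + rel[1]


def window_partition(x: Tensor, M: int) -> Tensor:
    """(h, w, c) → (num_windows, M², c), windows in row-major order."""
    h, w, c = x.shape
    x = x.reshape(h // M, M, w // M, M, c).transpose(0, 2, 1, 3, 4)
    return x.reshape((h // M) * (w // M), M * M, c)


def window_reverse(x: Tensor, M: int, h: int, w: int) -> Tensor:
    c = x.shape[-1]
    x = x.reshape(h // M, w // M, M, M, c).transpose(0, 2, 1, 3, 4)
    return x.reshape(h, w, c)


def shift_attention_mask(h: int, w: int, M: int, shift: int,
                         valid: np.ndarray | None = None) -> np.ndarray | None:
    """Additive mask (num_windows, M², M²) for cyclic-shift attention.

    Tokens may attend to each other only if they belonged to the same
    contiguous image region before the cyclic shift (and both are real,
    non-padding tokens when ``valid`` is given).  Entries are 0 (allowed)
    or a large negative number (forbidden).
    """
    if shift == 0 and valid is None:
        return None
    region = np.zeros((h, w), dtype=np.int64)
    if shift > 0:
        h_slices = (slice(0, h - M), slice(h - M, h - shift), slice(h - shift, h))
        w_slices = (slice(0, w - M), slice(w - M, w - shift), slice(w - shift, w))
        cnt = 0
        for hs in h_slices:
            for ws in w_slices:
                region[hs, ws] = cnt
                cnt += 1
    if valid is not None:
        region = np.where(valid, region, -1 - np.arange(h * w).reshape(h, w))
    region = np.roll(region, (-shift, -shift), axis=(0, 1)) if shift else region
    win = region.reshape(h // M, M, w // M, M).transpose(0, 2, 1, 3)
    win = win.reshape(-1, M * M)
    diff = win[:, :, None] != win[:, None, :]
    mask = np.where(diff, NEG_INF, 0.0)
    return mask


class WindowAttention(Module):
    """Multi-head self-attention inside M×M windows with relative bias."""

    def __init__(self, dim: int, heads: int, M: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must divide evenly into heads")
        self.dim, self.heads, self.M = dim, heads, M
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.rel_bias = Parameter(rng.normal(0.0, 0.02, size=((2 * M - 1) ** 2, heads)))
        self._rel_index = _relative_index(M)

    def forward(self, windows: Tensor, mask: np.ndarray | None = None) -> Tensor:
        nw, n, c = windows.shape
        H, d = self.heads, self.dim // self.heads
        qkv = self.qkv(windows).reshape(nw, n, 3, H, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]                   # (nw, H, n, d)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        bias = self.rel_bias[self._rel_index.reshape(-1)]  # (n², H)
        bias = bias.reshape(n, n, H).transpose(2, 0, 1)    # (H, n, n)
        logits = logits + bias
        if mask is not None:
            logits = logits + mask[:, None, :, :]
        attn = logits.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(nw, n, c)
        return self.proj(out)


class SwinBlock(Module):
    """One transformer block: (S)W-MSA with residual, then MLP with residual.

    ``shift`` > 0 selects the shifted-window variant.  Inputs whose spatial
    size is not a multiple of M are zero-padded with masked attention for
    the pad tokens and cropped back afterwards.
    """

    def __init__(self, dim: int, heads: int, M: int, mlp_ratio: float,
                 rng: np.random.Generator, shift: int = 0):
        self.M, self.shift = M, shift
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, M, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        self._mask_cache: dict[tuple, np.ndarray | None] = {}

    def _attention(self, x: Tensor) -> Tensor:
        h, w, c = x.shape
        M = self.M
        shift = self.shift if min(h, w) > M else 0  # one window => no shift
        ph, pw = (-h) % M, (-w) % M
        valid = None
        if ph or pw:
            x = x.pad(((0, ph), (0, pw), (0, 0)))
            valid = np.zeros((h + ph, w + pw), dtype=bool)
            valid[:h, :w] = True
        hp, wp = h + ph, w + pw
        key = (hp, wp, shift, ph, pw)
        if key not in self._mask_cache:
            self._mask_cache[key] = shift_attention_mask(hp, wp, M, shift, valid)
        mask = self._mask_cache[key]
        if shift:
            x = x.roll((-shift, -shift), (0, 1))
        wins = window_partition(x, M)
        wins = self.attn(wins, mask)
        x = window_reverse(wins, M, hp, wp)
        if shift:
            x = x.roll((shift, shift), (0, 1))
        if ph or pw:
            x = x[:h, :w, :]
        return x

    def forward(self, x: Tensor) -> Tensor:
        x = x + self._attention(self.norm1(x))
        x = x + self.mlp(self.norm2(x))
        return x


# ---------------------------------------------------------------------------
# full backbone
# ---------------------------------------------------------------------------

class SwinBackbone(Module):
    """Four-stage backbone producing the feature hierarchy U1..U4."""

    def __init__(self, config: SwinConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        C = config.base_channels
        self.embed = PatchEmbed(config.patch_size, C, rng)
        self.stages: list[list[SwinBlock]] = []
        self.merges: list[PatchMerge] = []
        for i, depth in enumerate(config.depths):
            dim = C * 2**i
            blocks = [
                SwinBlock(dim, config.heads[i], config.window_size,
                          config.mlp_ratio, rng,
                          shift=0 if b % 2 == 0 else config.window_size // 2)
                for b in range(depth)
            ]
            self.stages.append(blocks)
            if i < 3:
                self.merges.append(PatchMerge(dim, rng))

    def forward(self, image: np.ndarray) -> dict[str, FeatureMap]:
        fm = self.embed(image)
        x = fm.values
        outputs: dict[str, FeatureMap] = {}
        stride = self.config.patch_size
        for i, blocks in enumerate(self.stages):
            for blk in blocks:
                x = blk(x)
            outputs[f"U{i + 1}"] = FeatureMap(x, stride=stride, stage_tag=f"U{i + 1}")
            if i < 3:
                x = self.merges[i](x)
                stride *= 2
        return outputs


def wmsa_cost(h: int, w: int, C: int, M: int) -> int:
    """Closed-form operation count of windowed attention: 4hwC² + 2M²hwC."""
    return 4 * h * w * C * C + 2 * M * M * h * w * C
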