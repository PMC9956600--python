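"""Top-down feature pyramid and balanced feature enhancement.

From the backbone hierarchy U1..U4 a top-down pyramid S1..S4 is built:
S4 is U4 processed by a transformer block; each lower level fuses a
laterally processed U_i with the patch-expanded (upsampled, channel-halved)
level above it, and the sum is processed by another block.  All levels are
then projected to a common channel width D.

The balance-enhancement module has two parts.  The integration step resizes
every level to the S2 resolution (bilinear interpolation upward, max-pool
downward) and averages them, C = (1/L) Σ_l C_l.  The refinement step applies
an embedded-Gaussian non-local block — attention over *all* spatial
positions with similarity exp(θ(x_i)ᵀφ(x_j)), softmax-normalised — with a
residual connection.  The refined map is resized back to every level and
added, producing P1..P4 for the detection head.
"""

from __future__ import annotations

import numpy as np

from .backbone import FeatureMap, PatchExpand, SwinBlock, SwinConfig
from .nn import Linear, Module, Tensor

STRIDES = (4, 8, 16, 32)


# ---------------------------------------------------------------------------
# resizing primitives (fixed conventions so hand oracles are reproducible)
# ---------------------------------------------------------------------------

def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix with half-pixel (non-aligned) centers."""
    W = np.zeros((n_out, n_in))
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    W[np.arange(n_out), lo] += 1 - frac
    W[np.arange(n_out), hi] += frac
    return W


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of an (h, w, c) map, half-pixel-center convention."""
    h, w, c = x.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        return x
    Wh = Tensor(_bilinear_matrix(oh, h))
    Ww = Tensor(_bilinear_matrix(ow, w))
    y = (Wh @ x.reshape(h, w * c)).reshape(oh, w, c)
    y = y.transpose(1, 0, 2).reshape(w, oh * c)
    y = (Ww @ y).reshape(ow, oh, c).transpose(1, 0, 2)
    return y


def maxpool_down(x: Tensor, factor: int) -> Tensor:
    """Max pooling with kernel = stride = ``factor`` (integer downscale)."""
    h, w, c = x.shape
    if h % factor or w % factor:
        raise ValueError("maxpool_down needs dims divisible by the factor")
    y = x.reshape(h // factor, factor, w // factor, factor, c)
    return y.max(axis=3).max(axis=1)


def resize_to(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Resize policy of the balance module: max-pool down, bilinear up."""
    h, w, _ = x.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        return x
    if oh <= h and ow <= w and h % oh == 0 and w % ow == 0 and h // oh == w // ow:
        return maxpool_down(x, h // oh)
    return bilinear_resize(x, out_hw)


# ---------------------------------------------------------------------------
# non-local refinement
# ---------------------------------------------------------------------------

class NonLocalBlock(Module):
    """Embedded-Gaussian non-local attention with residual output.

    y_i = (1/C(x)) Σ_j exp(θ(x_i)ᵀφ(x_j)) · g(x_j), with C(x) the softmax
    normaliser; the output projection maps back to D channels and is added
    to the input.  Embeddings reduce channels D → D/2.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        inner = max(dim // 2, 1)
        self.theta = Linear(dim, inner, rng, bias=False)
        self.phi = Linear(dim, inner, rng, bias=False)
        self.g = Linear(dim, inner, rng, bias=False)
        self.out = Linear(inner, dim, rng, bias=False, scale=1e-3)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Row-stochastic (N, N) weight matrix over all spatial positions."""
        h, w, c = x.shape
        flat = x.reshape(h * w, c)
        logits = self.theta(flat) @ self.phi(flat).transpose(1, 0)
        return logits.softmax(axis=-1).numpy()

    def forward(self, x: Tensor) -> Tensor:
        h, w, c = x.shape
        flat = x.reshape(h * w, c)
        logits = self.theta(flat) @ self.phi(flat).transpose(1, 0)   # (N, N)
        weights = logits.softmax(axis=-1)
        y = weights @ self.g(flat)                                   # (N, D/2)
        return x + self.out(y).reshape(h, w, c)


# ---------------------------------------------------------------------------
# the neck
# ---------------------------------------------------------------------------

class PyramidNeck(Module):
    """U1..U4 → S1..S4 → (balance-enhance) → P1..P4.

    ``reference_level`` names the resolution at which the levels are
    averaged (S2, stride 8).  ``out_channels`` D is the common width of the
    projected levels and of P1..P4.
    """

    def __init__(self, config: SwinConfig, out_channels: int = 256,
                 reference_level: str = "S2", expand_blocks: int = 2,
                 lateral_blocks: int = 1, seed: int = 1):
        rng = np.random.default_rng(seed)
        self.config = config
        self.D = out_channels
        self.reference_level = reference_level
        ch = config.stage_channels                  # (C, 2C, 4C, 8C)
        M, ratio = config.window_size, config.mlp_ratio

        def blocks(dim, n):
            return [SwinBlock(dim, max(dim // 32, 1), M, ratio, rng)
                    for _ in range(n)]

        self.top_block = blocks(ch[3], 1)           # U4 → S4 path
        self.lateral = [blocks(ch[i], lateral_blocks) for i in range(3)]
        self.expand = [PatchExpand(ch[i + 1], rng) for i in range(3)]
        self.expand_pre = [blocks(ch[i + 1], expand_blocks - 1) for i in range(3)]
        self.fuse = [blocks(ch[i], 1) for i in range(3)]
        self.project = [Linear(ch[i], out_channels, rng) for i in range(4)]
        self.nonlocal_block = NonLocalBlock(out_channels, rng)

    # -- stage 1: top-down pyramid ----------------------------------------
    def build_topdown_pyramid(self, U: dict[str, FeatureMap]) -> dict[str, FeatureMap]:
        for i, tag in enumerate(("U1", "U2", "U3", "U4")):
            if tag not in U:
                raise KeyError(f"missing backbone level {tag}")
            if U[tag].stride != STRIDES[i]:
                raise ValueError(f"level {tag} has stride {U[tag].stride}, "
                                 f"expected {STRIDES[i]}")
        raw: dict[int, Tensor] = {}
        x = U["U4"].values
        for blk in self.top_block:
            x = blk(x)
        raw[3] = x
        for i in (2, 1, 0):
            lat = U[f"U{i + 1}"].values
            for blk in self.lateral[i]:
                lat = blk(lat)
            top = raw[i + 1]
            for blk in self.expand_pre[i]:
                top = blk(top)
            top = self.expand[i](top)
            if top.shape != lat.shape:
                raise ValueError(
                    f"S{i + 1}: lateral {lat.shape} vs top-down {top.shape}")
            fused = lat + top
            for blk in self.fuse[i]:
                fused = blk(fused)
            raw[i] = fused
        S = {}
        for i in range(4):
            proj = self.project[i](raw[i])
            S[f"S{i + 1}"] = FeatureMap(proj, stride=STRIDES[i], stage_tag=f"S{i + 1}")
        return S

    # -- stage 2: balanced integration (resize-and-average) ---------------
    def balance_integrate(self, S: dict[str, FeatureMap]) -> FeatureMap:
        tags = sorted(S)
        if len(tags) != 4:
            raise ValueError(f"balance integration expects 4 levels, got {len(tags)}")
        ref = S[self.reference_level]
        oh, ow, _ = ref.shape
        resized = [resize_to(S[t].values, (oh, ow)) for t in tags]
        total = resized[0]
        for r in resized[1:]:
            total = total + r
        return FeatureMap(total * (1.0 / len(resized)), stride=ref.stride,
                          stage_tag="balanced")

    # -- stage 3: non-local refinement -------------------------------------
    def nonlocal_refine(self, balanced: FeatureMap) -> FeatureMap:
        refined = self.nonlocal_block(balanced.values)
        return FeatureMap(refined, stride=balanced.stride, stage_tag="refined")

    # -- stage 4: redistribute to all levels --------------------------------
    def redistribute(self, refined: FeatureMap,
                     S: dict[str, FeatureMap]) -> dict[str, FeatureMap]:
        P = {}
        for i in range(4):
            tag = f"S{i + 1}"
            lvl = S[tag]
            h, w, _ = lvl.shape
            add = resize_to(refined.values, (h, w))
            P[f"P{i + 1}"] = FeatureMap(lvl.values + add, stride=lvl.stride,
                                        stage_tag=f"P{i + 1}")
        return P

    def forward(self, U: dict[str, FeatureMap]) -> dict[str, FeatureMap]:
        S = self.build_topdown_pyramid(U)
        balanced = self.balance_integrate(S)
        refined = self.nonlocal_refine(balanced)
        return self.redistribute(refined, S)
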