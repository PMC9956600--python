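"""Synthetic UAV-like forest scenes with ground-truth dead-tree boxes.

Each scene is a textured green canopy viewed from above.  Live crowns are
unions of jittered green disks; standing dead crowns are rendered in a
gray-brown palette as sparse unions of disks plus radial branch strokes
(the defoliated-crown look), drawn last so their annotation boxes are the
tight axis-aligned envelopes of the visible dead-crown pixels.  Confuser
objects — discolored live crowns and bare-soil patches — are rendered but
never annotated, emulating the main sources of detection error in real
imagery.

Scenes are deterministic in the configured seed; per-scene seeds of a
dataset are spawned from the master seed via ``np.random.SeedSequence`` so
datasets are reproducible without global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .imagery import BoxAnnotation, Tile, coco_from_tiles, write_image

SMALL_AREA = 32 * 32        # box area below => small target
LARGE_AREA = 96 * 96        # box area above => large target


@dataclass(frozen=True)
class SceneConfig:
    """Generation parameters; defaults emulate 512×512 survey tiles with
    roughly one to three dead trees per tile, matching the sparse incidence
    of standing dead trees in the source imagery."""

    image_size: int = 512
    n_dead: int | tuple[int, int] = (1, 3)
    n_live: int | tuple[int, int] = (10, 22)
    crown_radius_small: tuple[float, float] = (4.0, 8.0)
    crown_radius_large: tuple[float, float] = (52.0, 68.0)
    small_fraction: float = 0.5
    dead_color_mean: tuple[float, float, float] = (150.0, 132.0, 108.0)
    dead_color_std: float = 10.0
    live_color_mean: tuple[float, float, float] = (46.0, 98.0, 42.0)
    live_color_std: float = 12.0
    confuser_rate: float = 0.15
    overlap_prob: float = 0.3
    texture_noise: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for name in ("small_fraction", "confuser_rate", "overlap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for rr in (self.crown_radius_small, self.crown_radius_large):
            if rr[0] <= 0 or rr[1] < rr[0]:
                raise ValueError("crown radius ranges must be positive and ordered")
            if rr[1] >= self.image_size / 2:
                raise ValueError("crown radius exceeds image size")


@dataclass
class SyntheticScene:
    tile: Tile
    annotations: list[BoxAnnotation]
    size_classes: list[str] = field(default_factory=list)
    dead_masks: list[np.ndarray] = field(default_factory=list)  # visible support

    @property
    def boxes(self) -> np.ndarray:
        return np.asarray([a.box for a in self.annotations],
                          dtype=np.float64).reshape(-1, 4)


def size_class_of(area: float) -> str:
    if area < SMALL_AREA:
        return "small"
    if area > LARGE_AREA:
        return "large"
    return "medium"


def _sample_count(spec, rng) -> int:
    if isinstance(spec, (tuple, list)):
        return int(rng.integers(spec[0], spec[1] + 1))
    return int(spec)


def _crown_mask(size: int, cx: float, cy: float, radius: float,
                rng: np.random.Generator, sparse: bool) -> np.ndarray:
    """Irregular crown support: 3–7 jittered disks, plus radial branch
    strokes for the sparse (dead) morphology."""
    mask = np.zeros((size, size), dtype=bool)
    n_disks = int(rng.integers(3, 8))
    for _ in range(n_disks):
        jr = radius * (0.45 if sparse else 0.6) * rng.uniform(0.5, 1.0)
        jx = cx + rng.normal(0, radius * 0.25)
        jy = cy + rng.normal(0, radius * 0.25)
        rr, cc = draw_disk((jy, jx), max(jr, 1.0), shape=mask.shape)
        mask[rr, cc] = True
    if sparse:
        n_branch = int(rng.integers(4, 9))
        for _ in range(n_branch):
            ang = rng.uniform(0, 2 * np.pi)
            ln = radius * rng.uniform(0.7, 1.0)
            y2 = int(np.clip(cy + ln * np.sin(ang), 0, size - 1))
            x2 = int(np.clip(cx + ln * np.cos(ang), 0, size - 1))
            rr, cc = draw_line(int(np.clip(cy, 0, size - 1)),
                               int(np.clip(cx, 0, size - 1)), y2, x2)
            mask[rr, cc] = True
            if radius > 6:      # thicken long branches by one pixel
                rr2 = np.clip(rr + 1, 0, size - 1)
                mask[rr2, cc] = True
    return mask


def _paint(image: np.ndarray, mask: np.ndarray, mean, std,
           rng: np.random.Generator) -> None:
    n = int(mask.sum())
    if n == 0:
        return
    shade = rng.normal(0, std, size=(n, 1))
    per_px = rng.normal(0, std * 0.4, size=(n, 3))
    image[mask] = np.asarray(mean) + shade + per_px


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one scene; deterministic in ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    size = config.image_size

    # textured canopy background: smooth illumination + fine noise
    base = np.asarray(config.live_color_mean) * 0.85
    smooth = gaussian_filter(rng.normal(0, 1, (size, size)), sigma=size / 16)
    smooth = smooth / (np.abs(smooth).max() + 1e-9)
    fine = rng.normal(0, 1, (size, size))
    tex = smooth * 2.5 * config.texture_noise + fine * config.texture_noise * 0.5
    image = base[None, None, :] + tex[:, :, None] * np.array([0.8, 1.0, 0.7])

    # live crowns, some discolored (confusers)
    n_live = _sample_count(config.n_live, rng)
    centers: list[tuple[float, float]] = []
    for _ in range(n_live):
        cx, cy = rng.uniform(0, size, 2)
        r = rng.uniform(6, max(size / 12, 8))
        mask = _crown_mask(size, cx, cy, r, rng, sparse=False)
        if rng.random() < config.confuser_rate:
            _paint(image, mask, (138.0, 122.0, 66.0), config.live_color_std, rng)
        else:
            _paint(image, mask, config.live_color_mean, config.live_color_std, rng)
        centers.append((cx, cy))

    # bare-soil patches (unannotated confusers)
    if rng.random() < config.confuser_rate:
        for _ in range(int(rng.integers(1, 3))):
            cx, cy = rng.uniform(0, size, 2)
            rr, cc = draw_disk((cy, cx), rng.uniform(size / 20, size / 10),
                               shape=(size, size))
            soil = np.zeros((size, size), dtype=bool)
            soil[rr, cc] = True
            _paint(image, soil, (172.0, 152.0, 120.0), 8.0, rng)

    # dead crowns, drawn last so annotations are tight on visible support
    n_dead = _sample_count(config.n_dead, rng)
    annotations: list[BoxAnnotation] = []
    classes: list[str] = []
    dead_masks: list[np.ndarray] = []
    for k in range(n_dead):
        rr_range = (config.crown_radius_small
                    if rng.random() < config.small_fraction
                    else config.crown_radius_large)
        radius = rng.uniform(*rr_range)
        margin = radius + 2
        if centers and rng.random() < config.overlap_prob:
            bx, by = centers[int(rng.integers(len(centers)))]
            cx = np.clip(bx + rng.normal(0, radius), margin, size - margin)
            cy = np.clip(by + rng.normal(0, radius), margin, size - margin)
        else:
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
        mask = _crown_mask(size, cx, cy, radius, rng, sparse=True)
        _paint(image, mask, config.dead_color_mean, config.dead_color_std, rng)
        dead_masks.append(mask)
        centers.append((cx, cy))

    tile = Tile(pixels=np.clip(image, 0, 255).astype(np.uint8),
                tile_id=f"scene_{config.seed}", source_id="synthetic")

    # boxes from the final visible dead support (later crowns may overlap)
    visible = np.zeros((size, size), dtype=np.int64) - 1
    for k, m in enumerate(dead_masks):
        visible[m] = k
    supports: list[np.ndarray] = []
    for k in range(n_dead):
        ys, xs = np.nonzero(visible == k)
        if ys.size == 0:
            continue
        box = (float(xs.min()), float(ys.min()),
               float(xs.max() + 1), float(ys.max() + 1))
        ann = BoxAnnotation(box=box, tile_id=tile.tile_id)
        annotations.append(ann)
        classes.append(size_class_of(ann.area))
        supports.append(visible == k)
    return SyntheticScene(tile=tile, annotations=annotations,
                          size_classes=classes, dead_masks=supports)


def scene_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-scene seeds spawned from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def generate_scenes(config: SceneConfig, n_scenes: int,
                    master_seed: int | None = None) -> list[SyntheticScene]:
    seeds = scene_seeds(config.seed if master_seed is None else master_seed,
                        n_scenes)
    return [generate_scene(replace(config, seed=s)) for s in seeds]


def generate_dataset(config: SceneConfig, n_scenes: int,
                     out_dir: str | Path) -> dict:
    """Write ``n_scenes`` PNG tiles plus one COCO JSON; returns a summary
    with the realized small/medium/large annotation counts."""
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenes = generate_scenes(config, n_scenes)
    tiles, anns, classes = [], [], []
    for i, sc in enumerate(scenes):
        sc.tile.tile_id = f"scene_{i:05d}"
        for a in sc.annotations:
            a.tile_id = sc.tile.tile_id
        tiles.append(sc.tile)
        anns.extend(sc.annotations)
        classes.extend(sc.size_classes)
        write_image(out / f"{sc.tile.tile_id}.png", sc.tile.pixels)
    doc = coco_from_tiles(tiles, anns)
    (out / "annotations.json").write_text(json.dumps(doc, indent=1))
    summary = {
        "n_images": len(tiles),
        "n_annotations": len(anns),
        "size_counts": {c: classes.count(c) for c in ("small", "medium", "large")},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return {"summary": summary, "coco": doc}


def scenes_as_samples(scenes: list[SyntheticScene]) -> list[tuple[np.ndarray, np.ndarray]]:
    """(image, gt boxes) pairs for the trainer."""
    return [(sc.tile.pixels, sc.boxes) for sc in scenes]


def easy_profile(image_size: int = 128, seed: int = 0) -> SceneConfig:
    """High-contrast, confuser-free scenes for desk-scale end-to-end runs."""
    return SceneConfig(
        image_size=image_size,
        n_dead=(1, 2),
        n_live=(4, 8),
        crown_radius_small=(6.0, 9.0),
        crown_radius_large=(14.0, 20.0),
        small_fraction=0.25,
        dead_color_mean=(205.0, 185.0, 150.0),
        dead_color_std=6.0,
        confuser_rate=0.0,
        overlap_prob=0.0,
        texture_noise=5.0,
        seed=seed,
    )
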