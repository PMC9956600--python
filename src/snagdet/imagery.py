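"""Imagery and annotation I/O: tiling, conversion, augmentation, splitting.

Coordinate convention used throughout the package: boxes are
(x_min, y_min, x_max, y_max), 0-based, half-open, in pixel units.  COCO
files use the standard (x, y, width, height) bbox encoding.

The pipeline mirrors a UAV survey workflow: a stitched orthomosaic is
cropped into fixed-size tiles (512×512 by default) whose center coordinates
are preserved; Labelme-style polygon/rectangle annotations are converted to
a single-category COCO document; training data is expanded with
geometry-preserving augmentation (horizontal/vertical flips and k·90°
rotations with exact box remaps); tiles are split 70/10/20 into
train/val/test with augmented copies following their source tile and the
test split left unaugmented.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "Tile", "BoxAnnotation", "DatasetManifest",
    "tile_orthomosaic", "read_mosaic", "read_image", "write_image",
    "convert_labelme_to_coco", "augment_dataset", "split_dataset",
    "summarize_manifest", "write_coco", "read_coco",
    "write_manifest", "read_manifest",
]

AUG_OPS = ("hflip", "vflip", "rot90k")


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class Tile:
    """A square RGB crop with provenance."""

    pixels: np.ndarray                 # (size, size, 3) uint8
    tile_id: str
    source_id: str = ""
    center_coord: tuple[float, float] | None = None  # (x, y) mosaic px or lon/lat

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        h, w = self.pixels.shape[:2]
        if h != w:
            raise ValueError(f"tile {self.tile_id}: height {h} != width {w}")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"tile {self.tile_id}: expected 3 channels")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class BoxAnnotation:
    """One axis-aligned standing-dead-tree box on a tile."""

    box: tuple[float, float, float, float]
    tile_id: str
    category: str = "sdt"

    def validate(self, tile_size: int) -> None:
        x1, y1, x2, y2 = self.box
        if not (0 <= x1 < x2 <= tile_size and 0 <= y1 < y2 <= tile_size):
            raise ValueError(f"invalid box {self.box} on tile {self.tile_id}")

    @property
    def area(self) -> float:
        x1, y1, x2, y2 = self.box
        return (x2 - x1) * (y2 - y1)


@dataclass
class DatasetManifest:
    per_site_image_counts: list[int] = field(default_factory=list)
    per_site_label_counts: list[int] = field(default_factory=list)
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    split_assignment: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if any(c < 0 for c in self.per_site_image_counts + self.per_site_label_counts):
            raise ValueError("negative count in manifest")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def summarize_manifest(manifest: DatasetManifest) -> tuple[int, int]:
    """Total (images, labels) across sites; exact sums of per-site counts."""
    manifest.validate()
    return (int(sum(manifest.per_site_image_counts)),
            int(sum(manifest.per_site_label_counts)))


# ---------------------------------------------------------------------------
# mosaics and tiling
# ---------------------------------------------------------------------------

def read_mosaic(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an orthomosaic (GeoTIFF/TIFF or plain raster image).

    Returns (pixels, geotransform-or-None).  The geotransform, when the
    TIFF carries ModelPixelScale + ModelTiepoint tags, is the affine
    (x0, dx, 0, y0, 0, -dy) mapping pixel to world coordinates.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            page = tf.pages[0]
            tags = {t.name: t.value for t in page.tags.values()}
        gt = None
        if "ModelPixelScaleTag" in tags and "ModelTiepointTag" in tags:
            sx, sy = tags["ModelPixelScaleTag"][:2]
            tie = tags["ModelTiepointTag"]
            px, py, _, gx, gy, _ = tie[:6]
            gt = np.array([gx - px * sx, sx, 0.0, gy + py * sy, 0.0, -sy])
        return arr, gt
    return np.asarray(Image.open(path).convert("RGB")), None


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def tile_orthomosaic(mosaic: np.ndarray, tile_size: int = 512,
                     source_id: str = "mosaic",
                     geotransform: np.ndarray | None = None) -> list[Tile]:
    """Cut the largest tileable region into a non-overlapping grid of tiles.

    Residual margins smaller than one tile are dropped.  Each tile records
    the center pixel coordinate of its crop in mosaic coordinates (or in
    world coordinates when a geotransform is supplied).
    """
    if tile_size < 32:
        raise ValueError("tile_size must be >= 32")
    mosaic = np.asarray(mosaic)
    if mosaic.ndim == 2:
        mosaic = np.repeat(mosaic[:, :, None], 3, axis=2)
    if mosaic.shape[2] > 3:
        mosaic = mosaic[:, :, :3]
    H, W = mosaic.shape[:2]
    ny, nx = H // tile_size, W // tile_size
    if ny == 0 or nx == 0:
        warnings.warn(f"mosaic {H}×{W} smaller than one {tile_size}px tile")
        return []
    tiles = []
    for iy in range(ny):
        for ix in range(nx):
            y0, x0 = iy * tile_size, ix * tile_size
            cx = x0 + tile_size / 2
            cy = y0 + tile_size / 2
            if geotransform is not None:
                g = geotransform
                cx, cy = g[0] + g[1] * cx + g[2] * cy, g[3] + g[4] * cx + g[5] * cy
            tiles.append(Tile(
                pixels=mosaic[y0:y0 + tile_size, x0:x0 + tile_size].copy(),
                tile_id=f"{source_id}_r{iy}_c{ix}",
                source_id=source_id,
                center_coord=(float(cx), float(cy)),
            ))
    return tiles


def stitch_tiles(tiles: list[Tile], ny: int, nx: int) -> np.ndarray:
    """Reassemble a row-major tile grid (inverse of tiling's covered region)."""
    size = tiles[0].size
    out = np.zeros((ny * size, nx * size, 3), dtype=tiles[0].pixels.dtype)
    for k, t in enumerate(tiles):
        iy, ix = divmod(k, nx)
        out[iy * size:(iy + 1) * size, ix * size:(ix + 1) * size] = t.pixels
    return out


# ---------------------------------------------------------------------------
# Labelme → COCO
# ---------------------------------------------------------------------------

def convert_labelme_to_coco(labelme_records: list[dict],
                            category: str = "sdt") -> tuple[dict, list[dict]]:
    """Convert Labelme-style records to one single-category COCO document.

    Each record needs ``imagePath`` (or ``image_path``), ``imageHeight``,
    ``imageWidth`` and a ``shapes`` list of dicts with ``points``; the COCO
    bbox is the min/max envelope of the points.  Shapes with fewer than two
    points are rejected and reported in the returned error list.
    """
    images, annotations, errors = [], [], []
    ann_id = 1
    for img_id, rec in enumerate(labelme_records, start=1):
        path = rec.get("imagePath") or rec.get("image_path") or f"image_{img_id}"
        images.append({
            "id": img_id, "file_name": str(path),
            "height": int(rec.get("imageHeight", 0)),
            "width": int(rec.get("imageWidth", 0)),
        })
        for shape in rec.get("shapes", []):
            pts = np.asarray(shape.get("points", []), dtype=np.float64)
            if pts.ndim != 2 or pts.shape[0] < 2:
                errors.append({"image_id": img_id,
                               "reason": "shape with <2 points",
                               "shape": shape.get("label", "?")})
                continue
            x1, y1 = pts.min(axis=0)
            x2, y2 = pts.max(axis=0)
            annotations.append({
                "id": ann_id, "image_id": img_id, "category_id": 1,
                "bbox": [float(x1), float(y1), float(x2 - x1), float(y2 - y1)],
                "area": float((x2 - x1) * (y2 - y1)),
                "iscrowd": 0,
            })
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": category}],
    }
    return doc, errors


def write_coco(path: str | Path, doc: dict) -> None:
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def coco_from_tiles(tiles: list[Tile],
                    annotations: list[BoxAnnotation]) -> dict:
    """Build a COCO document (xyxy boxes → xywh bboxes) from in-memory data."""
    images = [{"id": i + 1, "file_name": f"{t.tile_id}.png",
               "height": t.size, "width": t.size, "tile_id": t.tile_id}
              for i, t in enumerate(tiles)]
    id_of = {t.tile_id: i + 1 for i, t in enumerate(tiles)}
    anns = []
    for k, a in enumerate(annotations, start=1):
        x1, y1, x2, y2 = a.box
        anns.append({"id": k, "image_id": id_of[a.tile_id], "category_id": 1,
                     "bbox": [float(x1), float(y1), float(x2 - x1), float(y2 - y1)],
                     "area": float((x2 - x1) * (y2 - y1)), "iscrowd": 0})
    return {"images": images, "annotations": anns,
            "categories": [{"id": 1, "name": "sdt"}]}


def boxes_from_coco(doc: dict) -> dict[int, np.ndarray]:
    """image_id → (N, 4) xyxy boxes."""
    out: dict[int, list] = {img["id"]: [] for img in doc["images"]}
    for a in doc["annotations"]:
        x, y, w, h = a["bbox"]
        out[a["image_id"]].append([x, y, x + w, y + h])
    return {k: np.asarray(v, dtype=np.float64).reshape(-1, 4)
            for k, v in out.items()}


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _remap_box(box, op: str, size: int, k: int = 1):
    x1, y1, x2, y2 = box
    W = H = size
    if op == "hflip":
        return (W - x2, y1, W - x1, y2)
    if op == "vflip":
        return (x1, H - y2, x2, H - y1)
    if op == "rot90k":
        for _ in range(k % 4):
            # 90° clockwise on a square: (x, y) -> (H - y, x)
            x1, y1, x2, y2 = H - y2, x1, H - y1, x2
        return (x1, y1, x2, y2)
    raise ValueError(f"unknown augmentation op {op!r}")


def _transform_pixels(pixels: np.ndarray, op: str, k: int = 1) -> np.ndarray:
    if op == "hflip":
        return pixels[:, ::-1].copy()
    if op == "vflip":
        return pixels[::-1].copy()
    if op == "rot90k":
        return np.rot90(pixels, k=-k).copy()   # negative k = clockwise
    raise ValueError(f"unknown augmentation op {op!r}")


def augment_dataset(tiles: list[Tile], annotations: list[BoxAnnotation],
                    ops: tuple[str, ...] = AUG_OPS, seed: int = 0,
                    ) -> tuple[list[Tile], list[BoxAnnotation]]:
    """Expand a dataset with flips and 90°-multiple rotations.

    Every op in ``ops`` is applied to every tile once (``rot90k`` with a
    seeded random k ∈ {1,2,3}); outputs carry provenance back to the source
    tile in ``source_id`` and an op suffix on ``tile_id``.  Box remaps are
    exact reflections/rotations of the half-open pixel boxes.
    """
    for op in ops:
        if op not in AUG_OPS:
            raise ValueError(f"unknown augmentation op {op!r}; valid: {AUG_OPS}")
    rng = np.random.default_rng(seed)
    by_tile: dict[str, list[BoxAnnotation]] = {}
    for a in annotations:
        by_tile.setdefault(a.tile_id, []).append(a)
    out_tiles = list(tiles)
    out_anns = list(annotations)
    for t in tiles:
        for a in by_tile.get(t.tile_id, []):
            a.validate(t.size)
        for op in ops:
            k = int(rng.integers(1, 4)) if op == "rot90k" else 1
            new_id = f"{t.tile_id}__{op}{k if op == 'rot90k' else ''}"
            out_tiles.append(Tile(pixels=_transform_pixels(t.pixels, op, k),
                                  tile_id=new_id, source_id=t.tile_id,
                                  center_coord=t.center_coord))
            for a in by_tile.get(t.tile_id, []):
                out_anns.append(BoxAnnotation(
                    box=_remap_box(a.box, op, t.size, k),
                    tile_id=new_id, category=a.category))
    return out_tiles, out_anns


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(tile_ids: list[str],
                  fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                  seed: int = 0,
                  sources: dict[str, str] | None = None) -> dict[str, str]:
    """Assign tiles to train/val/test deterministically.

    Train and val get floor(n·f) tiles each and test receives the
    remainder, so counts always sum to n (568 source tiles at 70/10/20
    yield 397/56/115).  When
    ``sources`` maps augmented tile ids to their source tile id, augmented
    copies follow their source's split — except that augmented copies of
    test-split tiles are assigned to train, keeping the test split
    augmentation-free.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    sources = sources or {}
    roots = [t for t in tile_ids if t not in sources]
    rng = np.random.default_rng(seed)
    n = len(roots)
    if n < 3:
        warnings.warn("fewer tiles than splits; assigning all to train")
        assignment = {t: "train" for t in roots}
    else:
        n_train = int(n * fractions[0])
        n_val = int(n * fractions[1])
        n_test = n - n_train - n_val      # remainder lands in test
        order = rng.permutation(n)
        assignment = {}
        for i, idx in enumerate(order):
            if i < n_train:
                assignment[roots[idx]] = "train"
            elif i < n_train + n_val:
                assignment[roots[idx]] = "val"
            else:
                assignment[roots[idx]] = "test"
    for t in tile_ids:
        if t in sources:
            src_split = assignment.get(sources[t], "train")
            assignment[t] = "train" if src_split == "test" else src_split
    return assignment


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    manifest.validate()
    Path(path).write_text(yaml.safe_dump({
        "per_site_image_counts": list(map(int, manifest.per_site_image_counts)),
        "per_site_label_counts": list(map(int, manifest.per_site_label_counts)),
        "split_fractions": list(map(float, manifest.split_fractions)),
        "split_assignment": dict(manifest.split_assignment),
    }))


def read_manifest(path: str | Path) -> DatasetManifest:
    data = yaml.safe_load(Path(path).read_text())
    m = DatasetManifest(
        per_site_image_counts=list(data.get("per_site_image_counts", [])),
        per_site_label_counts=list(data.get("per_site_label_counts", [])),
        split_fractions=tuple(data.get("split_fractions", (0.7, 0.1, 0.2))),
        split_assignment=dict(data.get("split_assignment", {})),
    )
    m.validate()
    return m
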