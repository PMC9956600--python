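"""Tile a mosaic into 512-px crops, augment, and split 70/10/20.

Mimics the survey data pipeline: non-overlapping tiles with preserved
center coordinates, flip/rotation augmentation with exact box remaps, and a
deterministic train/val/test split in which augmented copies follow their
source tile and the test split stays unaugmented.
"""

import numpy as np

from snagdet.imagery import (BoxAnnotation, augment_dataset, split_dataset,
                             summarize_manifest, tile_orthomosaic,
                             DatasetManifest)

mosaic = (np.random.default_rng(0).random((1536, 2048, 3)) * 255).astype(np.uint8)
tiles = tile_orthomosaic(mosaic, tile_size=512, source_id="siteA")
print(f"{len(tiles)} tiles; first centers:",
      [t.center_coord for t in tiles[:3]])

annotations = [BoxAnnotation((100, 50, 200, 150), tiles[0].tile_id)]
aug_tiles, aug_anns = augment_dataset(tiles, annotations,
                                      ops=("hflip", "vflip", "rot90k"), seed=1)
print(f"after augmentation: {len(aug_tiles)} tiles, {len(aug_anns)} boxes")
print("hflip remap of (100,50,200,150) on width 512:", aug_anns[1].box)

sources = {t.tile_id: t.source_id for t in aug_tiles
           if t.source_id in {u.tile_id for u in aug_tiles}}
assignment = split_dataset([t.tile_id for t in aug_tiles], seed=2,
                           sources=sources)
counts = {s: list(assignment.values()).count(s) for s in ("train", "val", "test")}
print("split counts:", counts, "(augmented copies excluded from test)")

manifest = DatasetManifest(per_site_image_counts=[76, 104, 47, 341],
                           per_site_label_counts=[131, 179, 81, 587])
print("survey-style manifest totals (images, labels):",
      summarize_manifest(manifest))
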