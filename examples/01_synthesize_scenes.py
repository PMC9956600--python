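"""Generate a small synthetic forest dataset and summarise it.

Builds 6 UAV-like canopy tiles with annotated standing-dead-tree (SDT)
crowns plus unannotated confusers, writes PNGs + COCO JSON, and prints the
realized size-class counts (small < 32² px², large > 96² px² box area).
"""

from pathlib import Path

from snagdet.synth import SceneConfig, generate_dataset

config = SceneConfig(image_size=256, n_dead=(1, 3), seed=7,
                     crown_radius_large=(30.0, 45.0))
result = generate_dataset(config, n_scenes=6, out_dir=Path("scratch/example_ds"))

print("wrote", result["summary"]["n_images"], "tiles to scratch/example_ds/")
print("annotations:", result["summary"]["n_annotations"])
print("size classes:", result["summary"]["size_counts"])
print("Each annotation is the tight box around one rendered dead crown;")
print("live crowns and discoloured confusers are drawn but never annotated.")
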