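"""Run the windowed-attention backbone and balanced pyramid on one tile.

Shows the four-stage feature hierarchy U1..U4 (strides 4/8/16/32, channel
law C, 2C, 4C, 8C), the top-down pyramid S1..S4, and the balance-enhanced
detection features P1..P4, plus the closed-form attention cost.
"""

import numpy as np

from snagdet.backbone import SwinBackbone, SwinConfig, wmsa_cost
from snagdet.neck import PyramidNeck
from snagdet.synth import easy_profile, generate_scene

scene = generate_scene(easy_profile(image_size=128, seed=3))
config = SwinConfig.tiny_test(seed=0)          # C=24, depths (1,1,2,1), M=4
backbone = SwinBackbone(config)
U = backbone(scene.tile.pixels / 255.0)
for tag in ("U1", "U2", "U3", "U4"):
    print(tag, "shape", U[tag].shape, "stride", U[tag].stride)

neck = PyramidNeck(config, out_channels=32)
P = neck(U)
for tag in ("P1", "P2", "P3", "P4"):
    print(tag, "shape", P[tag].shape, "stride", P[tag].stride)

h = w = 128 // 4
print(f"windowed-attention cost at stage 1 (h=w={h}, C=24, M=4):",
      wmsa_cost(h, w, 24, 4), "ops — linear in h·w, quadratic in C")
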