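"""Explain a classifier's decision with five CAM techniques + ensemble.

Trains the tiny IRF model, picks a lesion-bearing slice, and compares
each technique's Otsu-binarized heat map against the true lesion mask
(B-scan-level IoU). The ensemble marks pixels where >= 3 of 5 techniques
agree.
"""

import numpy as np

from fluidcam import (
    ModelConfig,
    PhantomSpec,
    build_classifier,
    cam_binary_mask,
    generate_cscan,
    jaccard,
    make_examples,
    train,
)
from fluidcam.phantom import make_classification_slices

images, labels = make_classification_slices(100, 100, "IRF", seed=100)
model = build_classifier(ModelConfig.from_preset("tiny"), seed=0, pathology="IRF")
train(model, make_examples(images, labels), epochs=20, seed=0)

out = generate_cscan(PhantomSpec(lesion_counts={"IRF": 1}, n_slices=8, seed=42))
i = int(np.argmax(out.labels["IRF"]))
sl = out.cscan.slices[i]
print(f"slice {i}: prediction score {model.predict(sl).positive_score:.4f} (gate 0.5)")

for technique in ("gradcam", "gradcampp", "scorecam", "ablationcam",
                  "selfmatching", "ensemble"):
    mask = cam_binary_mask(model, sl, technique, 1)
    iou = jaccard(mask.values, out.masks["IRF"][i])
    print(f"  {technique:12s} IoU vs lesion mask: {iou:.4f}")
# CAM heat maps localize coarsely (IoU well below 1); the post-processing
# stage (example 05) sharpens them into usable fluid masks.
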