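"""Reference confusion-matrix tallies for OCT fluid classification.

Published benchmark counts (TP, FP, TN, FN) of three binary classifier
variants evaluated per pathology on a 52,650-image spectral-domain OCT
test set. They serve as fixed inputs for validating the classification
metric formulas and for the metric-recomputation entry points; the
variants are the model trained on raw speckled images ("noisy"), the
full-size despeckled-input model ("gcds"), and its reduced-depth
counterpart ("small_gcds").
"""

from __future__ import annotations

from .quantify import ConfusionCounts

#: pathology -> variant -> ConfusionCounts
CONFUSION_COUNTS: dict[str, dict[str, ConfusionCounts]] = {
    "IRF": {
        "noisy": ConfusionCounts(tp=8797, fp=2919, tn=40224, fn=710),
        "gcds": ConfusionCounts(tp=8407, fp=2213, tn=40930, fn=1100),
        "small_gcds": ConfusionCounts(tp=8556, fp=2803, tn=40340, fn=951),
    },
    "SRF": {
        "noisy": ConfusionCounts(tp=2182, fp=613, tn=49641, fn=214),
        "gcds": ConfusionCounts(tp=2291, fp=1161, tn=49093, fn=105),
        "small_gcds": ConfusionCounts(tp=2017, fp=365, tn=49889, fn=379),
    },
    "PED": {
        "noisy": ConfusionCounts(tp=2714, fp=2511, tn=46434, fn=991),
        "gcds": ConfusionCounts(tp=2699, fp=2795, tn=46150, fn=1006),
        "small_gcds": ConfusionCounts(tp=2531, fp=1464, tn=47481, fn=1174),
    },
}
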