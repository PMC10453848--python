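"""Fluid volumetry: CAM mask -> refinement -> mm^3, plus responder status.

Runs the oracle-gated pipeline on phantom C-scans (ground-truth labels as
the gate, dilated ground-truth masks standing in for CAM output, the
noise-free render as the denoised input), refines with selective
thresholding, and sums pixel cuboids (11.7 x 47.2 x 2.0 um^3) into mm^3.
"""

import numpy as np
from scipy import ndimage

from fluidcam import PhantomSpec, cohort_summary, cscan_volume, generate_cscan, responder_status

reports = []
for s in range(5):
    out = generate_cscan(
        PhantomSpec(lesion_counts={"IRF": 1}, n_slices=16, seed=300 + s), f"scan{s}"
    )
    dilated = [ndimage.binary_dilation(m, iterations=8) for m in out.masks["IRF"]]
    rep = cscan_volume(
        out.cscan, None, pathology="IRF", postproc_method="selective",
        gate_labels=out.labels["IRF"], cam_masks=dilated,
        intensity_slices=out.clean, gt_masks=out.masks["IRF"],
    )
    reports.append(rep)
    print(f"{rep.scan_id}: predicted {rep.predicted_volume_mm3:.5f} mm^3, "
          f"ground truth {rep.ground_truth_volume_mm3:.5f} mm^3, "
          f"Dice {rep.volumetric_dice:.3f}")

print()
print(cohort_summary(reports).to_string(index=False))

pre, post = reports[0].predicted_volume_mm3, reports[1].predicted_volume_mm3
print(f"\ntreatment response if volume went {pre:.5f} -> {post:.5f} mm^3: "
      f"{responder_status(pre, post)}")
# Predicted volumes within ~20% of ground truth show the refinement +
# voxel arithmetic chain is sound; the 10% rule classifies the change.
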