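"""Expert-annotation preprocessing around a nodule.

Generates a phantom with one nodule, derives the annotation (widest slice
and in-plane centroid) from ground truth, and cuts the 16-slice crops.
"""

import numpy as np

from petlung import NoduleAnnotation, crop_manual, generate_phantom
from petlung.phantom import NoduleSpec, PhantomSpec

spec = PhantomSpec.create(
    "fast",
    seed=2,
    nodules=(
        NoduleSpec(
            center_slice=30, center_row=66.5, center_col=80.5,
            diameter_px=8.0, pet_uptake=6.0,
        ),
    ),
)
study, truth = generate_phantom(spec, label="malignant")

ss, rr, cc = np.nonzero(truth.nodule_mask)
ann = NoduleAnnotation(
    case_id=study.case_id,
    representative_slice=int(ss.mean()),
    center=(float(rr.mean()), float(cc.mean())),
    label="malignant",
)
result = crop_manual(study, ann)

print(f"annotated representative slice : {ann.representative_slice}")
print(f"slice window [start, stop)     : {result.slice_range}")
print(f"CT crop shape                  : {result.ct_crop.shape}")
print(f"PET crop shape (after resize)  : {result.pet_crop_resized.shape}")
print(f"center CT value (nodule, HU)   : {result.ct_crop[8, 32, 32]:.0f}")

# Both crops are 16 x 64 x 64; the crop centers on the nodule, whose soft-
# tissue density (~20 HU) stands out against the lung air around it.
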