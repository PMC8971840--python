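"""Cross-validated training of both architectures on a small cohort.

Runs the automated route end to end — phantoms, localization, two-channel
input assembly, stratified CV — and compares held-out AUCs with the paired
DeLong test. A 20-case, few-epoch run keeps this a coffee-break example;
the acceptance suite does the full 112-case version.
"""

from petlung import (
    LocalizerParams, PredictionSet, delong_test, generate_cohort, roc_auc,
)
from petlung.training import TrainConfig, build_dataset, train_cv

studies, _ = generate_cohort(n_cases=20, malignant_fraction=0.5, seed=11)
config = TrainConfig(epochs=8, folds=4, seed=0)
params = LocalizerParams(crop_width_px=64, num_slices=32, pet_crop_px=16)
X, y, ids = build_dataset(studies, config, localizer_params=params)

pred_sets = {}
for arch in ("hrnet", "resnet"):
    preds = train_cv(X, y, ids, arch=arch, config=config)
    preds.sort(key=lambda p: p.case_id)
    pset = PredictionSet.from_predictions(preds)
    pred_sets[arch] = pset
    roc = roc_auc(pset)
    print(f"{arch:>6}: held-out AUC {roc.auc:.3f} "
          f"[{roc.ci_low:.3f}, {roc.ci_high:.3f}]")

auc_a, auc_b, p = delong_test(pred_sets["hrnet"], pred_sets["resnet"])
print(f"paired DeLong test: AUC diff {auc_a - auc_b:+.3f}, p = {p:.4f}")

# Both networks separate the phantom classes well above chance; the DeLong
# p-value says whether their AUCs differ beyond paired sampling noise.
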