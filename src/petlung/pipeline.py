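"""End-to-end experiment orchestration.

One call chains phantom-cohort generation (or externally supplied studies),
the chosen preprocessing route, cross-validated training of the four model
arms (HRNet / ResNet × PET-CT / CT-only), and the ROC comparison grid: one
AUC with CI per arm plus the paired DeLong test for every arm pair.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .evaluation import PredictionSet, delong_test, roc_auc, threshold_metrics
from .localizer import LocalizerParams
from .manual_roi import NoduleAnnotation
from .phantom import CohortRanges, generate_cohort
from .training import TrainConfig, build_dataset, train_cv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "annotations_from_truth"]

ARMS = [
    ("hrnet", "petct"),
    ("hrnet", "ct"),
    ("resnet", "petct"),
    ("resnet", "ct"),
]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one experiment run."""

    mode: str = "automated"  # or "manual"
    n_cases: int = 112
    malignant_fraction: float = 79 / 112
    profile: str = "fast"
    seed: int = 0
    folds: int = 5
    epochs: int = 15
    batch_size: int = 8
    learning_rate: float = 3e-3
    input_shape: tuple[int, int, int] = (8, 16, 16)
    localizer: LocalizerParams | None = None
    arms: tuple[tuple[str, str], ...] = tuple(ARMS)

    def __post_init__(self):
        if self.mode not in ("automated", "manual"):
            raise ValueError(f"mode must be automated or manual, got {self.mode!r}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def annotations_from_truth(studies, truths) -> dict[str, NoduleAnnotation]:
    """Derive manual annotations from phantom ground truth (the nodule's
    widest slice and in-plane centroid)."""
    anns = {}
    for study, truth in zip(studies, truths):
        mask = truth.nodule_mask
        per_slice = mask.reshape(mask.shape[0], -1).sum(axis=1)
        k = int(per_slice.argmax())
        rr, cc = np.nonzero(mask[k])
        anns[study.case_id] = NoduleAnnotation(
            case_id=study.case_id,
            representative_slice=k,
            center=(float(rr.mean()), float(cc.mean())),
            label=study.label,
        )
    return anns


def _default_fast_localizer() -> LocalizerParams:
    # crop sizes scaled 1/4 to match the fast phantom profile's 128px grid
    return LocalizerParams(crop_width_px=64, num_slices=32, pet_crop_px=16)


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every arm of the comparison and return (optionally write) the report."""
    logger.info("stage: phantom cohort (n=%d, profile=%s)", config.n_cases, config.profile)
    studies, truths = generate_cohort(
        n_cases=config.n_cases,
        malignant_fraction=config.malignant_fraction,
        seed=config.seed,
        profile=config.profile,
    )
    annotations = None
    if config.mode == "manual":
        annotations = annotations_from_truth(studies, truths)

    loc_params = config.localizer
    if loc_params is None:
        loc_params = (
            _default_fast_localizer() if config.profile == "fast" else LocalizerParams()
        )

    report: dict = {
        "config_hash": config.config_hash(),
        "config": {k: str(v) for k, v in asdict(config).items()},
        "arms": {},
        "comparisons": {},
    }
    pred_sets: dict[str, PredictionSet] = {}
    for arch, channels in config.arms:
        arm = f"{arch}-{channels}"
        logger.info("stage: train arm %s", arm)
        tc = TrainConfig(
            folds=config.folds,
            seed=config.seed,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            channels=channels,
            input_shape=config.input_shape,
        )
        X, y, ids = build_dataset(
            studies, tc, mode=config.mode,
            localizer_params=loc_params, annotations=annotations,
        )
        preds = train_cv(X, y, ids, arch=arch, config=tc)
        preds.sort(key=lambda p: p.case_id)
        pset = PredictionSet.from_predictions(preds)
        pred_sets[arm] = pset
        roc = roc_auc(pset)
        sens, spec, acc = threshold_metrics(pset, 0.5)
        report["arms"][arm] = {
            "auc": roc.auc,
            "ci": [roc.ci_low, roc.ci_high],
            "sensitivity": sens,
            "specificity": spec,
            "accuracy": acc,
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
        }
    for (arm_a, arm_b) in itertools.combinations(pred_sets, 2):
        auc_a, auc_b, p = delong_test(pred_sets[arm_a], pred_sets[arm_b])
        report["comparisons"][f"{arm_a} vs {arm_b}"] = {
            "auc_a": auc_a, "auc_b": auc_b, "p": p,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        import pandas as pd

        rows = [
            {"arm": arm, "case_id": cid, "label": int(lab), "score": float(s)}
            for arm, pset in pred_sets.items()
            for cid, lab, s in zip(pset.case_ids, pset.labels, pset.scores)
        ]
        pd.DataFrame(rows).to_csv(out_dir / "predictions.csv", index=False)
    return report
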