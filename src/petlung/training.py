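"""Dataset assembly and (stratified) cross-validated training.

The network input is a two-channel volume: channel 0 the lung-windowed CT
crop, channel 1 the max-normalized PET crop upsampled to the CT grid (a
``ct``-only mode drops channel 1).  Crops from either preprocessing route
(automated localizer or manual annotation) are resampled to a common, small
training resolution so fivefold cross-validation runs at desk scale; the
resolution is a :class:`TrainConfig` field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .localizer import LocalizerParams, extract_lung_volume
from .manual_roi import NoduleAnnotation, crop_manual
from .models import HrnetConfig, ResnetConfig, build_hrnet3d, build_resnet3d
from .nn import Adam, Tensor, softmax
from .nn.autodiff import cross_entropy_logits
from .volumes import StudyPair
from .windowing import LUNG_WINDOW, apply_window, normalize_pet

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "ModelPrediction",
    "prepare_input",
    "build_dataset",
    "train_model",
    "train_cv",
    "training_accuracy",
]

LABEL_TO_INT = {"benign": 0, "malignant": 1}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one cross-validated run."""

    folds: int = 5
    seed: int = 0
    epochs: int = 15
    batch_size: int = 8
    learning_rate: float = 3e-3
    channels: str = "petct"  # or "ct"
    class_weighting: bool = True
    input_shape: tuple[int, int, int] = (8, 16, 16)  # (D, H, W)
    base_channels: int = 8
    blocks_per_stage: int = 1

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.channels not in ("petct", "ct"):
            raise ValueError(f"channels must be petct or ct, got {self.channels!r}")

    @property
    def n_channels(self) -> int:
        return 2 if self.channels == "petct" else 1


@dataclass(frozen=True)
class ModelPrediction:
    """Held-out malignancy score for one case."""

    case_id: str
    score: float
    fold_index: int
    label: int


def _resize_volume(vol: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Resample to ``shape``: exact block averaging when each axis divides
    evenly (the common case here), trilinear interpolation otherwise."""
    if vol.shape == tuple(shape):
        return vol.astype(np.float32)
    if all(s % t == 0 for s, t in zip(vol.shape, shape)):
        f = [s // t for s, t in zip(vol.shape, shape)]
        return (
            vol.reshape(shape[0], f[0], shape[1], f[1], shape[2], f[2])
            .mean(axis=(1, 3, 5))
            .astype(np.float32)
        )
    from scipy.ndimage import zoom

    factors = [t / s for t, s in zip(shape, vol.shape)]
    out = zoom(vol.astype(np.float32), factors, order=1)
    return out[: shape[0], : shape[1], : shape[2]].astype(np.float32)


def prepare_input(
    ct_crop: np.ndarray,
    pet_crop: np.ndarray | None,
    config: TrainConfig,
) -> np.ndarray:
    """Window/normalize crops and stack them into the (C, D, H, W) input."""
    ct = apply_window(ct_crop, LUNG_WINDOW)
    ct = _resize_volume(ct, config.input_shape)
    if config.channels == "ct":
        return ct[None]
    pet = normalize_pet(pet_crop)
    pet = _resize_volume(pet, config.input_shape)
    return np.stack([ct, pet])


def build_dataset(
    studies: list[StudyPair],
    config: TrainConfig,
    *,
    mode: str = "automated",
    localizer_params: LocalizerParams | None = None,
    annotations: dict[str, NoduleAnnotation] | None = None,
    return_crops: bool = False,
):
    """Run the chosen preprocessing on every study and assemble arrays.

    Returns ``(X, y, case_ids)`` with X of shape (N, C, D, H, W); with
    ``return_crops`` the per-case crop results are appended for provenance.
    """
    xs, ys, ids, crops = [], [], [], []
    for study in studies:
        if mode == "automated":
            crop = extract_lung_volume(study, localizer_params or LocalizerParams())
            x = prepare_input(crop.ct_crop, crop.pet_crop, config)
        elif mode == "manual":
            if annotations is None or study.case_id not in annotations:
                raise ValueError(f"manual mode requires an annotation for {study.case_id}")
            crop = crop_manual(study, annotations[study.case_id])
            x = prepare_input(crop.ct_crop, crop.pet_crop_resized, config)
        else:
            raise ValueError(f"mode must be automated or manual, got {mode!r}")
        xs.append(x)
        ys.append(LABEL_TO_INT[study.label])
        ids.append(study.case_id)
        crops.append(crop)
    X = np.stack(xs)
    y = np.asarray(ys, dtype=np.int64)
    if return_crops:
        return X, y, ids, crops
    return X, y, ids


def _make_model(arch: str, config: TrainConfig, seed: int):
    shape = (config.n_channels,) + config.input_shape
    if arch == "hrnet":
        return build_hrnet3d(
            HrnetConfig(
                base_channels=config.base_channels,
                blocks_per_stage=config.blocks_per_stage,
                input_shape=shape,
                seed=seed,
            )
        )
    if arch == "resnet":
        return build_resnet3d(
            ResnetConfig(
                base_channels=config.base_channels, input_shape=shape, seed=seed
            )
        )
    raise ValueError(f"arch must be hrnet or resnet, got {arch!r}")


def train_model(
    model,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
):
    """Adam + cross-entropy minibatch training, in place."""
    weights = None
    if config.class_weighting:
        counts = np.bincount(y, minlength=2).astype(np.float32)
        counts = np.maximum(counts, 1)
        weights = (counts.sum() / (2 * counts)).astype(np.float32)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = len(y)
    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:  # batchnorm needs a batch
                continue
            logits = model(Tensor(X[idx]))
            loss = cross_entropy_logits(logits, y[idx], class_weights=weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        logger.debug("epoch %d: loss %.4f", epoch, float(np.mean(losses)))
    return model


def predict_scores(model, X: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Malignancy probabilities (softmax of class 1) in eval mode."""
    model.eval()
    out = []
    for start in range(0, len(X), batch_size):
        logits = model(Tensor(X[start : start + batch_size]))
        out.append(softmax(logits.data)[:, 1])
    return np.concatenate(out)


def training_accuracy(model, X: np.ndarray, y: np.ndarray) -> float:
    scores = predict_scores(model, X)
    return float(((scores >= 0.5).astype(int) == y).mean())


def train_cv(
    X: np.ndarray,
    y: np.ndarray,
    case_ids: list[str],
    arch: str = "hrnet",
    config: TrainConfig = TrainConfig(),
) -> list[ModelPrediction]:
    """Stratified k-fold cross-validation; every case scored exactly once
    by the model that did not see it."""
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    preds: list[ModelPrediction] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        if np.unique(y[train_idx]).size < 2:
            raise ValueError(f"fold {fold}: a class is absent from the training split")
        rng = np.random.default_rng([config.seed, fold])
        model = _make_model(arch, config, seed=config.seed * 1000 + fold)
        train_model(model, X[train_idx], y[train_idx], config, rng)
        scores = predict_scores(model, X[test_idx])
        for i, s in zip(test_idx, scores):
            preds.append(
                ModelPrediction(
                    case_id=case_ids[i], score=float(s), fold_index=fold, label=int(y[i])
                )
            )
    return preds
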