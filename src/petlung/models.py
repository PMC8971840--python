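"""3D classifier architectures.

Two families, mirroring the comparison the pipeline is built around:

* :class:`HrNet3d` — a high-resolution multi-branch network.  The top
  branch never passes through a stride or pooling layer, so its feature
  maps retain the input spatial size at every stage; lower branches run at
  resolutions halved per branch and all branches exchange information
  through multi-scale fusion (nearest-neighbour upsampling toward higher
  resolutions, strided convolution toward lower ones).
* :class:`ResNet3d` — a conventional residual baseline whose feature maps
  are strictly downsampled stage by stage before global pooling.

Both take two-channel ``(CT, PET)`` inputs (early channel fusion, PET
upsampled to the CT grid beforehand) and emit two-class logits.  Class
evidence maps (:func:`compute_heatmap`) come from the class-weighted last
feature map, min-max normalized and upsampled to the input spatial shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom as nd_zoom

from .nn import BatchNorm3d, Conv3d, Linear, Module, Tensor
from .nn.autodiff import (
    add,
    concat,
    global_avg_pool,
    global_max_pool,
    relu,
    upsample_nearest,
)

__all__ = [
    "HrnetConfig",
    "ResnetConfig",
    "HrNet3d",
    "ResNet3d",
    "FuseMultiscale",
    "build_hrnet3d",
    "build_resnet3d",
    "compute_heatmap",
]


@dataclass(frozen=True)
class HrnetConfig:
    """High-resolution network hyper-parameters.

    ``input_shape`` is (channels, D, H, W); every spatial size must be
    divisible by ``2**(n_branches - 1)`` so the lowest branch has an
    integral grid.
    """

    n_branches: int = 3
    base_channels: int = 16
    blocks_per_stage: int = 2
    input_shape: tuple[int, int, int, int] = (2, 16, 64, 64)
    head_pool: str = "max"
    seed: int = 0

    def __post_init__(self):
        if self.head_pool not in ("max", "avg"):
            raise ValueError("head_pool must be 'max' or 'avg'")
        if self.n_branches < 1:
            raise ValueError("need at least one branch")
        div = 2 ** (self.n_branches - 1)
        if any(s % div for s in self.input_shape[1:]):
            raise ValueError(
                f"input spatial shape {self.input_shape[1:]} not divisible by {div} "
                f"(required for {self.n_branches} branches)"
            )


@dataclass(frozen=True)
class ResnetConfig:
    """Residual baseline: ``n_stages`` stages, each halving the grid."""

    n_stages: int = 3
    base_channels: int = 16
    input_shape: tuple[int, int, int, int] = (2, 16, 64, 64)
    head_pool: str = "max"
    seed: int = 0

    def __post_init__(self):
        if self.head_pool not in ("max", "avg"):
            raise ValueError("head_pool must be 'max' or 'avg'")
        div = 2**self.n_stages
        if any(s % div == 0 and s // div < 1 or s % div for s in self.input_shape[1:]):
            raise ValueError(
                f"input spatial shape {self.input_shape[1:]} not divisible by {div}"
            )


class ResidualBlock(Module):
    def __init__(self, c_in: int, c_out: int, stride: int = 1, rng=None):
        self.conv1 = Conv3d(c_in, c_out, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm3d(c_out)
        self.conv2 = Conv3d(c_out, c_out, 3, rng=rng)
        self.bn2 = BatchNorm3d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv3d(c_in, c_out, 1, stride=stride, pad=0, bias=False, rng=rng)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(relu(self.bn1(self.conv1(x)))))
        skip = self.proj(x) if self.proj is not None else x
        return relu(add(out, skip))


class FuseMultiscale(Module):
    """Multi-scale fusion: every branch receives the sum of all branches'
    maps resampled to its resolution.

    All branches carry the same channel count, so upsampling toward higher
    resolutions is parameter-free nearest-neighbour repetition; downsampling
    toward lower resolutions is a strided convolution (one per ordered
    branch pair), bias-free so fusion stays linear in its inputs.
    """

    def __init__(self, n_branches: int, channels: int, rng=None):
        self.n_branches = n_branches
        self.down = {}
        for j in range(n_branches):
            for i in range(j + 1, n_branches):
                self.down[(j, i)] = Conv3d(
                    channels, channels, 3, stride=2 ** (i - j), bias=False, rng=rng
                )
        self._down_list = list(self.down.values())  # for parameter discovery

    def forward(self, features: list[Tensor]) -> list[Tensor]:
        n = len(features)
        if n != self.n_branches:
            raise ValueError(f"expected {self.n_branches} feature maps, got {n}")
        outs = []
        for i in range(n):
            total = features[i]
            for j in range(n):
                if j == i:
                    continue
                if j > i:  # lower resolution -> upsample
                    contrib = upsample_nearest(features[j], 2 ** (j - i))
                else:  # higher resolution -> strided conv
                    contrib = self.down[(j, i)](features[j])
                if contrib.shape != total.shape:
                    raise ValueError(
                        f"fusion shape mismatch on branch {i}: "
                        f"{contrib.shape} vs {total.shape}"
                    )
                total = add(total, contrib)
            outs.append(total)
        return outs


class HrNet3d(Module):
    """The multi-branch high-resolution classifier.

    Structure: a stride-1 stem, then one stage per branch.  Stage ``s``
    runs ``blocks_per_stage`` residual blocks on each of the ``s+1`` active
    branches, fuses them, and (until all branches exist) opens the next
    branch with a stride-2 transition from the lowest one.  The head
    global-average-pools every branch, concatenates, and maps linearly to
    two classes.  The fused top-branch map of the last stage is kept as
    ``last_feature_map`` for heat-map computation.
    """

    def __init__(self, config: HrnetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        c_in = config.input_shape[0]
        self.stem = Conv3d(c_in, c, 3, rng=rng)
        self.stem_bn = BatchNorm3d(c)
        self.stages = []
        self.fusions = []
        self.transitions = []
        for s in range(config.n_branches):
            n_active = s + 1
            stage = [
                [
                    ResidualBlock(c, c, rng=rng)
                    for _ in range(config.blocks_per_stage)
                ]
                for _ in range(n_active)
            ]
            self.stages.append(stage)
            self.fusions.append(
                FuseMultiscale(n_active, c, rng=rng) if n_active > 1 else None
            )
            if s < config.n_branches - 1:
                self.transitions.append(Conv3d(c, c, 3, stride=2, rng=rng))
        self.head = Linear(c * config.n_branches, 2, rng=rng)
        self.last_feature_map: np.ndarray | None = None
        self.top_branch_shapes: list[tuple[int, ...]] = []

    def forward(self, x: Tensor) -> Tensor:
        self.top_branch_shapes = []
        h = relu(self.stem_bn(self.stem(x)))
        branches = [h]
        self.top_branch_shapes.append(h.shape[2:])
        for s, stage in enumerate(self.stages):
            branches = [
                self._run_blocks(stage[i], branches[i]) for i in range(len(branches))
            ]
            if self.fusions[s] is not None:
                branches = self.fusions[s](branches)
            self.top_branch_shapes.append(branches[0].shape[2:])
            if s < len(self.stages) - 1:
                branches.append(self.transitions[s](branches[-1]))
        self.last_feature_map = branches[0].data
        pool = global_max_pool if self.config.head_pool == "max" else global_avg_pool
        pooled = concat([pool(b) for b in branches], axis=1)
        return self.head(pooled)

    @staticmethod
    def _run_blocks(blocks, x):
        for blk in blocks:
            x = blk(x)
        return x

    def malignant_channel_weights(self) -> np.ndarray:
        """Head weights of the malignant class for the top branch's channels."""
        c = self.config.base_channels
        return self.head.w.data[:c, 1]


class ResNet3d(Module):
    """Conventional residual classifier: resolution halves every stage."""

    def __init__(self, config: ResnetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        self.stem = Conv3d(config.input_shape[0], c, 3, rng=rng)
        self.stem_bn = BatchNorm3d(c)
        self.blocks = []
        widths = [c * 2**i for i in range(config.n_stages)]
        prev = c
        for wdt in widths:
            self.blocks.append(ResidualBlock(prev, wdt, stride=2, rng=rng))
            prev = wdt
        self.head = Linear(prev, 2, rng=rng)
        self.last_feature_map: np.ndarray | None = None
        self.stage_shapes: list[tuple[int, ...]] = []

    def forward(self, x: Tensor) -> Tensor:
        h = relu(self.stem_bn(self.stem(x)))
        self.stage_shapes = [h.shape[2:]]
        for blk in self.blocks:
            h = blk(h)
            self.stage_shapes.append(h.shape[2:])
        self.last_feature_map = h.data
        pool = global_max_pool if self.config.head_pool == "max" else global_avg_pool
        return self.head(pool(h))

    def malignant_channel_weights(self) -> np.ndarray:
        return self.head.w.data[:, 1]


def build_hrnet3d(config: HrnetConfig = HrnetConfig()) -> HrNet3d:
    """Construct the high-resolution network (deterministic from config)."""
    return HrNet3d(config)


def build_resnet3d(config: ResnetConfig = ResnetConfig()) -> ResNet3d:
    return ResNet3d(config)


def compute_heatmap(model, x: np.ndarray) -> np.ndarray:
    """Class-evidence map for the malignant class on one input.

    Runs a forward pass on ``x`` (C, D, H, W), weights the channels of the
    model's last feature map by the malignant-class head weights, min-max
    normalizes to [0, 1] and trilinearly upsamples to the input spatial
    shape.  A degenerate constant map yields all zeros with a warning.
    """
    model.eval()
    model.forward(Tensor(x[None]))
    fmap = model.last_feature_map[0]  # (C, d, h, w)
    w = model.malignant_channel_weights()
    cam = np.tensordot(w, fmap, axes=(0, 0))
    rng_span = cam.max() - cam.min()
    if rng_span <= 1e-12:
        warnings.warn("constant feature map; heatmap is uninformative", stacklevel=2)
        cam = np.zeros_like(cam)
    else:
        cam = (cam - cam.min()) / rng_span
    target = x.shape[1:]
    if cam.shape != target:
        factors = [t / s for t, s in zip(target, cam.shape)]
        cam = nd_zoom(cam, factors, order=1)
        cam = np.clip(cam, 0.0, 1.0)
        if cam.shape != target:  # rounding guard
            cam = np.pad(
                cam,
                [(0, t - s) for t, s in zip(target, cam.shape)],
                mode="edge",
            )[tuple(slice(0, t) for t in target)]
    return cam.astype(np.float32)
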