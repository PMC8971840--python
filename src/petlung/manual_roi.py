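"""Expert-annotation preprocessing: fixed small crops around a nodule.

The alternative to the automated localizer: a physician marks the
representative slice (maximum nodule diameter) and the in-plane center, and
the pipeline cuts 16 consecutive slices with a 64x64 CT window and the
matching 16x16 PET window, the latter resized to 64x64 bilinearly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import StudyPair

logger = logging.getLogger(__name__)

__all__ = ["NoduleAnnotation", "ManualCropResult", "crop_manual", "read_annotations"]

CT_CROP_PX = 64
NUM_SLICES = 16


@dataclass(frozen=True)
class NoduleAnnotation:
    """One expert-marked nodule: representative slice, in-plane center, label."""

    case_id: str
    representative_slice: int
    center: tuple[float, float]  # (row, col) in CT pixels
    label: str

    def __post_init__(self):
        if self.label not in ("benign", "malignant"):
            raise ValueError(f"label must be benign or malignant, got {self.label!r}")


@dataclass(frozen=True)
class ManualCropResult:
    ct_crop: np.ndarray  # (16, 64, 64)
    pet_crop_resized: np.ndarray  # (16, 64, 64)
    slice_range: tuple[int, int]  # [start, stop)
    crop_origin: tuple[int, int]


def _window(center: float, width: int, size: int) -> int:
    start = int(np.floor(center - width / 2.0 + 0.5))
    return min(max(start, 0), size - width)


def crop_manual(study: StudyPair, ann: NoduleAnnotation) -> ManualCropResult:
    """Cut the 16-slice 64x64 CT crop and the matching resized PET crop.

    The 16 slices are centered on the representative slice (8 above, 7 below
    plus the slice itself); at the volume ends the window shifts inward
    rather than padding, since a nodule is interior by definition.
    """
    ct = study.ct
    n_s, n_r, n_c = ct.shape
    k = ann.representative_slice
    if not 0 <= k < n_s:
        raise ValueError(f"representative slice {k} outside volume of {n_s} slices")
    r, c = ann.center
    if not (0 <= r < n_r and 0 <= c < n_c):
        raise ValueError(f"annotation center {ann.center} outside slice bounds {(n_r, n_c)}")
    if n_s < NUM_SLICES:
        raise ValueError(f"volume has {n_s} slices; {NUM_SLICES} required")

    s0 = min(max(k - NUM_SLICES // 2, 0), n_s - NUM_SLICES)
    if s0 != k - NUM_SLICES // 2:
        logger.info("slice window shifted inward to [%d, %d)", s0, s0 + NUM_SLICES)
    r0 = _window(r, CT_CROP_PX, n_r)
    c0 = _window(c, CT_CROP_PX, n_c)
    ct_crop = ct.voxels[s0 : s0 + NUM_SLICES, r0 : r0 + CT_CROP_PX, c0 : c0 + CT_CROP_PX]

    pet = study.pet.voxels
    f = n_c / pet.shape[2]
    # PET sample centers over the same physical window, in PET pixel coords
    axis = (np.arange(CT_CROP_PX) + 0.5) - 0.5  # CT offsets within the window
    rows = np.clip((r0 + axis + 0.5) / f - 0.5, 0, pet.shape[1] - 1)
    cols = np.clip((c0 + axis + 0.5) / f - 0.5, 0, pet.shape[2] - 1)
    gr, gc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([gr.ravel(), gc.ravel()])
    pet_crop = np.empty((NUM_SLICES, CT_CROP_PX, CT_CROP_PX), dtype=np.float32)
    for i in range(NUM_SLICES):
        pet_crop[i] = ndimage.map_coordinates(
            pet[s0 + i], coords, order=1, mode="nearest"
        ).reshape(CT_CROP_PX, CT_CROP_PX)

    return ManualCropResult(
        ct_crop=np.ascontiguousarray(ct_crop, dtype=np.float32),
        pet_crop_resized=pet_crop,
        slice_range=(s0, s0 + NUM_SLICES),
        crop_origin=(r0, c0),
    )


def read_annotations(path) -> list[NoduleAnnotation]:
    """Load annotations from CSV (columns case_id, slice, row, col, label).

    Only the first annotation per case is kept; extras are logged.
    """
    df = pd.read_csv(Path(path))
    anns: list[NoduleAnnotation] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        cid = str(row.case_id)
        if cid in seen:
            logger.warning("case %s: extra annotation ignored", cid)
            continue
        seen.add(cid)
        anns.append(
            NoduleAnnotation(
                case_id=cid,
                representative_slice=int(row.slice),
                center=(float(row.row), float(row.col)),
                label=str(row.label),
            )
        )
    return anns
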