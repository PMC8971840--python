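"""Rule-based, annotation-free lung-field localization.

The procedure works on mediastinal-windowed CT, where intrathoracic air is
rendered black, and never segments the lungs:

1. per slice, threshold air (HU <= -160) and find the connected tissue
   components; the **body block** is the largest component that is neither
   too small nor centered near the image border, with its internal holes
   (lungs, trachea) filled in;
2. around the image center column, widen a symmetric **central band** until
   it frames 33% of the body-block area — this confines the air count to the
   mediastinal/lung region and ignores stray black holes near the body edge;
3. scanning superior to inferior, the **lung apex** is the first slice whose
   air fraction (air pixels inside body ∩ band, over the body-block area)
   reaches 5%;
4. from the apex, a 256x256 in-plane window centered on the body centroid is
   carried down 96 consecutive slices for CT, with the same physical window
   sampled from the PET grid at 64x64.

All percentages and sizes are :class:`LocalizerParams` fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .volumes import CtVolume, StudyPair
from .windowing import AIR_THRESHOLD_HU

logger = logging.getLogger(__name__)

__all__ = [
    "ContourRegion",
    "LocalizerParams",
    "LungCropResult",
    "BodyNotFoundError",
    "ApexNotFoundError",
    "binarize_air",
    "find_contours",
    "select_body_contour",
    "central_band",
    "air_fraction",
    "detect_lung_apex",
    "extract_lung_volume",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


class BodyNotFoundError(RuntimeError):
    """No contour on a slice qualifies as the main body block."""


class ApexNotFoundError(RuntimeError):
    """No slice reaches the air-fraction threshold."""


@dataclass(frozen=True)
class ContourRegion:
    """A connected component's outer boundary with its enclosed region.

    ``area_px`` and ``centroid`` are computed on the hole-filled component,
    so internal air spaces count toward the body-block area.  ``mask`` is
    the filled region on the full image grid.
    """

    boundary: np.ndarray  # (n, 2) closed polygon, (row, col)
    area_px: float
    centroid: tuple[float, float]
    mask: np.ndarray = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class LocalizerParams:
    """Tunables of the localization rule.

    ``air_fraction_threshold`` is the "5% of the body block area" rule;
    ``band_fraction`` the "33%" central frame; ``min_body_area_fraction``
    and ``edge_margin_fraction`` quantify "overly small" and "biased toward
    the edge" when picking the body contour.
    """

    air_fraction_threshold: float = 0.05
    band_fraction: float = 0.33
    crop_width_px: int = 256
    num_slices: int = 96
    pet_crop_px: int = 64
    min_body_area_fraction: float = 0.10
    edge_margin_fraction: float = 0.10
    air_threshold_hu: float = AIR_THRESHOLD_HU

    def __post_init__(self):
        for name in ("air_fraction_threshold", "band_fraction", "min_body_area_fraction",
                     "edge_margin_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.crop_width_px <= 0 or self.num_slices <= 0 or self.pet_crop_px <= 0:
            raise ValueError("crop sizes must be positive")


@dataclass(frozen=True)
class LungCropResult:
    """Aligned CT/PET sub-volumes plus provenance of how they were cut."""

    ct_crop: np.ndarray  # (num_slices, crop_width, crop_width) HU
    pet_crop: np.ndarray  # (num_slices, pet_crop_px, pet_crop_px) activity
    apex_slice_index: int
    crop_origin: tuple[int, int]  # (row, col) of the CT window's top-left
    body_centroid: tuple[float, float]
    padded_slices: int = 0
    shifted_px: tuple[int, int] = (0, 0)


# ---------------------------------------------------------------------------
# per-slice primitives
# ---------------------------------------------------------------------------

def binarize_air(slice_hu: np.ndarray, threshold_hu: float = AIR_THRESHOLD_HU) -> np.ndarray:
    """Boolean air mask: true where HU <= threshold (mediastinal ``black``)."""
    return np.asarray(slice_hu) <= threshold_hu


def find_contours(mask: np.ndarray) -> list[ContourRegion]:
    """Outer contour of every 8-connected foreground component.

    Areas and centroids are computed on the hole-filled component, so a body
    cross-section with enclosed lungs yields a single region whose area
    includes the lungs; the hole boundaries are not reported.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    regions: list[ContourRegion] = []
    for i in range(1, n + 1):
        comp = ndimage.binary_fill_holes(labels == i)
        area = float(comp.sum())
        rr, cc = np.nonzero(comp)
        centroid = (float(rr.mean()), float(cc.mean()))
        padded = np.pad(comp, 1).astype(float)
        polys = measure.find_contours(padded, 0.5)
        boundary = max(polys, key=len) - 1.0  # undo pad offset
        regions.append(ContourRegion(boundary=boundary, area_px=area,
                                     centroid=centroid, mask=comp))
    return regions


def select_body_contour(
    regions: list[ContourRegion],
    image_shape: tuple[int, int],
    params: LocalizerParams = LocalizerParams(),
) -> ContourRegion:
    """Pick the body block among tissue contours.

    A region qualifies if its area is at least ``min_body_area_fraction`` of
    the image and its centroid sits at least ``edge_margin_fraction`` of the
    respective image side away from every border.  The largest qualifying
    region wins; equal areas are broken by centrality.
    """
    h, w = image_shape
    min_area = params.min_body_area_fraction * h * w
    margin_r = params.edge_margin_fraction * h
    margin_c = params.edge_margin_fraction * w
    candidates = []
    for reg in regions:
        r, c = reg.centroid
        if reg.area_px < min_area:
            continue
        if r < margin_r or r > h - 1 - margin_r or c < margin_c or c > w - 1 - margin_c:
            continue
        candidates.append(reg)
    if not candidates:
        raise BodyNotFoundError(
            f"no contour passes area >= {min_area:.0f} px and the edge-margin rule"
        )
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    return min(
        candidates,
        key=lambda reg: (-reg.area_px, float(np.hypot(*(np.array(reg.centroid) - center)))),
    )


def central_band(
    body: ContourRegion,
    image_shape: tuple[int, int],
    band_fraction: float = 0.33,
) -> tuple[int, int]:
    """Narrowest symmetric column interval around the image center framing
    ``band_fraction`` of the body-block area.

    Returns an inclusive ``(col_lo, col_hi)`` interval.  Starting from the
    center column, the interval grows one column on each side until the body
    area inside it reaches the target (clipped at the image borders).
    """
    if body.area_px <= 0:
        raise ValueError("body area must be positive")
    h, w = image_shape
    col_counts = body.mask.sum(axis=0).astype(float)
    target = band_fraction * body.area_px
    c0 = w // 2
    for half in range(w):
        lo = max(0, c0 - half)
        hi = min(w - 1, c0 + half)
        if col_counts[lo : hi + 1].sum() >= target:
            return (lo, hi)
    return (0, w - 1)


def air_fraction(
    slice_hu: np.ndarray,
    body: ContourRegion,
    band: tuple[int, int],
    threshold_hu: float = AIR_THRESHOLD_HU,
) -> float:
    """Air pixels inside body ∩ band, as a fraction of the body-block area."""
    air = binarize_air(slice_hu, threshold_hu)
    lo, hi = band
    band_mask = np.zeros_like(air, dtype=bool)
    band_mask[:, lo : hi + 1] = True
    count = float(np.count_nonzero(air & body.mask & band_mask))
    return count / body.area_px


def _slice_body(slice_hu: np.ndarray, params: LocalizerParams) -> ContourRegion:
    tissue = ~binarize_air(slice_hu, params.air_threshold_hu)
    regions = find_contours(tissue)
    return select_body_contour(regions, slice_hu.shape, params)


def detect_lung_apex(ct: CtVolume, params: LocalizerParams = LocalizerParams()) -> int:
    """First slice (superior→inferior) whose air fraction reaches the threshold.

    Slices without a recognizable body block are skipped.  Raises
    :class:`ApexNotFoundError` if no slice qualifies.
    """
    skipped = 0
    for k in range(ct.shape[0]):
        slice_hu = ct.voxels[k]
        try:
            body = _slice_body(slice_hu, params)
        except BodyNotFoundError:
            skipped += 1
            continue
        band = central_band(body, slice_hu.shape, params.band_fraction)
        if air_fraction(slice_hu, body, band, params.air_threshold_hu) >= params.air_fraction_threshold:
            if skipped:
                logger.debug("detect_lung_apex: skipped %d bodyless slice(s)", skipped)
            return k
    raise ApexNotFoundError(
        f"no slice of {ct.shape[0]} reaches air fraction {params.air_fraction_threshold}"
    )


# ---------------------------------------------------------------------------
# volume extraction
# ---------------------------------------------------------------------------

def _crop_window(center: float, width: int, size: int) -> tuple[int, int]:
    """Integer window [start, start+width) centered on ``center``, shifted
    inward if it exits [0, size). Returns (start, shift applied)."""
    # floor(x + 0.5) rather than round(): keeps integer translations of the
    # body translating the crop identically (no banker's rounding at .5)
    start = int(np.floor(center - width / 2.0 + 0.5))
    shifted = min(max(start, 0), size - width)
    return shifted, shifted - start


def extract_lung_volume(
    study: StudyPair,
    params: LocalizerParams = LocalizerParams(),
) -> LungCropResult:
    """Run apex detection and cut the aligned CT/PET training sub-volumes.

    The CT crop is ``crop_width_px`` square, centered on the body centroid of
    the apex slice, over slices ``[apex, apex + num_slices)``; slices past
    the inferior end are padded with air (HU -1000 / activity 0).  The PET
    crop covers the same physical window, sampled bilinearly to
    ``pet_crop_px`` square.
    """
    ct = study.ct
    apex = detect_lung_apex(ct, params)
    body = _slice_body(ct.voxels[apex], params)
    n_s, n_r, n_c = ct.shape
    w = params.crop_width_px
    if w > n_r or w > n_c:
        raise ValueError(f"crop width {w} exceeds CT in-plane size {(n_r, n_c)}")
    r0, shift_r = _crop_window(body.centroid[0], w, n_r)
    c0, shift_c = _crop_window(body.centroid[1], w, n_c)
    if shift_r or shift_c:
        logger.info("crop shifted inward by (%d, %d) px to stay on the grid", shift_r, shift_c)

    n_take = min(params.num_slices, n_s - apex)
    n_pad = params.num_slices - n_take
    ct_crop = np.full((params.num_slices, w, w), -1000.0, dtype=np.float32)
    ct_crop[:n_take] = ct.voxels[apex : apex + n_take, r0 : r0 + w, c0 : c0 + w]

    pet = study.pet.voxels
    p = params.pet_crop_px
    f = ct.shape[2] / pet.shape[2]  # in-plane CT→PET downscale factor
    pet_crop = np.zeros((params.num_slices, p, p), dtype=np.float32)
    # sample centers of the PET crop, expressed in CT pixel coordinates, then
    # mapped onto the PET grid (aligned grids: pet_x = (ct_x + 0.5)/f - 0.5)
    rows_ct = r0 + (np.arange(p) + 0.5) * w / p - 0.5
    cols_ct = c0 + (np.arange(p) + 0.5) * w / p - 0.5
    rows_pet = np.clip((rows_ct + 0.5) / f - 0.5, 0, pet.shape[1] - 1)
    cols_pet = np.clip((cols_ct + 0.5) / f - 0.5, 0, pet.shape[2] - 1)
    grid_r, grid_c = np.meshgrid(rows_pet, cols_pet, indexing="ij")
    coords = np.stack([grid_r.ravel(), grid_c.ravel()])
    for i in range(n_take):
        pet_crop[i] = ndimage.map_coordinates(
            pet[apex + i], coords, order=1, mode="nearest"
        ).reshape(p, p)
    if n_pad:
        logger.info("padded %d inferior slice(s) with air", n_pad)
    return LungCropResult(
        ct_crop=ct_crop,
        pet_crop=pet_crop,
        apex_slice_index=apex,
        crop_origin=(r0, c0),
        body_centroid=body.centroid,
        padded_slices=n_pad,
        shifted_px=(shift_r, shift_c),
    )
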