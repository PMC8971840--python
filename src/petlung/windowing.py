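"""CT display windows and model-input normalizations.

A display window maps Hounsfield units linearly onto [0, 1] between the
window bounds ``level - width/2`` and ``level + width/2`` and clips outside
them (the standard radiology convention).  Two windows matter here:

* the **mediastinal window** (WL 40 / WW 400, bounds -160..+240), under
  which the tracheal lumen and lung parenchyma are rendered black — this is
  what the rule-based lung localizer thresholds on; and
* the **lung window** (WL -400 / WW 1500), the CT normalization fed to the
  classifiers.

PET model input is normalized by the volume maximum so the hottest voxel
maps to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "MEDIASTINAL_WINDOW",
    "LUNG_WINDOW",
    "AIR_THRESHOLD_HU",
    "window_bounds",
    "apply_window",
    "normalize_pet",
]


@dataclass(frozen=True)
class WindowSpec:
    """A display window defined by level (WL) and width (WW) in HU."""

    level_hu: float
    width_hu: float

    def __post_init__(self):
        if self.width_hu <= 0:
            raise ValueError(f"window width must be positive, got {self.width_hu}")


MEDIASTINAL_WINDOW = WindowSpec(level_hu=40.0, width_hu=400.0)
LUNG_WINDOW = WindowSpec(level_hu=-400.0, width_hu=1500.0)

#: Air/"black" threshold used by the localizer: the mediastinal lower bound.
#: Voxels at or below this HU count as air.
AIR_THRESHOLD_HU = -160.0


def window_bounds(spec: WindowSpec) -> tuple[float, float]:
    """Return the (lower, upper) HU clip bounds ``level ∓ width/2``."""
    half = spec.width_hu / 2.0
    return (spec.level_hu - half, spec.level_hu + half)


def apply_window(volume: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Map HU values through ``spec`` onto [0, 1].

    Values at or below the lower bound become 0 ("entirely black"), values
    at or above the upper bound become 1 ("entirely white"), with a linear
    ramp in between.  Shape is preserved; the result is float32.
    """
    lower, upper = window_bounds(spec)
    vol = np.asarray(volume, dtype=np.float32)
    return np.clip((vol - lower) / (upper - lower), 0.0, 1.0).astype(np.float32)


def normalize_pet(voxels: np.ndarray, *, per_slice: bool = False) -> np.ndarray:
    """Scale PET activity onto [0, 1] by the volume maximum.

    The maximum is taken over the whole 3D volume by default; ``per_slice``
    normalizes each trans-axial slice independently instead.  An all-zero
    volume is returned unchanged (with a log message) rather than dividing
    by zero.
    """
    vox = np.asarray(voxels, dtype=np.float32)
    if vox.min() < 0:
        raise ValueError("PET activity must be nonnegative")
    if per_slice:
        maxima = vox.reshape(vox.shape[0], -1).max(axis=1)
        out = np.zeros_like(vox)
        nz = maxima > 0
        out[nz] = vox[nz] / maxima[nz, None, None]
        if not nz.all():
            logger.warning("normalize_pet: %d all-zero slice(s) left at zero", (~nz).sum())
        return out
    peak = vox.max()
    if peak == 0:
        logger.warning("normalize_pet: all-zero volume, returning zeros")
        return np.zeros_like(vox)
    return vox / peak
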