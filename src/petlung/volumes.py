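"""CT / PET volume containers and readers.

Volumes are stored as ``(slice, row, col)`` arrays with slice 0 the most
superior trans-axial slice (the order in which a radiologist scrolls a chest
CT from the apices down).  CT voxels are Hounsfield units, PET voxels are
nonnegative activity values co-registered to the CT frame by the scanner
(hardware-fused PET-CT); no software registration is performed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

HU_MIN = -1024.0
HU_MAX = 3071.0

__all__ = [
    "CtVolume",
    "PetVolume",
    "StudyPair",
    "FormatError",
    "UnitError",
    "AlignmentError",
    "read_ct_series",
    "read_pet_series",
    "write_nifti",
    "pair_study",
]


class FormatError(ValueError):
    """Raised when a series on disk is structurally inconsistent."""


class UnitError(ValueError):
    """Raised when voxel values cannot be mapped to the expected units."""


class AlignmentError(ValueError):
    """Raised when CT and PET volumes do not cover a compatible extent."""


def _as_volume_array(voxels) -> np.ndarray:
    arr = np.asarray(voxels, dtype=np.float32)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D (slice, row, col) array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class CtVolume:
    """A CT volume in Hounsfield units.

    Attributes
    ----------
    voxels
        ``(slice, row, col)`` float array in HU, clipped to the 12-bit CT
        range [-1024, 3071].
    slice_thickness_mm, pixel_spacing_mm
        Physical voxel size; ``pixel_spacing_mm`` is ``(row, col)``.
    """

    voxels: np.ndarray
    slice_thickness_mm: float = 3.75
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    slice_order: str = "superior_to_inferior"

    def __post_init__(self):
        arr = _as_volume_array(self.voxels)
        if arr.shape[0] < 1 or arr.shape[1] < 16 or arr.shape[2] < 16:
            raise FormatError(f"CT grid {arr.shape} below minimum (1, 16, 16)")
        if self.slice_thickness_mm <= 0 or min(self.pixel_spacing_mm) <= 0:
            raise ValueError("spacing must be positive")
        if self.slice_order != "superior_to_inferior":
            raise ValueError(f"unsupported slice order {self.slice_order!r}")
        if arr.min() < HU_MIN or arr.max() > HU_MAX:
            warnings.warn("CT voxels outside [-1024, 3071]; clipping", stacklevel=3)
            arr = np.clip(arr, HU_MIN, HU_MAX)
        object.__setattr__(self, "voxels", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        n_s, n_r, n_c = self.voxels.shape
        return (
            n_s * self.slice_thickness_mm,
            n_r * self.pixel_spacing_mm[0],
            n_c * self.pixel_spacing_mm[1],
        )


@dataclass(frozen=True)
class PetVolume:
    """A PET activity volume, same axis convention as :class:`CtVolume`."""

    voxels: np.ndarray
    slice_thickness_mm: float = 3.75
    pixel_spacing_mm: tuple[float, float] = (4.0, 4.0)
    slice_order: str = "superior_to_inferior"

    def __post_init__(self):
        arr = _as_volume_array(self.voxels)
        if arr.min() < 0:
            raise UnitError("PET activity values must be nonnegative")
        if self.slice_thickness_mm <= 0 or min(self.pixel_spacing_mm) <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "voxels", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        n_s, n_r, n_c = self.voxels.shape
        return (
            n_s * self.slice_thickness_mm,
            n_r * self.pixel_spacing_mm[0],
            n_c * self.pixel_spacing_mm[1],
        )


@dataclass(frozen=True)
class StudyPair:
    """Co-registered CT + PET volumes for one case.

    The PET in-plane grid is the CT grid downscaled by an integer factor
    (512 -> 128 on the scanner this models, i.e. factor 4), and after
    :func:`pair_study` the PET slice count equals the CT slice count.
    """

    case_id: str
    ct: CtVolume
    pet: PetVolume
    label: str = "unknown"

    def __post_init__(self):
        if self.label not in ("benign", "malignant", "unknown"):
            raise ValueError(f"label must be benign/malignant/unknown, got {self.label!r}")

    @property
    def inplane_downscale(self) -> int:
        return self.ct.shape[2] // self.pet.shape[2]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_nifti(path: Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Load a NIfTI file into (slice, row, col) order, slice 0 most superior.

    NIfTI canonical (RAS) arrays are (x=col, y=row, z) with z increasing
    toward the head, so the z axis is reversed to put the superior end first.
    """
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = img.get_fdata(dtype=np.float32)  # scl_slope / scl_inter applied
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NIfTI volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    vol = np.transpose(data, (2, 1, 0))[::-1]  # (z,y,x), superior first
    return np.ascontiguousarray(vol), float(zooms[2]), (float(zooms[1]), float(zooms[0]))


def _read_dicom_dir(path: Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    datasets = []
    for f in files:
        if not f.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM clutter in the directory
            continue
    if not datasets:
        raise FormatError(f"no readable DICOM slices under {path}")
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent in-plane dimensions across slices: {sorted(shapes)}")
    # superior first: decreasing patient z
    try:
        datasets.sort(key=lambda ds: -float(ds.ImagePositionPatient[2]))
    except (AttributeError, IndexError):
        datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise UnitError("DICOM slice lacks rescale slope/intercept; cannot map to units")
        arr = ds.pixel_array.astype(np.float32)
        slices.append(arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
    ds0 = datasets[0]
    thickness = float(getattr(ds0, "SliceThickness", 1.0) or 1.0)
    spacing = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    return np.stack(slices), thickness, (float(spacing[0]), float(spacing[1]))


def _read_any(path) -> tuple[np.ndarray, float, tuple[float, float]]:
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        return _read_nifti(path)
    raise FormatError(f"unrecognized volume source: {path}")


def read_ct_series(path) -> CtVolume:
    """Read a CT volume (DICOM series directory or NIfTI file) as Hounsfield units."""
    vox, thick, spacing = _read_any(path)
    return CtVolume(vox, slice_thickness_mm=thick, pixel_spacing_mm=spacing)


def read_pet_series(path) -> PetVolume:
    """Read a PET volume; raises :class:`UnitError` on negative activity values."""
    vox, thick, spacing = _read_any(path)
    if vox.min() < 0:
        raise UnitError(f"PET volume contains negative values (min {vox.min():.3g})")
    return PetVolume(vox, slice_thickness_mm=thick, pixel_spacing_mm=spacing)


def write_nifti(volume: CtVolume | PetVolume, path) -> None:
    """Serialize a volume to NIfTI, inverting the read-time axis convention."""
    data = np.transpose(volume.voxels[::-1], (2, 1, 0)).astype(np.float32)
    affine = np.diag(
        [
            volume.pixel_spacing_mm[1],
            volume.pixel_spacing_mm[0],
            volume.slice_thickness_mm,
            1.0,
        ]
    )
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(
        (volume.pixel_spacing_mm[1], volume.pixel_spacing_mm[0], volume.slice_thickness_mm)
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def _resample_slices(pet: np.ndarray, n_target: int, method: str) -> np.ndarray:
    n_src = pet.shape[0]
    if n_src == n_target:
        return pet
    if method == "nearest":
        idx = np.minimum(((np.arange(n_target) + 0.5) * n_src / n_target).astype(int), n_src - 1)
        return pet[idx]
    if method == "trilinear":
        from scipy.ndimage import map_coordinates

        z = (np.arange(n_target) + 0.5) * n_src / n_target - 0.5
        out = np.empty((n_target,) + pet.shape[1:], dtype=pet.dtype)
        zc = np.clip(z, 0, n_src - 1)
        lo = np.floor(zc).astype(int)
        hi = np.minimum(lo + 1, n_src - 1)
        w = (zc - lo).astype(np.float32)[:, None, None]
        out[:] = pet[lo] * (1 - w) + pet[hi] * w
        return out
    raise ValueError(f"unknown slice resampling method {method!r}")


def pair_study(
    ct: CtVolume,
    pet: PetVolume,
    case_id: str,
    label: str = "unknown",
    *,
    extent_rtol: float = 0.05,
    slice_resampling: str = "nearest",
) -> StudyPair:
    """Pair a CT and a PET volume into a co-registered study.

    The PET is resampled along the slice axis onto the CT slice grid
    (``nearest`` by default, ``trilinear`` optional).  CT voxels are never
    modified.  Physical extents must agree within ``extent_rtol`` on every
    axis, otherwise an :class:`AlignmentError` is raised.
    """
    ct_ext = np.array(ct.extent_mm)
    pet_ext = np.array(pet.extent_mm)
    rel = np.abs(ct_ext - pet_ext) / ct_ext
    if np.any(rel > extent_rtol):
        raise AlignmentError(
            f"CT extent {tuple(ct_ext)} vs PET extent {tuple(pet_ext)} mm differ by "
            f"{rel.max():.1%} (> {extent_rtol:.0%} tolerance)"
        )
    vox = _resample_slices(pet.voxels, ct.shape[0], slice_resampling)
    if vox.shape[0] != pet.shape[0]:
        thickness = ct.slice_thickness_mm
        pet = PetVolume(vox, slice_thickness_mm=thickness, pixel_spacing_mm=pet.pixel_spacing_mm)
    return StudyPair(case_id=case_id, ct=ct, pet=pet, label=label)
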