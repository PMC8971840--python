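"""Synthetic thorax PET-CT phantoms with known geometry and labels.

A phantom is an elliptical soft-tissue body (HU ~40) in an air background
(HU -1000).  A tracheal air column runs through the uppermost slices; from
``lung_start_slice`` downward two lung ellipses (HU -850, i.e. below the
mediastinal air threshold) appear and grow inferiorly, so the 5%-air apex
rule triggers a few slices below the first lung voxel.  Spherical nodules of
controllable diameter, HU and PET uptake sit inside the lungs.  The PET
volume has uniform background uptake inside the body, hot nodules, Gaussian
smoothing, and an in-plane grid downscaled 4x from the CT (512 -> 128 on the
scanner this emulates).

Ground truth (:class:`PhantomTruth`) records both the first slice containing
lung air and the first slice whose in-band air fraction reaches 5% — the
latter computed by brute-force pixel counting, independently of the
localizer's contour machinery — plus the lung and nodule masks.

Two geometry profiles exist: ``full`` (512x512 in-plane, the scanner matrix)
and ``fast`` (128x128, all in-plane sizes scaled by 1/4) for quick sweeps
and training runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import CtVolume, PetVolume, StudyPair

__all__ = [
    "NoduleSpec",
    "PhantomSpec",
    "PhantomTruth",
    "CohortRanges",
    "generate_phantom",
    "generate_cohort",
]

PET_DOWNSCALE = 4


@dataclass(frozen=True)
class NoduleSpec:
    """One spherical nodule: center in (slice, row, col) voxels, in-plane
    diameter in CT pixels, CT density and PET uptake."""

    center_slice: int
    center_row: float
    center_col: float
    diameter_px: float
    hu: float = 20.0
    pet_uptake: float = 6.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic thorax.

    Defaults describe the ``full`` 512x512 profile; :meth:`create` scales
    the in-plane geometry for other grid sizes.
    """

    n_slices: int = 120
    image_px: int = 512
    body_center: tuple[float, float] = (266.0, 256.0)
    body_semiaxes: tuple[float, float] = (150.0, 200.0)  # (row, col)
    tissue_hu: float = 40.0
    background_hu: float = -1000.0
    lung_hu: float = -850.0
    trachea_radius_px: float = 8.0
    lung_start_slice: int = 10
    lung_col_offset: float = 66.0
    lung_semiaxes: tuple[float, float] = (97.0, 58.0)  # full-size (row, col)
    lung_initial_scale: float = 0.5
    lung_growth_per_slice: float = 0.04
    nodules: tuple[NoduleSpec, ...] = ()
    pet_background: float = 0.5
    pet_smoothing_px: float = 1.0
    noise_sigma_hu: float = 10.0
    slice_thickness_mm: float = 3.75
    pixel_spacing_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.lung_start_slice < self.n_slices:
            raise ValueError("lung_start_slice must lie inside the volume")
        if min(self.body_semiaxes) <= 0 or min(self.lung_semiaxes) <= 0:
            raise ValueError("semi-axes must be positive")

    @classmethod
    def create(cls, profile: str = "full", **overrides) -> "PhantomSpec":
        """Build a spec for a named geometry profile (``full`` or ``fast``)."""
        if profile == "full":
            base = cls()
        elif profile == "fast":
            s = 1.0 / 4.0
            base = cls(
                n_slices=48,
                image_px=128,
                body_center=(266.0 * s, 256.0 * s),
                body_semiaxes=(150.0 * s, 200.0 * s),
                trachea_radius_px=8.0 * s,
                lung_start_slice=8,
                lung_col_offset=66.0 * s,
                lung_semiaxes=(97.0 * s, 58.0 * s),
                pixel_spacing_mm=4.0,
            )
        else:
            raise ValueError(f"unknown profile {profile!r}")
        return replace(base, **overrides)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of one phantom.

    ``first_air_slice`` is where lung voxels first appear; ``apex_slice`` is
    the first slice whose air fraction inside the body's 33% central band
    reaches 5% — the quantity the localizer is scored against.
    """

    first_air_slice: int
    apex_slice: int
    body_centroid: tuple[float, float]
    lung_mask: np.ndarray = field(repr=False)
    nodule_mask: np.ndarray = field(repr=False)
    air_fraction_per_slice: np.ndarray = field(repr=False)
    label: str = "unknown"


def _ellipse_mask(shape, center, semiaxes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = semiaxes
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


def _band_air_fraction(
    body: np.ndarray, air: np.ndarray, band_fraction: float = 0.33,
    threshold: float | None = None,
) -> float:
    """Brute-force in-band air fraction: grow a symmetric column interval
    around the image center until it frames ``band_fraction`` of the body
    area, then count air inside body ∩ band."""
    w = body.shape[1]
    counts = body.sum(axis=0)
    target = band_fraction * body.sum()
    c0 = w // 2
    lo = hi = c0
    total = counts[c0]
    while total < target and (lo > 0 or hi < w - 1):
        lo = max(0, lo - 1)
        hi = min(w - 1, hi + 1)
        total = counts[lo : hi + 1].sum()
    in_band = np.zeros_like(body)
    in_band[:, lo : hi + 1] = body[:, lo : hi + 1]
    return float(np.count_nonzero(air & in_band)) / float(body.sum())


def _lung_masks_slice(spec: PhantomSpec, k: int, shape) -> np.ndarray:
    """Boolean lung mask (both lungs) on slice k, empty above lung_start."""
    if k < spec.lung_start_slice:
        return np.zeros(shape, dtype=bool)
    scale = min(
        1.0,
        spec.lung_initial_scale + spec.lung_growth_per_slice * (k - spec.lung_start_slice),
    )
    a = spec.lung_semiaxes[0] * scale
    b = spec.lung_semiaxes[1] * scale
    cr, cc = spec.body_center
    left = _ellipse_mask(shape, (cr, cc - spec.lung_col_offset), (a, b))
    right = _ellipse_mask(shape, (cr, cc + spec.lung_col_offset), (a, b))
    return left | right


def _nodule_mask(spec: PhantomSpec, nod: NoduleSpec, shape3d) -> np.ndarray:
    """Physically spherical nodule rasterized on the anisotropic voxel grid."""
    n_s, n_r, n_c = shape3d
    r_mm = nod.diameter_px / 2.0 * spec.pixel_spacing_mm
    ss, rr, cc = np.ogrid[:n_s, :n_r, :n_c]
    d2 = (
        ((ss - nod.center_slice) * spec.slice_thickness_mm) ** 2
        + ((rr - nod.center_row) * spec.pixel_spacing_mm) ** 2
        + ((cc - nod.center_col) * spec.pixel_spacing_mm) ** 2
    )
    return d2 <= r_mm**2


def generate_phantom(
    spec: PhantomSpec, label: str = "unknown"
) -> tuple[StudyPair, PhantomTruth]:
    """Render a phantom CT/PET study pair and its ground truth.

    Fully reproducible from ``spec.seed``; raises ``ValueError`` when a
    nodule is not contained in the lung regions.
    """
    shape2d = (spec.image_px, spec.image_px)
    shape3d = (spec.n_slices,) + shape2d
    body2d = _ellipse_mask(shape2d, spec.body_center, spec.body_semiaxes)
    trachea2d = _ellipse_mask(
        shape2d,
        (spec.body_center[0] - 0.55 * spec.body_semiaxes[0], spec.body_center[1]),
        (spec.trachea_radius_px, spec.trachea_radius_px),
    )

    ct = np.full(shape3d, spec.background_hu, dtype=np.float32)
    lung_mask = np.zeros(shape3d, dtype=bool)
    air_fracs = np.zeros(spec.n_slices, dtype=np.float64)
    for k in range(spec.n_slices):
        lungs = _lung_masks_slice(spec, k, shape2d) & body2d
        lung_mask[k] = lungs
        sl = ct[k]
        sl[body2d] = spec.tissue_hu
        sl[lungs] = spec.lung_hu
        if k < spec.lung_start_slice:
            sl[trachea2d & body2d] = spec.background_hu
        air2d = lungs | (trachea2d & body2d if k < spec.lung_start_slice else lungs)
        air_fracs[k] = _band_air_fraction(body2d, air2d)

    nodule_mask = np.zeros(shape3d, dtype=bool)
    for nod in spec.nodules:
        nmask = _nodule_mask(spec, nod, shape3d)
        if not nmask.any():
            raise ValueError(f"nodule {nod} rasterizes to zero voxels")
        if not (nmask <= lung_mask).all():
            raise ValueError(f"nodule {nod} is not fully inside the lung regions")
        ct[nmask] = nod.hu
        nodule_mask |= nmask

    apex_candidates = np.nonzero(air_fracs >= 0.05)[0]
    if apex_candidates.size == 0:
        raise ValueError("phantom never reaches 5% in-band air; adjust lung geometry")
    apex_slice = int(apex_candidates[0])

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma_hu > 0:
        ct = ct + rng.normal(0.0, spec.noise_sigma_hu, size=shape3d).astype(np.float32)
        ct = np.clip(ct, -1024.0, 3071.0)

    pet_px = spec.image_px // PET_DOWNSCALE
    pet = np.zeros((spec.n_slices, pet_px, pet_px), dtype=np.float32)
    # block-average the CT-resolution activity painting onto the PET grid
    activity = np.zeros(shape3d, dtype=np.float32)
    for k in range(spec.n_slices):
        activity[k][body2d] = spec.pet_background
    for nod in spec.nodules:
        activity[_nodule_mask(spec, nod, shape3d)] = nod.pet_uptake
    pet = activity.reshape(
        spec.n_slices, pet_px, PET_DOWNSCALE, pet_px, PET_DOWNSCALE
    ).mean(axis=(2, 4))
    if spec.pet_smoothing_px > 0:
        pet = gaussian_filter(pet, sigma=(0, spec.pet_smoothing_px, spec.pet_smoothing_px))
    pet = np.maximum(pet, 0.0)

    ct_vol = CtVolume(
        ct,
        slice_thickness_mm=spec.slice_thickness_mm,
        pixel_spacing_mm=(spec.pixel_spacing_mm, spec.pixel_spacing_mm),
    )
    pet_vol = PetVolume(
        pet,
        slice_thickness_mm=spec.slice_thickness_mm,
        pixel_spacing_mm=(
            spec.pixel_spacing_mm * PET_DOWNSCALE,
            spec.pixel_spacing_mm * PET_DOWNSCALE,
        ),
    )
    study = StudyPair(case_id=f"phantom-{spec.seed}", ct=ct_vol, pet=pet_vol, label=label)
    truth = PhantomTruth(
        first_air_slice=spec.lung_start_slice,
        apex_slice=apex_slice,
        body_centroid=spec.body_center,
        lung_mask=lung_mask,
        nodule_mask=nodule_mask,
        air_fraction_per_slice=air_fracs,
        label=label,
    )
    return study, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortRanges:
    """Class-conditional nodule distributions for generated cohorts.

    Malignant nodules are larger and hotter by construction (uptake
    N(6, 1) vs N(2, 0.8); in-plane diameters N(30, 8) vs N(20, 6) px on the
    512 grid, truncated positive), which makes the classification task
    well-posed and separable.
    """

    uptake_malignant: tuple[float, float] = (6.0, 1.0)
    uptake_benign: tuple[float, float] = (2.0, 0.8)
    diameter_malignant_px: tuple[float, float] = (30.0, 8.0)
    diameter_benign_px: tuple[float, float] = (20.0, 6.0)


def _truncated_normal(rng, mean, sd, low):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return float(x)
    return float(low + abs(rng.normal(0, sd)))  # pragma: no cover


def generate_cohort(
    n_cases: int = 112,
    malignant_fraction: float = 79 / 112,
    param_ranges: CohortRanges = CohortRanges(),
    seed: int = 0,
    profile: str = "fast",
) -> tuple[list[StudyPair], list[PhantomTruth]]:
    """Generate a labeled phantom cohort with separable classes.

    Class counts are ``round(n * malignant_fraction)`` malignant, the rest
    benign (the default fraction reproduces a 79/33 split at n=112).
    Per-case seeds are derived deterministically from the master seed.
    """
    if n_cases < 2:
        raise ValueError("need at least 2 cases")
    n_mal = int(round(n_cases * malignant_fraction))
    if not 0 < n_mal < n_cases:
        raise ValueError(
            f"malignant fraction {malignant_fraction} infeasible for n={n_cases}"
        )
    labels = ["malignant"] * n_mal + ["benign"] * (n_cases - n_mal)
    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n_cases)
    base = PhantomSpec.create(profile)
    scale = base.image_px / 512.0

    studies: list[StudyPair] = []
    truths: list[PhantomTruth] = []
    for i, label in enumerate(labels):
        rng = np.random.default_rng(case_seeds[i])
        if label == "malignant":
            upt = _truncated_normal(rng, *param_ranges.uptake_malignant, 0.2)
            diam = _truncated_normal(rng, *param_ranges.diameter_malignant_px, 8.0)
        else:
            upt = _truncated_normal(rng, *param_ranges.uptake_benign, 0.2)
            diam = _truncated_normal(rng, *param_ranges.diameter_benign_px, 8.0)
        diam *= scale
        # place the nodule where the lungs are at full size, near a lung center
        full_scale_slice = base.lung_start_slice + math.ceil(
            (1.0 - base.lung_initial_scale) / base.lung_growth_per_slice
        )
        lo = full_scale_slice + 2
        hi = base.n_slices - 4
        k = int(rng.integers(lo, hi))
        side = rng.choice([-1.0, 1.0])
        jitter_r = rng.normal(0, base.lung_semiaxes[0] * 0.15)
        jitter_c = rng.normal(0, base.lung_semiaxes[1] * 0.15)
        nod = NoduleSpec(
            center_slice=k,
            center_row=base.body_center[0] + jitter_r,
            center_col=base.body_center[1] + side * base.lung_col_offset + jitter_c,
            diameter_px=diam,
            pet_uptake=upt,
        )
        spec = replace(base, nodules=(nod,), seed=int(case_seeds[i]))
        for attempt in range(20):
            try:
                study, truth = generate_phantom(spec, label=label)
                break
            except ValueError:
                # nodule clipped the lung boundary: pull it toward the lung center
                nod = replace(
                    nod,
                    center_row=0.5 * (nod.center_row + base.body_center[0]),
                    center_col=0.5
                    * (
                        nod.center_col
                        + base.body_center[1]
                        + side * base.lung_col_offset
                    ),
                    diameter_px=max(4.0 * scale * 4, nod.diameter_px * 0.85),
                )
                spec = replace(base, nodules=(nod,), seed=int(case_seeds[i]))
        else:  # pragma: no cover
            raise RuntimeError(f"could not place nodule for case {i}")
        study = replace(study, case_id=f"case-{i:03d}")
        studies.append(study)
        truths.append(truth)
    return studies, truths
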