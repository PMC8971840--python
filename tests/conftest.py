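import numpy as np
import pytest

from petlung.localizer import LocalizerParams
from petlung.phantom import NoduleSpec, PhantomSpec, generate_phantom

FAST_LOCALIZER = LocalizerParams(crop_width_px=64, num_slices=32, pet_crop_px=16)


@pytest.fixture(scope="session")
def fast_spec() -> PhantomSpec:
    return PhantomSpec.create("fast", seed=3)


@pytest.fixture(scope="session")
def fast_phantom(fast_spec):
    """One quarter-resolution phantom study + truth, no nodule."""
    return generate_phantom(fast_spec)


@pytest.fixture(scope="session")
def nodule_phantom():
    """Quarter-resolution phantom with a single malignant-style nodule."""
    spec = PhantomSpec.create(
        "fast",
        seed=9,
        nodules=(
            NoduleSpec(
                center_slice=30,
                center_row=266.0 / 4,
                center_col=(256 + 66) / 4,
                diameter_px=8.0,
                pet_uptake=6.0,
            ),
        ),
    )
    return generate_phantom(spec, label="malignant")


@pytest.fixture(scope="session")
def fast_localizer_params() -> LocalizerParams:
    return FAST_LOCALIZER
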