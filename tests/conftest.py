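import numpy as np
import pytest

from btbquant import (
    ChipSimConfig,
    SectionSimConfig,
    extract_roi_traces,
    simulate_chip_stack,
    simulate_section_set,
)


@pytest.fixture
def clean_chip():
    """Noise-free chip simulation at the default acquisition design."""
    cfg = ChipSimConfig(true_kin=0.18, noise_sd=0.0, seed=11)
    return simulate_chip_stack(cfg)


@pytest.fixture
def clean_trace(clean_chip):
    return extract_roi_traces(
        clean_chip.stack, clean_chip.mask, clean_chip.times,
        device_id="dev-1", model_label="BBB",
    )


@pytest.fixture
def clean_section():
    """Noise-free small section set (fast to render)."""
    cfg = SectionSimConfig(
        n_lesions=12, noise_sd=0.0, image_shape=(256, 256), seed=7,
        lesion_area_range=(0.02, 0.4),
    )
    return simulate_section_set(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
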