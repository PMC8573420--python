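import numpy as np
import pytest

from nirsnet import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(
    samples: np.ndarray,
    fs: float = 13.33,
    condition: str = "near",
    subject_id: str = "S01",
) -> Recording:
    labels = tuple(f"CH{i:02d}" for i in range(1, samples.shape[0] + 1))
    return Recording(
        subject_id=subject_id,
        condition=condition,
        fs=fs,
        channel_labels=labels,
        samples=samples,
    )


@pytest.fixture
def noise_recording(rng) -> Recording:
    """Three channels of white noise, 180 s at 13.33 Hz."""
    return make_recording(rng.standard_normal((3, 2400)))
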