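import numpy as np
import pytest

from tensionmap import synthetic as syn


@pytest.fixture
def single_exp_hist():
    """Bright single-exponential decay, tau = 3.0 ns, 1e6 photons."""
    return syn.gen_decay_histogram(
        syn.DecaySpec(components=((3.0, 1.0),), total_photons=1e6, seed=42)
    )


@pytest.fixture
def band_image():
    """Attachment-band photon-count image with truth field attached."""
    field = syn.band_concentration_field((96, 96), band_uM=30.9, interior_uM=5.9)
    return syn.gen_attachment_image(
        syn.ImageSpec(
            shape=(96, 96), concentration_field=field, cpp=200.0,
            v_eff=0.235e-15, seed=7,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
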