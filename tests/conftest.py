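import numpy as np
import pytest

from synapsekit import SynapseGeometry, render_synapse_channels, segment_synapse


@pytest.fixture(scope="session")
def geometry():
    """Small concentric synapse that keeps image operations fast."""
    return SynapseGeometry(
        center=(4.8, 4.8), r_csmac=1.2, r_psmac=2.8, r_contact=4.0,
        pixel_size=0.1, image_shape=(96, 96),
    )


@pytest.fixture(scope="session")
def clean_image(geometry):
    return render_synapse_channels(geometry, noise="none")


@pytest.fixture(scope="session")
def partition(clean_image):
    return segment_synapse(clean_image)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
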