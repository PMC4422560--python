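import pytest

from chemotax import simulate


@pytest.fixture
def small_acq() -> simulate.AcquisitionParams:
    """Reduced field of view and frame count to keep rendering fast; same
    pixel size and frame interval as the full assay."""
    return simulate.AcquisitionParams(
        image_shape=(512, 640), n_pre_frames=5, n_post_frames=10
    )


@pytest.fixture
def full_acq() -> simulate.AcquisitionParams:
    return simulate.AcquisitionParams()
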