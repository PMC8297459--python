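import numpy as np
import pytest

from nucseg import SceneSpec, count_cells, generate_scene, segment_image, screening_suite

SUITE_SEED = 7  # fixed suite identity: the acceptance scenes are deterministic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A quick 256x256 scene with a dozen well-separated nuclei."""
    return generate_scene(SceneSpec(height=256, width=256, n_nuclei=12, seed=3))


@pytest.fixture(scope="session")
def high_snr_suite():
    """The deterministic 20-image 512x512 high-SNR suite (5-150 nuclei)."""
    return screening_suite(20, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def suite_segmentations(high_snr_suite):
    """Label maps from running the full pipeline on the whole suite.

    Shared session-wide: both the count-recovery and the segmentation-
    fidelity checks read from this single run.
    """
    return [segment_image(s.image) for s in high_snr_suite]
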