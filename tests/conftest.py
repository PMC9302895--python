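import numpy as np
import pytest

from blinkcount import (
    BenchmarkConfig,
    ModelParams,
    PhotoStateModel,
    build_params,
    make_benchmark,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def three_state():
    return PhotoStateModel.three_state()


@pytest.fixture
def four_state():
    return PhotoStateModel.four_state()


@pytest.fixture
def two_state():
    return PhotoStateModel.two_state()


@pytest.fixture
def simple_params(three_state):
    """Quickly-bleaching single-bright-state kinetics for small tests."""
    return build_params(
        three_state,
        mu_A=[450.0],
        mu_B=[1000.0],
        gain=50.0,
        p_bleach=0.1,
        p_bright_to_dark=0.15,
        p_dark_to_bright=0.25,
    )


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Two small ROIs with full ground truth (single-trace smoke data)."""
    return make_benchmark(
        BenchmarkConfig(n_rois=2, n_frames=400, n_sites=6, labeling_eff=0.7,
                        seed=42)
    )
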