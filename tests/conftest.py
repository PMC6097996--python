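import numpy as np
import pytest

from cabat import ResponseModelParams, accuracy_grid, build_bank


@pytest.fixture(scope="session")
def calibration_bank():
    """27 tracks x 27 accuracy levels x 2 x 2 factorial bank."""
    return build_bank(
        [f"t{i:02d}" for i in range(27)], accuracy_grid(27, 0.5, 1.0), seed=0
    )


@pytest.fixture(scope="session")
def adaptive_bank():
    """The 25 x 100 x 2 x 2 = 10,000-item adaptive test bank."""
    return build_bank(
        [f"t{i:02d}" for i in range(25)], accuracy_grid(100, 0.5, 1.0), seed=0
    )


@pytest.fixture
def params():
    return ResponseModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
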