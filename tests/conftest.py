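import numpy as np
import pytest

from chronoglm.design import TrialTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trials():
    """Six trials, one incorrect, hand-written timing."""
    return TrialTable(
        onset_s=np.array([6.0, 11.0, 17.0, 22.0, 28.0, 34.0]),
        rt_s=np.array([0.30, 0.40, 0.50, np.nan, 0.35, 0.45]),
        condition=np.array(["negative", "neutral", "positive",
                            "negative", "neutral", "positive"], dtype=object),
        correct=np.array([True, True, True, False, True, True]),
        isi_s=np.array([5.0, 6.0, 5.0, 6.0, 6.0, 6.0]),
    )
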