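import numpy as np
import pytest

import mosaicspeech as ms


@pytest.fixture(scope="session")
def rate():
    return 44_100


@pytest.fixture(scope="session")
def short_utterance():
    """A 2-s speech-like fixture with a flat 120-Hz fundamental."""
    return ms.gen_utterance(
        ms.SyntheticUtteranceSpec(duration_s=2.0, seed=3,
                                  f0_start_hz=120.0, f0_end_hz=120.0)
    )


@pytest.fixture(scope="session")
def sentence_utterance():
    """A default-scale (4.3 s) speech-like fixture."""
    return ms.gen_utterance(ms.SyntheticUtteranceSpec(seed=1))


@pytest.fixture(scope="session")
def bank4():
    return ms.get_bank(4)


@pytest.fixture(scope="session")
def grid4_40(short_utterance, bank4):
    return ms.compute_power_grid(short_utterance, bank4, 40.0)


@pytest.fixture(scope="session")
def white_noise(rate):
    rng = np.random.default_rng(12345)
    return ms.Waveform(rng.standard_normal(2 * rate), rate)
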