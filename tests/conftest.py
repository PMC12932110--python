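import numpy as np
import pytest

from specmotion import masks, speech, synthetic_data as sd


@pytest.fixture(scope="session")
def large_ternary_pair():
    """Positive- and negative-parity ternary masks with >= 1e5 elements."""
    base = masks.sample_binary_base(301, 401, seed=42)
    pos = masks.build_ternary_mask(base, masks.CorrelationSpec(d=1, Q=1))
    neg = masks.build_ternary_mask(base, masks.CorrelationSpec(d=1, Q=-1))
    return pos, neg


@pytest.fixture(scope="session")
def chirp_corpus():
    """Small synthetic corpus of rising and falling chirps with ground truth."""
    rng = np.random.default_rng(2024)
    corpus = []
    for k in range(6):
        direction = "rise" if k % 2 == 0 else "fall"
        spec = sd.ChirpSpec(direction=direction, seed=int(rng.integers(0, 2**31)))
        corpus.append((spec, sd.gen_chirp_waveform(spec)))
    return corpus


@pytest.fixture(scope="session")
def chirp_spectrograms(chirp_corpus):
    return [(spec, speech.compute_spectrogram(wave))
            for spec, wave in chirp_corpus]
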