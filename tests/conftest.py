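import numpy as np
import pytest

from ppgsleep.pipeline import extract_corpus_features
from ppgsleep.preprocess import preprocess_epoch
from ppgsleep.pulse import build_pulse_series, detect_peaks, locate_fiducials
from ppgsleep.synthetic import StageParams, generate_pulse_train, simulate_corpus

FS = 128.0


@pytest.fixture(scope="session")
def corpus_features():
    """Feature matrix of a 4-subject, 200-epoch-per-subject synthetic corpus.

    Shared across classifier and acceptance tests; stages are separable by
    construction of the default presets.
    """
    corpus = simulate_corpus(n_subjects=4, epochs_per_subject=200, seed=11)
    return extract_corpus_features(corpus)


@pytest.fixture(scope="session")
def clean_epoch():
    """One preprocessed noise-free 60 bpm epoch with its pulse artifacts."""
    params = StageParams("LS", hr_mean=60.0, hr_sd=0.0, resp_rate=0.25,
                         riam_depth=0.0, rifm_depth=0.0, ipar_target=0.5,
                         noise_sd=0.0)
    x = generate_pulse_train(params, 60.0, FS, seed=0)[: int(30 * FS)]
    y = preprocess_epoch(x, FS)
    peaks = detect_peaks(y, FS)
    beats = locate_fiducials(y, peaks, FS)
    ps = build_pulse_series(peaks, y, FS)
    return {"raw": x, "epoch": y, "peaks": peaks, "beats": beats, "ps": ps}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
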