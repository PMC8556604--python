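import numpy as np
import pytest

from icareject.classifier import train
from icareject.core import FEATURE_NAMES, standard_montage
from icareject.synthetic import SyntheticSpec, make_labelled_corpus


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def small_corpus(spec):
    """150 labelled synthetic components (training-sized smoke corpus)."""
    return make_labelled_corpus(150, spec, seed=1)


@pytest.fixture(scope="session")
def small_classifier(small_corpus):
    df, labels = small_corpus
    return train(df[list(FEATURE_NAMES)].to_numpy(), labels)


@pytest.fixture(scope="session")
def big_corpus(spec):
    """The 600-train / 600-test parameter-recovery corpus (seed 1 / 2)."""
    train_set = make_labelled_corpus(600, spec, seed=1)
    test_set = make_labelled_corpus(600, spec, seed=2)
    return train_set, test_set


def feature_matrix(df):
    return df[list(FEATURE_NAMES)].to_numpy(float)


@pytest.fixture(scope="session")
def pink_noise():
    def _make(rng, n, lam=1.0, srate=512.0):
        freqs = np.fft.rfftfreq(n, d=1.0 / srate)
        shape = np.ones_like(freqs)
        shape[1:] = freqs[1:] ** (-lam / 2.0)
        shape[0] = shape[1]
        spec_ = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(
            len(freqs)
        )
        x = np.fft.irfft(spec_ * shape, n=n)
        return x / x.std()

    return _make
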