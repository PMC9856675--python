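import numpy as np
import pytest

import rtspect as r


@pytest.fixture(scope="session")
def montage64():
    return r.default_montage()


@pytest.fixture(scope="session")
def small_trials():
    """3 subjects x 200 trials with the default planted effects."""
    return r.generate_trials(3, 200, seed=7)


def make_blob_dataset(n=240, size=16, noise=0.1, seed=0):
    """Linearly separable 3-class toy topomaps: one bright blob per class
    at a class-specific position and plane."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, size, size, 3))
    labels = []
    spots = [(3, 3, 0), (3, size - 5, 1), (size - 5, size // 2, 2)]
    names = ("fast", "medium", "slow")
    for i in range(n):
        c = i % 3
        r0, c0, plane = spots[c]
        X[i, r0 - 1:r0 + 2, c0 - 1:c0 + 2, plane] = 1.0
        labels.append(names[c])
    X += rng.normal(0, noise, X.shape)
    return X, np.array(labels)


@pytest.fixture(scope="session")
def blob_data():
    return make_blob_dataset()


@pytest.fixture(scope="session")
def tiny_decoder(blob_data):
    """A small decoder trained to high accuracy on the blob toy set."""
    X, y = blob_data
    cfg = r.DecoderConfig(conv_filters=(4, 8), fc_units=(16,), dropout=0.1,
                          learning_rate=0.02, epochs=20, batch_size=32, seed=0)
    d = r.build_decoder(cfg, X.shape[1:])
    r.train(d, X, y, cfg)
    return d
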