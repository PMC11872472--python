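import numpy as np
import pytest

from qtshape.kshape import kshape_fit
from qtshape.preprocess import znormalize
from qtshape.synth_ecg import SynthRecordConfig, default_shape, generate_record, render_beat


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_record():
    """Zero-noise, identity-warp, single-morphology record (60 beats)."""
    cfg = SynthRecordConfig(
        n_beats=60,
        mean_rr_ms=900.0,
        class_mixture={"normal": 1.0},
        seed=1,
    )
    return generate_record(cfg)


def three_class_beats(n_beats: int, noise_sd: float, seed: int):
    """Z-scored beats cycling normal/inverted/biphasic, with labels."""
    gen = np.random.default_rng(seed)
    classes = ["normal", "inverted", "biphasic"]
    rows, labels = [], []
    for i in range(n_beats):
        c = i % 3
        samples, *_ = render_beat(
            default_shape(classes[c]), 900.0, 250.0, noise_sd_mv=noise_sd, rng=gen
        )
        rows.append(znormalize(samples).z)
        labels.append(c)
    return np.array(rows), np.array(labels)


@pytest.fixture(scope="session")
def clustered_three_class():
    X, y = three_class_beats(36, 0.03, seed=5)
    model = kshape_fit(X, k=3, n_init=5, max_iter=50, seed=2)
    return X, y, model
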