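import numpy as np
import pytest

from dspline.data_model import EpochSet
from dspline.dsp import VectorizedTrials, scatter_matrices


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_epochs():
    """Two 3x10 trials with deterministic values."""
    t1 = np.arange(30, dtype=float).reshape(3, 10)
    t2 = -np.arange(30, dtype=float).reshape(3, 10)
    return EpochSet(
        trials=[t1, t2], labels=["Ug", "Sc"],
        channel_names=["c1", "c2", "c3"], sampling_rate=500.0, onset_index=2,
    )


@pytest.fixture
def random_epochs(rng):
    def make(n_trials=6, n_channels=4, n_samples=50, labels=None,
             onset_index=10, scale=1.0):
        trials = [scale * rng.normal(size=(n_channels, n_samples))
                  for _ in range(n_trials)]
        if labels is None:
            labels = ["A" if i % 2 == 0 else "B" for i in range(n_trials)]
        return EpochSet(
            trials=trials, labels=labels,
            channel_names=[f"ch{i}" for i in range(n_channels)],
            sampling_rate=500.0, onset_index=onset_index,
        )
    return make


@pytest.fixture
def toy_vectors():
    """Class A at (1,0),(0,1); class B at (-1,0),(0,-1)."""
    return VectorizedTrials(
        vectors=np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]]),
        labels=["A", "A", "B", "B"], dims=(1, 2),
    )


@pytest.fixture
def toy_scatter(toy_vectors):
    # gamma=0.1 with mean(diag(S_W)) = 1 gives ridge exactly 0.1
    return scatter_matrices(toy_vectors, reg_gamma=0.1, materialize=True)


def random_vectorized(rng, n_per_class=(8, 6), dim=5, spread=1.0):
    """Random labeled vectors with distinct class means."""
    vecs, labels = [], []
    for j, nj in enumerate(n_per_class):
        mean = rng.normal(scale=spread, size=dim)
        vecs.append(mean + rng.normal(size=(nj, dim)))
        labels += [f"C{j}"] * nj
    return VectorizedTrials(
        vectors=np.vstack(vecs), labels=labels, dims=(1, dim),
    )
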