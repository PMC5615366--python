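import numpy as np
import pytest

from shapebind import (
    AffinityModel,
    IndependentModel,
    SimulationSpec,
    load_shape_table,
)


@pytest.fixture(scope="session")
def shape_table():
    return load_shape_table()


@pytest.fixture(scope="session")
def raw_shape_table():
    return load_shape_table(standardize=False)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def consensus_like_w(rng: np.random.Generator, M: int, scale: float = 2.0) -> np.ndarray:
    """Energies with a clear consensus: favored base 0, others positive."""
    w = rng.normal(0.0, 1.0, size=(M, 4))
    w -= w.min(axis=1, keepdims=True)
    return w * scale


@pytest.fixture
def small_true_model(rng, shape_table):
    """A shape-corrected ground-truth model on an 8-bp motif."""
    w = consensus_like_w(rng, 8)
    from shapebind import ShapeCorrection

    df = rng.normal(0.0, 0.3, size=(7, shape_table.K))
    return AffinityModel(
        independent=IndependentModel(w=w, mu=0.0),
        correction=ShapeCorrection(df=df, table=shape_table),
    )


@pytest.fixture
def tiny_training_set(rng):
    """A 24-sequence training set from a planted 5-bp motif."""
    from shapebind import simulate_training_set

    w = consensus_like_w(rng, 5)
    spec = SimulationSpec(
        M=5, true_w=w, seq_length=24, n_pos=12, n_neg=12, noise_sd=0.05, seed=77
    )
    return spec, simulate_training_set(spec)
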