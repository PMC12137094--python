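import numpy as np
import pytest

from relaxindex.phantom import LayerProfile, PhantomSpec, generate_series


def make_spec(seed: int = 11, **overrides) -> PhantomSpec:
    """Phantom spec used across tests; overrides tweak single conditions."""
    defaults = dict(
        seed=seed,
        noise_sigma=0.0,
        drift_t1t2_um=(150.0, 0.0),
        drift_t2post_um=(-120.0, 0.0),
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def flat_layers(erm_row: float = 120.0, rpe_row: float = 210.0) -> dict:
    return dict(
        erm_profile=LayerProfile(const=erm_row),
        rpe_profile=LayerProfile(const=rpe_row),
    )


@pytest.fixture(scope="session")
def clean_series():
    """Noise-free curved-layer series with 150/-120 um programmed drifts."""
    return generate_series(make_spec(seed=11))


@pytest.fixture(scope="session")
def noisy_series():
    """Same geometry with 5%-of-range additive noise."""
    return generate_series(make_spec(seed=11, noise_sigma=0.05))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def true_rows_at(truth_rows: np.ndarray, columns: np.ndarray) -> np.ndarray:
    """Evaluate per-column truth rows at (fractional) trace columns."""
    return np.interp(columns, np.arange(truth_rows.size), truth_rows)
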