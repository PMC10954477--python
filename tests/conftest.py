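import numpy as np
import pytest

from wclike import ExchangeModel, SpinLockCondition
from wclike.synthetic_data import FixtureSpec, generate_rd_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240122)


@pytest.fixture
def two_state_model():
    """The tautomeric dT·rG exchange model (hybrid duplex, pH 7.4)."""
    p = 0.00083
    return ExchangeModel(
        states=("GS", "ES1"),
        populations=(1 - p, p),
        kex={("GS", "ES1"): 7200.0},
        delta_omega={"G-N1": {"ES1": 34.9}, "T-N3": {"ES1": 25.7}},
        r1=2.5,
        r2=18.0,
    )


@pytest.fixture
def three_state_model():
    """The triangular dG·rU model with tautomeric ES1 and anionic ES2."""
    p1, p2 = 0.0019, 0.0012
    return ExchangeModel(
        states=("GS", "ES1", "ES2"),
        populations=(1 - p1 - p2, p1, p2),
        kex={("GS", "ES1"): 4000.0, ("GS", "ES2"): 5000.0, ("ES1", "ES2"): 13000.0},
        delta_omega={
            "G-N1": {"ES1": 21.0, "ES2": 1.0},
            "U-N3": {"ES1": 36.0, "ES2": 58.0},
        },
        r1=2.5,
        r2=18.0,
    )


@pytest.fixture
def cond():
    return SpinLockCondition(power_hz=1000.0, offset_hz=800.0)


def small_grid_spec(**kwargs):
    """Reduced acquisition grid for tests that refit many replicates."""
    defaults = dict(
        label="dT-rG",
        ph=7.4,
        powers=(600.0, 1800.0),
        n_offsets=7,
        delays=(0.0, 0.06, 0.12),
        mc_iterations=50,
    )
    defaults.update(kwargs)
    return FixtureSpec(**defaults)


@pytest.fixture(scope="session")
def dtrg_dataset():
    """One full-grid noisy dT·rG dataset shared by fitting tests."""
    spec = FixtureSpec(label="dT-rG", ph=7.4, seed=11)
    return generate_rd_dataset(spec)
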