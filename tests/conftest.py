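import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_counts():
    """A tiny deterministic county counts frame (3 counties)."""
    from countyrisk.records import CELL_COLUMNS, POP_COLUMNS

    rows = [
        ("10001", [3, 5, 1, 2, 1, 4], [40_000, 30_000, 120_000]),
        ("10002", [1, 2, 0, 1, 0, 2], [15_000, 25_000, 90_000]),
        ("10003", [0, 1, 1, 0, 1, 1], [8_000, 12_000, 60_000]),
    ]
    return pd.DataFrame(
        [
            {"fips": f, **dict(zip(CELL_COLUMNS, s)), **dict(zip(POP_COLUMNS, n))}
            for f, s, n in rows
        ]
    )


@pytest.fixture(scope="session")
def fitted_small_model(small_counts):
    """One shared stage-1 fit reused by shrinkage/validity/summary tests."""
    from countyrisk.hierarchical import ShootingRateModel

    model = ShootingRateModel(
        chains=2, warmup=300, draws=300, seed=1234, rhat_threshold=1.2
    )
    return model.fit(small_counts)


@pytest.fixture(scope="session")
def synthetic_posterior():
    """A hand-built PosteriorDraws with known theta/mu values (no MCMC)."""
    from countyrisk.hierarchical import PosteriorDraws

    rng = np.random.default_rng(99)
    # 401 draws puts the 2.5/50/97.5 percentiles exactly on order statistics
    n, C = 401, 4
    fips = [f"9{i:04d}" for i in range(C)]
    theta = rng.lognormal(mean=np.log(1e-5), sigma=0.3, size=(n, C, 6))
    mu = rng.normal(-11.0, 0.2, size=(n, 6))
    sigma = np.abs(rng.normal(0.5, 0.05, size=(n, 6)))
    rho = np.tile(np.eye(6), (n, 1, 1))
    return PosteriorDraws(
        fips=fips, mu=mu, sigma=sigma, rho=rho, theta=theta,
        n_chains=1, n_draws_per_chain=401,
        diagnostics={"rhat_max": 1.0}, config={"seed": 99},
    )
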