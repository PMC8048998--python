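import warnings

import numpy as np
import pytest

import nestcam as nc


@pytest.fixture(scope="session")
def small_sim():
    """One simulated site/year with moderate survival and detection."""
    cfg = nc.SimulationConfig(
        n_sites=1, n_years_per_site=1, n_nests=15,
        theta_phi=5.8, sigma_mu_phi=0.0, rng_seed=11,
    )
    return cfg, nc.simulate_site_year(cfg, 0)


@pytest.fixture(scope="session")
def small_posterior(small_sim):
    """A quick (non-publication-scale) fit reused across tests."""
    _, sim = small_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", nc.ConvergenceWarning)
        post = nc.fit_survival_model(
            [sim.to_observation_series()],
            mcmc=nc.McmcConfig(n_chains=2, n_warmup=600, n_samples=600,
                               rng_seed=4),
        )
    return post


def enumerate_loglik(y, phi, p):
    """Brute-force marginal likelihood: sum over every latent path in
    {0,1,2}^T.  Independent oracle for the forward recursion."""
    from math import comb

    T = len(y)
    total = 0.0
    for code in range(3**T):
        path = []
        c = code
        for _ in range(T):
            path.append(c % 3)
            c //= 3
        if path[0] != 2:
            continue
        prob = 1.0
        for t in range(1, T):
            a, b = path[t - 1], path[t]
            if b > a:
                prob = 0.0
                break
            prob *= comb(a, b) * phi**b * (1 - phi) ** (a - b)
        if prob == 0.0:
            continue
        for t in range(T):
            if y[t] is None:
                continue
            z, obs = path[t], y[t]
            if obs > z:
                prob = 0.0
                break
            prob *= comb(z, obs) * p[t] ** obs * (1 - p[t]) ** (z - obs)
        total += prob
    return np.log(total) if total > 0 else -np.inf
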