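"""Shared fixtures: small seeded datasets and a short-chain MCMC budget."""

import numpy as np
import pytest

from balanceprior import (
    BalancingPriorSpec,
    ImbalancedDataset,
    MCMCConfig,
    StructuralModel,
)

TRUE_EMAX = StructuralModel("emax", {"A": 2.0, "B": 10.0, "C": 10.0})


def make_emax_pair(
    seed: int = 42,
    fraction: float = 0.1,
    n_pop: int = 200,
    residual_sd: float = 0.25,
):
    """One imbalanced weight-age pair: complete majority stratum (age >= 18)
    plus a random minority subsample (age <= 5) sized fraction x majority."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(2, 25, n_pop)
    weight = TRUE_EMAX.predict(age) + rng.normal(0, residual_sd, n_pop)
    maj = np.where(age >= 18)[0]
    pool = np.where(age <= 5)[0]
    n_min = max(1, round(fraction * len(maj)))
    sel = rng.choice(pool, n_min, replace=False)
    idx = np.concatenate([maj, sel])
    mask = np.concatenate([np.zeros(len(maj), bool), np.ones(n_min, bool)])
    ds = ImbalancedDataset.from_arrays(age[idx], weight[idx], mask)
    prior = BalancingPriorSpec.from_multiplier(mask, 1.0 / fraction)
    return ds, prior


@pytest.fixture(scope="session")
def emax_pair():
    return make_emax_pair()


@pytest.fixture(scope="session")
def short_mcmc():
    """Sampler budget large enough for stable posterior means in tests."""
    return MCMCConfig(n_burn=16 * 1500, n_sample=16 * 1500, thin=10, n_walkers=16, seed=7)


@pytest.fixture(scope="session")
def balanced_dataset():
    """A balanced Emax dataset (no imbalance; minority label only formal)."""
    rng = np.random.default_rng(11)
    age = rng.uniform(2, 25, 200)
    weight = TRUE_EMAX.predict(age) + rng.normal(0, 0.25, 200)
    mask = np.zeros(200, bool)
    mask[:5] = True  # formal label; fits in conventional mode ignore it
    return ImbalancedDataset.from_arrays(age, weight, mask)
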