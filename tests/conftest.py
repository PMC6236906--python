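"""Shared fixtures.

The heavy simulation-replicate fixtures are session-scoped so the
parameter-recovery, robustness, and model-selection acceptance tests can
share fits instead of refitting.
"""

from __future__ import annotations

import numpy as np
import pytest

import hseghmm as h


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def space12():
    return h.build_state_space()


@pytest.fixture
def space4():
    return h.build_state_space(["A", "AA", "AAAB", "AAAAB"])


@pytest.fixture
def params_t():
    return h.GlobalParams(
        purity=0.9, ploidy=1.6, logR_scale2=0.3, logOR_scale2=0.5, df=4.0,
        family="t",
    )


@pytest.fixture
def params_norm():
    return h.GlobalParams(
        purity=0.9, ploidy=1.6, logR_scale2=0.6, logOR_scale2=0.5,
        family="normal",
    )


def random_chain(J: int, rng) -> h.ChainParams:
    init = rng.dirichlet(np.ones(J))
    trans = rng.dirichlet(np.ones(J), size=J)
    return h.ChainParams(init=init, trans=trans)


def random_log_emissions(N: int, J: int, rng) -> np.ndarray:
    return rng.normal(-1.0, 1.5, size=(N, J))


# ---------------------------------------------------------------------------
# session-scoped simulation fits (shared across acceptance criteria)

N_SIM1_REPS = 50
N_SIM1_LOCI = 2000
SIM1_SEED_BASE = 1000


@pytest.fixture(scope="session")
def sim1_replicates():
    """Heavy-tailed-logR design replicates at reduced scale."""
    return [
        h.simulate(h.SimConfig(n_loci=N_SIM1_LOCI, seed=SIM1_SEED_BASE + r))
        for r in range(N_SIM1_REPS)
    ]


@pytest.fixture(scope="session")
def sim1_t_fits(sim1_replicates):
    return [
        h.fit(ds.loci, ds.space_true, family="t", max_iter=300)
        for ds in sim1_replicates
    ]


@pytest.fixture(scope="session")
def sim1_norm_fits10(sim1_replicates):
    """Normal-family fits of the first 10 heavy-tailed replicates."""
    return [
        h.fit(ds.loci, ds.space_true, family="normal", max_iter=300)
        for ds in sim1_replicates[:10]
    ]


N_SIM2_REPS = 6


@pytest.fixture(scope="session")
def sim2_replicates():
    """Normal-mixture-logR design replicates."""
    return [
        h.simulate(
            h.SimConfig(scenario="mixnorm_logR", n_loci=2000, seed=2000 + r)
        )
        for r in range(N_SIM2_REPS)
    ]


@pytest.fixture(scope="session")
def sim2_fits(sim2_replicates):
    """(t fits, normal fits) on the normal-mixture replicates."""
    fits_t = [
        h.fit(ds.loci, ds.space_true, family="t", max_iter=300)
        for ds in sim2_replicates
    ]
    fits_n = [
        h.fit(ds.loci, ds.space_true, family="normal", max_iter=300)
        for ds in sim2_replicates
    ]
    return fits_t, fits_n
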