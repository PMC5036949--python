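"""Shared fixtures and small helpers for the test suite."""

import numpy as np
import pytest

from mapdp import core
from mapdp.exp_family import (
    ComponentModel,
    FullGaussianModel,
    NIWPrior,
    SphericalGaussianModel,
    SphericalGaussianPrior,
    _Stats,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs():
    """Three well-separated spherical blobs with labels."""
    rng = np.random.default_rng(7)
    means = np.array([[0.0, 0.0], [12.0, 0.0], [6.0, 12.0]])
    X = np.vstack([rng.normal(m, 1.0, size=(60, 2)) for m in means])
    y = np.repeat([0, 1, 2], 60)
    perm = rng.permutation(180)
    return X[perm], y[perm]


@pytest.fixture
def spherical_model(blobs):
    X, _ = blobs
    return SphericalGaussianModel(
        SphericalGaussianPrior(X.mean(axis=0), float(X.var()), 1.0)
    )


@pytest.fixture
def niw_model(blobs):
    X, _ = blobs
    return FullGaussianModel(NIWPrior(X.mean(axis=0), 1.0, 4.0, np.cov(X.T, bias=True)))


class ConstantCostModel(ComponentModel):
    """Stub model with identical cost for every cluster and the prior.

    With geometry neutralized, the assignment rule reduces to comparing
    ``-ln N_k`` terms only, which lets tests pin down tie-breaking and
    count bookkeeping exactly.
    """

    def __init__(self, dim=1, cost=1.0):
        self.dim = dim
        self.cost = cost

    def empty_stats(self, capacity=8):
        return _Stats(capacity, {})

    def add(self, stats, k, x):
        stats.counts[k] += 1

    def remove(self, stats, k, x):
        stats.counts[k] -= 1

    def new_cluster(self, stats):
        if stats.K == stats.capacity:
            stats.grow()
        k = stats.K
        stats.counts[k] = 0
        stats.K += 1
        return k

    def drop(self, stats, k):
        K = stats.K
        stats.counts[k:K - 1] = stats.counts[k + 1:K]
        stats.K = K - 1

    def costs(self, stats, x):
        return np.full(stats.K, self.cost)

    def cost_prior(self, x):
        return self.cost

    def posterior(self, stats, k):
        return None

    def validate(self, X):
        pass


@pytest.fixture
def constant_model():
    return ConstantCostModel()


def fit_small(X, model, **kwargs):
    defaults = dict(n0=1.0, seed=0)
    defaults.update(kwargs)
    return core.fit(np.asarray(X, float), model, core.MapDpConfig(**defaults))
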