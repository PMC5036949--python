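"""Conjugate exponential-family component models.

Each supported feature family pairs a conjugate prior with a closed-form
posterior update and posterior-predictive log density:

=================  ====================  ==============================
data               prior                 posterior predictive
=================  ====================  ==============================
gaussian_spherical Normal (known var)    Normal
gaussian_full      Normal-inv-Wishart    multivariate Student-t
bernoulli          Beta                  Bernoulli(a / (a + b))
binomial           Beta                  beta-binomial
categorical        Dirichlet             categorical(alpha / sum(alpha))
poisson            Gamma (shape, rate)   negative binomial
=================  ====================  ==============================

Two API layers live here.  The *scalar* layer (``ConjugateFamily``
subclasses) exposes ``posterior_update`` and ``log_predictive`` for a
single hyperparameter set, and is the reference implementation used by
the test oracles.  The *engine* layer (``ComponentModel`` subclasses)
maintains sufficient statistics for many clusters at once and evaluates
all per-cluster costs with vectorized numpy; it is what the clustering
loop actually runs on.  The two layers are required to agree to
numerical precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml
from scipy.special import betaln, gammaln
from scipy.stats import multivariate_t

__all__ = [
    "Feature",
    "FeatureSchema",
    "SphericalGaussianPrior",
    "NIWPrior",
    "BetaPrior",
    "DirichletPrior",
    "GammaPrior",
    "SphericalGaussianFamily",
    "FullGaussianFamily",
    "BernoulliFamily",
    "BinomialFamily",
    "CategoricalFamily",
    "PoissonFamily",
    "elliptical_log_predictive",
    "ComponentModel",
    "SphericalGaussianModel",
    "FullGaussianModel",
    "EllipticalModel",
    "family_for",
]

LOG_2PI = np.log(2.0 * np.pi)

VALID_KINDS = (
    "gaussian_spherical",
    "gaussian_full",
    "bernoulli",
    "binomial",
    "categorical",
    "poisson",
)


class SupportError(ValueError):
    """An observation lies outside the support of its feature family."""


# ---------------------------------------------------------------------------
# Feature schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """Declared type of one dataset column."""

    name: str
    kind: str
    n_trials: int | None = None
    n_levels: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "binomial":
            if self.n_trials is None or self.n_trials < 1:
                raise ValueError(f"binomial feature {self.name!r} needs n_trials >= 1")
        if self.kind == "categorical":
            if self.n_levels is None or self.n_levels < 2:
                raise ValueError(f"categorical feature {self.name!r} needs n_levels >= 2")


class FeatureSchema:
    """Ordered collection of :class:`Feature` covering every data column."""

    def __init__(self, features: Sequence[Feature]):
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")
        self.features = list(features)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i: int) -> Feature:
        return self.features[i]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @classmethod
    def from_list(cls, entries: Sequence[dict]) -> "FeatureSchema":
        feats = []
        for e in entries:
            params = dict(e.get("params") or {})
            feats.append(
                Feature(
                    name=e["name"],
                    kind=e["kind"],
                    n_trials=params.get("n_trials"),
                    n_levels=params.get("n_levels"),
                )
            )
        return cls(feats)

    @classmethod
    def from_file(cls, path) -> "FeatureSchema":
        """Read a schema sidecar (YAML or JSON list of {name, kind, params})."""
        text = open(path).read()
        entries = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_list(entries)

    def to_list(self) -> list[dict]:
        out = []
        for f in self.features:
            params = {}
            if f.n_trials is not None:
                params["n_trials"] = f.n_trials
            if f.n_levels is not None:
                params["n_levels"] = f.n_levels
            out.append({"name": f.name, "kind": f.kind, "params": params})
        return out


# ---------------------------------------------------------------------------
# Prior / posterior hyperparameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphericalGaussianPrior:
    """Normal prior on a cluster centroid with known spherical cluster variance.

    Parameters
    ----------
    mu0 : ndarray, shape (D,)
        Prior centroid location.
    var0 : float
        Prior centroid variance (sigma_0^2).
    var : float
        Known within-cluster variance (sigma-hat^2), shared by all clusters.
    """

    mu0: np.ndarray
    var0: float
    var: float

    def __post_init__(self):
        object.__setattr__(self, "mu0", np.atleast_1d(np.asarray(self.mu0, float)))
        if self.var0 <= 0 or self.var <= 0:
            raise ValueError("variances must be strictly positive")


@dataclass(frozen=True)
class NIWPrior:
    """Normal-inverse-Wishart prior for a full-covariance Gaussian cluster."""

    m0: np.ndarray
    kappa0: float
    nu0: float
    S0: np.ndarray

    def __post_init__(self):
        m0 = np.atleast_1d(np.asarray(self.m0, float))
        S0 = np.atleast_2d(np.asarray(self.S0, float))
        object.__setattr__(self, "m0", m0)
        object.__setattr__(self, "S0", S0)
        d = m0.shape[0]
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")
        if self.nu0 <= d - 1:
            raise ValueError("nu0 must exceed D - 1")
        if S0.shape != (d, d):
            raise ValueError("S0 shape does not match m0")

    @property
    def dim(self) -> int:
        return self.m0.shape[0]


@dataclass(frozen=True)
class BetaPrior:
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta hyperparameters must be positive")


@dataclass(frozen=True)
class DirichletPrior:
    alpha: np.ndarray

    def __post_init__(self):
        alpha = np.atleast_1d(np.asarray(self.alpha, float))
        object.__setattr__(self, "alpha", alpha)
        if np.any(alpha <= 0):
            raise ValueError("Dirichlet hyperparameters must be positive")


@dataclass(frozen=True)
class GammaPrior:
    """Gamma prior for a Poisson rate, shape ``a`` and rate ``b``."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Gamma hyperparameters must be positive")


def _require_finite(hyper) -> None:
    for v in vars(hyper).values():
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite hyperparameters: {hyper}")


# ---------------------------------------------------------------------------
# Scalar family layer
# ---------------------------------------------------------------------------


class ConjugateFamily:
    """Reference (non-vectorized) conjugate updates and predictives."""

    def check_support(self, x) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    def posterior_update(self, prior, points):
        raise NotImplementedError

    def log_predictive(self, hyper, x) -> float:
        raise NotImplementedError


class SphericalGaussianFamily(ConjugateFamily):
    def check_support(self, x) -> None:
        if not np.all(np.isfinite(x)):
            raise SupportError(f"non-finite spherical Gaussian observation {x!r}")

    def posterior_update(self, prior: SphericalGaussianPrior, points) -> SphericalGaussianPrior:
        pts = np.atleast_2d(np.asarray(points, float)) if len(points) else None
        if pts is None:
            return prior
        for p in pts:
            self.check_support(p)
        n = pts.shape[0]
        var_k = 1.0 / (1.0 / prior.var0 + n / prior.var)
        mu_k = var_k * (prior.mu0 / prior.var0 + pts.sum(axis=0) / prior.var)
        return SphericalGaussianPrior(mu_k, var_k, prior.var)

    def log_predictive(self, hyper: SphericalGaussianPrior, x) -> float:
        _require_finite(hyper)
        x = np.atleast_1d(np.asarray(x, float))
        self.check_support(x)
        v = hyper.var0 + hyper.var
        d = x.shape[0]
        return float(-0.5 * np.sum((x - hyper.mu0) ** 2) / v - 0.5 * d * (np.log(v) + LOG_2PI))


class FullGaussianFamily(ConjugateFamily):
    """Full-covariance Gaussian with an NIW prior; predictive is Student-t."""

    def check_support(self, x) -> None:
        if not np.all(np.isfinite(x)):
            raise SupportError(f"non-finite Gaussian observation {x!r}")

    def posterior_update(self, prior: NIWPrior, points) -> NIWPrior:
        if len(points) == 0:
            return prior
        pts = np.atleast_2d(np.asarray(points, float))
        for p in pts:
            self.check_support(p)
        n = pts.shape[0]
        xbar = pts.mean(axis=0)
        kappa_n = prior.kappa0 + n
        nu_n = prior.nu0 + n
        m_n = (prior.kappa0 * prior.m0 + n * xbar) / kappa_n
        centered = pts - xbar
        scatter = centered.T @ centered
        dev = (xbar - prior.m0)[:, None]
        S_n = prior.S0 + scatter + (prior.kappa0 * n / kappa_n) * (dev @ dev.T)
        return NIWPrior(m_n, kappa_n, nu_n, S_n)

    def log_predictive(self, hyper: NIWPrior, x) -> float:
        _require_finite(hyper)
        x = np.atleast_1d(np.asarray(x, float))
        self.check_support(x)
        d = hyper.dim
        df = hyper.nu0 - d + 1
        shape = hyper.S0 * (hyper.kappa0 + 1) / (hyper.kappa0 * df)
        return float(multivariate_t.logpdf(x, loc=hyper.m0, shape=shape, df=df))


class BernoulliFamily(ConjugateFamily):
    def check_support(self, x) -> None:
        if x not in (0, 1):
            raise SupportError(f"Bernoulli observation must be 0/1, got {x!r}")

    def posterior_update(self, prior: BetaPrior, points) -> BetaPrior:
        pts = list(points)
        for p in pts:
            self.check_support(p)
        ones = sum(pts)
        return BetaPrior(prior.a + ones, prior.b + len(pts) - ones)

    def log_predictive(self, hyper: BetaPrior, x) -> float:
        _require_finite(hyper)
        self.check_support(x)
        p1 = hyper.a / (hyper.a + hyper.b)
        return float(np.log(p1) if x == 1 else np.log1p(-p1))


class BinomialFamily(ConjugateFamily):
    def __init__(self, n_trials: int):
        if n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        self.n_trials = int(n_trials)

    def check_support(self, x) -> None:
        if x != int(x) or not (0 <= x <= self.n_trials):
            raise SupportError(
                f"binomial observation must be an integer in [0, {self.n_trials}], got {x!r}"
            )

    def posterior_update(self, prior: BetaPrior, points) -> BetaPrior:
        pts = list(points)
        for p in pts:
            self.check_support(p)
        s = sum(pts)
        return BetaPrior(prior.a + s, prior.b + self.n_trials * len(pts) - s)

    def log_predictive(self, hyper: BetaPrior, x) -> float:
        _require_finite(hyper)
        self.check_support(x)
        n = self.n_trials
        comb = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
        return float(comb + betaln(hyper.a + x, hyper.b + n - x) - betaln(hyper.a, hyper.b))


class CategoricalFamily(ConjugateFamily):
    def __init__(self, n_levels: int):
        if n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        self.n_levels = int(n_levels)

    def check_support(self, x) -> None:
        if x != int(x) or not (0 <= x < self.n_levels):
            raise SupportError(
                f"categorical observation must be a level in [0, {self.n_levels}), got {x!r}"
            )

    def posterior_update(self, prior: DirichletPrior, points) -> DirichletPrior:
        alpha = prior.alpha.copy()
        if alpha.shape[0] != self.n_levels:
            raise ValueError("Dirichlet prior length does not match n_levels")
        for p in points:
            self.check_support(p)
            alpha[int(p)] += 1
        return DirichletPrior(alpha)

    def log_predictive(self, hyper: DirichletPrior, x) -> float:
        _require_finite(hyper)
        self.check_support(x)
        return float(np.log(hyper.alpha[int(x)]) - np.log(hyper.alpha.sum()))


class PoissonFamily(ConjugateFamily):
    def check_support(self, x) -> None:
        if x != int(x) or x < 0:
            raise SupportError(f"Poisson observation must be a count >= 0, got {x!r}")

    def posterior_update(self, prior: GammaPrior, points) -> GammaPrior:
        pts = list(points)
        for p in pts:
            self.check_support(p)
        return GammaPrior(prior.a + sum(pts), prior.b + len(pts))

    def log_predictive(self, hyper: GammaPrior, x) -> float:
        """Negative-binomial mass from integrating the Poisson rate out."""
        _require_finite(hyper)
        self.check_support(x)
        a, b = hyper.a, hyper.b
        return float(
            gammaln(a + x)
            - gammaln(a)
            - gammaln(x + 1)
            + a * np.log(b / (b + 1.0))
            - x * np.log(b + 1.0)
        )


def family_for(feature: Feature) -> ConjugateFamily:
    """Scalar family instance for a schema feature."""
    if feature.kind == "gaussian_spherical":
        return SphericalGaussianFamily()
    if feature.kind == "gaussian_full":
        return FullGaussianFamily()
    if feature.kind == "bernoulli":
        return BernoulliFamily()
    if feature.kind == "binomial":
        return BinomialFamily(feature.n_trials)
    if feature.kind == "categorical":
        return CategoricalFamily(feature.n_levels)
    if feature.kind == "poisson":
        return PoissonFamily()
    raise ValueError(feature.kind)


def elliptical_log_predictive(families, thetas, x) -> float:
    """Factorized log predictive across independent features.

    ``x`` entries that are NaN are treated as missing and contribute 0
    (they are marginalized out of the factorized density).
    """
    x = np.atleast_1d(np.asarray(x, float))
    if len(thetas) != x.shape[0] or len(families) != x.shape[0]:
        raise ValueError("schema / vector length mismatch")
    total = 0.0
    for fam, theta, xm in zip(families, thetas, x):
        if np.isnan(xm):
            continue
        total += fam.log_predictive(theta, xm)
    return total


# ---------------------------------------------------------------------------
# Vectorized engine layer
# ---------------------------------------------------------------------------


class ComponentModel:
    """Per-cluster sufficient statistics plus vectorized assignment costs.

    A model instance is stateless; all mutable quantities live in the
    stats object it creates.  ``costs`` returns ``d_k = -ln f(x | theta_k)``
    for every live cluster, where ``theta_k`` is the conjugate posterior
    from the points currently registered in the stats.  The caller is
    responsible for removing a point before evaluating its own exclusion
    cost.
    """

    dim: int

    def empty_stats(self, capacity: int = 8):
        raise NotImplementedError

    def add(self, stats, k: int, x) -> None:
        raise NotImplementedError

    def remove(self, stats, k: int, x) -> None:
        raise NotImplementedError

    def new_cluster(self, stats) -> int:
        raise NotImplementedError

    def drop(self, stats, k: int) -> None:
        raise NotImplementedError

    def costs(self, stats, x) -> np.ndarray:
        raise NotImplementedError

    def cost_prior(self, x) -> float:
        raise NotImplementedError

    def posterior(self, stats, k: int):
        """Posterior hyperparameters for cluster ``k`` (no exclusion)."""
        raise NotImplementedError

    def sample_prior_feature(self, rng, m: int, size: int) -> np.ndarray:
        """Draws from the prior predictive of feature ``m``."""
        raise NotImplementedError

    def predictive_modes(self, stats, k: int) -> np.ndarray:
        """Per-feature posterior-predictive modes for cluster ``k``."""
        raise NotImplementedError

    def validate(self, X: np.ndarray) -> None:
        """Raise on rows outside the model's support (NaN allowed upstream)."""
        if X.ndim != 2 or X.shape[1] != self.dim:
            raise ValueError(f"expected an (N, {self.dim}) data matrix, got {X.shape}")

    # -- generic helpers -------------------------------------------------

    def exclusion_cost_sum(self, X: np.ndarray, z: np.ndarray, stats) -> float:
        """Sum over points of ``d_{i, z_i}`` with point ``i`` excluded.

        Generic remove/evaluate/re-add loop; the concrete engines
        override this with per-cluster vectorized versions.
        """
        total = 0.0
        for i in range(X.shape[0]):
            x = X[i]
            k = int(z[i])
            self.remove(stats, k, x)
            total += float(self.costs(stats, x)[k])
            self.add(stats, k, x)
        return total

    def cluster_log_marginal(self, Xk) -> float:
        """Exact log marginal likelihood of a point set under the prior.

        Chain rule of conjugate predictives; the result is order
        invariant.
        """
        stats = self.empty_stats(capacity=1)
        self.new_cluster(stats)
        total = 0.0
        for x in np.atleast_2d(Xk):
            total -= float(self.costs(stats, x)[0])
            self.add(stats, 0, x)
        return total

    def init_stats(self, X: np.ndarray, z: np.ndarray, K: int):
        stats = self.empty_stats(capacity=max(8, K))
        for _ in range(K):
            self.new_cluster(stats)
        for x, k in zip(X, z):
            self.add(stats, int(k), x)
        return stats


class _Stats:
    """Minimal container for cluster counts and model arrays."""

    __slots__ = ("K", "counts", "arrays")

    def __init__(self, capacity: int, arrays: dict):
        self.K = 0
        self.counts = np.zeros(capacity, dtype=np.int64)
        self.arrays = arrays

    @property
    def capacity(self) -> int:
        return self.counts.shape[0]

    def grow(self) -> None:
        cap = self.capacity
        self.counts = np.concatenate([self.counts, np.zeros(cap, np.int64)])
        for name, arr in self.arrays.items():
            pad = np.zeros((cap,) + arr.shape[1:], dtype=arr.dtype)
            self.arrays[name] = np.concatenate([arr, pad])


class SphericalGaussianModel(ComponentModel):
    """Spherical Gaussian clusters with known variance (vectorized)."""

    def __init__(self, prior: SphericalGaussianPrior):
        self.prior = prior
        self.dim = prior.mu0.shape[0]

    def empty_stats(self, capacity: int = 8):
        return _Stats(capacity, {"sum": np.zeros((capacity, self.dim))})

    def add(self, stats, k, x):
        stats.counts[k] += 1
        stats.arrays["sum"][k] += x

    def remove(self, stats, k, x):
        stats.counts[k] -= 1
        stats.arrays["sum"][k] -= x

    def new_cluster(self, stats):
        if stats.K == stats.capacity:
            stats.grow()
        k = stats.K
        stats.counts[k] = 0
        stats.arrays["sum"][k] = 0.0
        stats.K += 1
        return k

    def drop(self, stats, k):
        K = stats.K
        stats.counts[k:K - 1] = stats.counts[k + 1:K]
        stats.arrays["sum"][k:K - 1] = stats.arrays["sum"][k + 1:K]
        stats.K = K - 1

    def _posterior_arrays(self, stats):
        p = self.prior
        n = stats.counts[: stats.K]
        var_k = 1.0 / (1.0 / p.var0 + n / p.var)
        mu_k = var_k[:, None] * (p.mu0 / p.var0 + stats.arrays["sum"][: stats.K] / p.var)
        return mu_k, var_k

    def costs(self, stats, x):
        mu_k, var_k = self._posterior_arrays(stats)
        v = var_k + self.prior.var
        sq = np.einsum("kd,kd->k", x - mu_k, x - mu_k)
        return 0.5 * sq / v + 0.5 * self.dim * (np.log(v) + LOG_2PI)

    def cost_prior(self, x):
        p = self.prior
        v = p.var0 + p.var
        return float(0.5 * np.sum((x - p.mu0) ** 2) / v + 0.5 * self.dim * (np.log(v) + LOG_2PI))

    def posterior(self, stats, k):
        mu_k, var_k = self._posterior_arrays(stats)
        return SphericalGaussianPrior(mu_k[k], float(var_k[k]), self.prior.var)

    def exclusion_cost_sum(self, X, z, stats):
        p = self.prior
        total = 0.0
        for k in range(stats.K):
            Xk = X[z == k]
            n_excl = Xk.shape[0] - 1
            var_k = 1.0 / (1.0 / p.var0 + n_excl / p.var)
            mu = var_k * (p.mu0 / p.var0 + (stats.arrays["sum"][k] - Xk) / p.var)
            v = var_k + p.var
            sq = ((Xk - mu) ** 2).sum(axis=1)
            total += float(np.sum(0.5 * sq / v + 0.5 * self.dim * (np.log(v) + LOG_2PI)))
        return total

    def sample_prior_feature(self, rng, m, size):
        p = self.prior
        return rng.normal(p.mu0[m], np.sqrt(p.var0 + p.var), size=size)

    def predictive_modes(self, stats, k):
        mu_k, _ = self._posterior_arrays(stats)
        return mu_k[k].copy()

    def validate(self, X):
        super().validate(X)
        if not np.all(np.isfinite(X)):
            raise SupportError("spherical Gaussian model requires finite data")


class FullGaussianModel(ComponentModel):
    """Full-covariance Gaussian clusters under an NIW prior (vectorized).

    Per-cluster statistics are the count, the coordinate sum and the raw
    outer-product sum, from which the NIW posterior and its Student-t
    predictive are reconstituted on demand.
    """

    def __init__(self, prior: NIWPrior):
        self.prior = prior
        self.dim = prior.dim
        self._m0outer = prior.kappa0 * np.outer(prior.m0, prior.m0)
        self._lg_table = None

    def empty_stats(self, capacity: int = 8):
        d = self.dim
        return _Stats(
            capacity,
            {"sum": np.zeros((capacity, d)), "sq": np.zeros((capacity, d, d))},
        )

    def add(self, stats, k, x):
        stats.counts[k] += 1
        stats.arrays["sum"][k] += x
        stats.arrays["sq"][k] += np.outer(x, x)

    def remove(self, stats, k, x):
        stats.counts[k] -= 1
        stats.arrays["sum"][k] -= x
        stats.arrays["sq"][k] -= np.outer(x, x)

    def new_cluster(self, stats):
        if stats.K == stats.capacity:
            stats.grow()
        k = stats.K
        stats.counts[k] = 0
        stats.arrays["sum"][k] = 0.0
        stats.arrays["sq"][k] = 0.0
        stats.K += 1
        return k

    def drop(self, stats, k):
        K = stats.K
        stats.counts[k:K - 1] = stats.counts[k + 1:K]
        stats.arrays["sum"][k:K - 1] = stats.arrays["sum"][k + 1:K]
        stats.arrays["sq"][k:K - 1] = stats.arrays["sq"][k + 1:K]
        stats.K = K - 1

    def _posterior_arrays(self, stats):
        p = self.prior
        K = stats.K
        n = stats.counts[:K].astype(float)
        kappa_n = p.kappa0 + n
        nu_n = p.nu0 + n
        m_n = (p.kappa0 * p.m0 + stats.arrays["sum"][:K]) / kappa_n[:, None]
        # S_n = S0 + sum(x x^T) + kappa0 m0 m0^T - kappa_n m_n m_n^T
        S_n = (
            p.S0
            + stats.arrays["sq"][:K]
            + self._m0outer
            - kappa_n[:, None, None] * np.einsum("ki,kj->kij", m_n, m_n)
        )
        return m_n, kappa_n, nu_n, S_n

    @staticmethod
    def _t_cost(x, loc, kappa, nu, S, d, lg=None):
        """Vectorized -log Student-t density for stacked NIW posteriors.

        ``lg`` optionally supplies the precomputed log-gamma ratio
        ``lnG((df+d)/2) - lnG(df/2)``, which depends only on the count.
        """
        df = nu - d + 1
        factor = (kappa + 1.0) / (kappa * df)
        scale = S * factor[:, None, None]
        dev = x - loc
        if d == 1:
            s = scale[:, 0, 0]
            logdet = np.log(s)
            quad = dev[:, 0] ** 2 / s
        elif d == 2:
            # explicit 2x2 inverse: the generic stacked solve dominates
            # the sweep cost otherwise
            a = scale[:, 0, 0]
            b = scale[:, 0, 1]
            c = scale[:, 1, 0]
            e = scale[:, 1, 1]
            det = a * e - b * c
            logdet = np.log(det)
            dx, dy = dev[:, 0], dev[:, 1]
            quad = (e * dx * dx - (b + c) * dx * dy + a * dy * dy) / det
        else:
            sign, logdet = np.linalg.slogdet(scale)
            sol = np.linalg.solve(scale, dev[..., None])[..., 0]
            quad = np.einsum("kd,kd->k", dev, sol)
        if lg is None:
            lg = gammaln(0.5 * (df + d)) - gammaln(0.5 * df)
        lp = (
            lg
            - 0.5 * d * (np.log(df) + np.log(np.pi))
            - 0.5 * logdet
            - 0.5 * (df + d) * np.log1p(quad / df)
        )
        return -lp

    def _lg(self, n):
        """Cached log-gamma ratio of the t normalizer, indexed by count."""
        need = int(np.max(n)) + 1
        if self._lg_table is None or self._lg_table.shape[0] < need:
            grid = np.arange(max(need, 1024))
            df = self.prior.nu0 + grid - self.dim + 1
            self._lg_table = gammaln(0.5 * (df + self.dim)) - gammaln(0.5 * df)
        return self._lg_table[np.asarray(n, dtype=np.intp)]

    def costs(self, stats, x):
        m_n, kappa_n, nu_n, S_n = self._posterior_arrays(stats)
        lg = self._lg(stats.counts[: stats.K])
        return self._t_cost(x, m_n, kappa_n, nu_n, S_n, self.dim, lg=lg)

    def cost_prior(self, x):
        p = self.prior
        return float(
            self._t_cost(
                np.asarray(x, float)[None, :],
                p.m0[None, :],
                np.array([p.kappa0]),
                np.array([p.nu0]),
                p.S0[None, :, :],
                self.dim,
            )[0]
        )

    def posterior(self, stats, k):
        m_n, kappa_n, nu_n, S_n = self._posterior_arrays(stats)
        return NIWPrior(m_n[k], float(kappa_n[k]), float(nu_n[k]), S_n[k])

    def exclusion_cost_sum(self, X, z, stats):
        p = self.prior
        d = self.dim
        total = 0.0
        for k in range(stats.K):
            Xk = X[z == k]
            m_cnt = Xk.shape[0]
            n_excl = m_cnt - 1
            kappa = np.full(m_cnt, p.kappa0 + n_excl)
            nu = np.full(m_cnt, p.nu0 + n_excl)
            m_n = (p.kappa0 * p.m0 + stats.arrays["sum"][k] - Xk) / kappa[:, None]
            S_n = (
                p.S0
                + (stats.arrays["sq"][k] - np.einsum("mi,mj->mij", Xk, Xk))
                + self._m0outer
                - kappa[:, None, None] * np.einsum("mi,mj->mij", m_n, m_n)
            )
            total += float(np.sum(self._t_cost(Xk, m_n, kappa, nu, S_n, d)))
        return total

    def sample_prior_feature(self, rng, m, size):
        p = self.prior
        df = p.nu0 - self.dim + 1
        scale = p.S0[m, m] * (p.kappa0 + 1) / (p.kappa0 * df)
        return p.m0[m] + np.sqrt(scale) * rng.standard_t(df, size=size)

    def predictive_modes(self, stats, k):
        m_n, _, _, _ = self._posterior_arrays(stats)
        return m_n[k].copy()

    def validate(self, X):
        super().validate(X)
        if not np.all(np.isfinite(X)):
            raise SupportError("full Gaussian model requires finite data")


class _FeatureEngine:
    """Vectorized sufficient statistics for one feature of the elliptical model.

    Keeps its own per-cluster observation count so that missing entries
    (NaN) never enter the statistics.
    """

    def __init__(self, feature: Feature, prior):
        self.feature = feature
        self.prior = prior
        self.kind = feature.kind
        self.family = family_for(feature)
        if self.kind == "gaussian_full" and prior.dim != 1:
            raise ValueError("elliptical gaussian_full features must be one-dimensional")

    def empty(self, capacity):
        arrs = {"n": np.zeros(capacity)}
        if self.kind == "categorical":
            arrs["lvl"] = np.zeros((capacity, self.feature.n_levels))
        else:
            arrs["s"] = np.zeros(capacity)
            if self.kind == "gaussian_full":
                arrs["s2"] = np.zeros(capacity)
        return arrs

    def add(self, arrs, k, xm, sign=1.0):
        arrs["n"][k] += sign
        if self.kind == "categorical":
            arrs["lvl"][k, int(xm)] += sign
        else:
            arrs["s"][k] += sign * xm
            if self.kind == "gaussian_full":
                arrs["s2"][k] += sign * xm * xm

    def costs(self, arrs, K, xm):
        """-log predictive of ``xm`` under each cluster's posterior."""
        n = arrs["n"][:K]
        p = self.prior
        kind = self.kind
        if kind == "gaussian_spherical":
            s = arrs["s"][:K]
            var_k = 1.0 / (1.0 / p.var0 + n / p.var)
            mu_k = var_k * (p.mu0[0] / p.var0 + s / p.var)
            v = var_k + p.var
            return 0.5 * (xm - mu_k) ** 2 / v + 0.5 * (np.log(v) + LOG_2PI)
        if kind == "gaussian_full":
            s, s2 = arrs["s"][:K], arrs["s2"][:K]
            kap = p.kappa0 + n
            nu = p.nu0 + n
            mn = (p.kappa0 * p.m0[0] + s) / kap
            Sn = p.S0[0, 0] + s2 + p.kappa0 * p.m0[0] ** 2 - kap * mn * mn
            df = nu
            scale = Sn * (kap + 1.0) / (kap * df)
            lp = (
                gammaln(0.5 * (df + 1))
                - gammaln(0.5 * df)
                - 0.5 * (np.log(df) + np.log(np.pi) + np.log(scale))
                - 0.5 * (df + 1) * np.log1p((xm - mn) ** 2 / (scale * df))
            )
            return -lp
        if kind == "bernoulli":
            a = p.a + arrs["s"][:K]
            b = p.b + n - arrs["s"][:K]
            p1 = a / (a + b)
            return -np.log(p1 if xm == 1 else 1.0 - p1)
        if kind == "binomial":
            nt = self.feature.n_trials
            a = p.a + arrs["s"][:K]
            b = p.b + nt * n - arrs["s"][:K]
            comb = gammaln(nt + 1) - gammaln(xm + 1) - gammaln(nt - xm + 1)
            return -(comb + betaln(a + xm, b + nt - xm) - betaln(a, b))
        if kind == "categorical":
            alpha = p.alpha[None, :] + arrs["lvl"][:K]
            return -(np.log(alpha[:, int(xm)]) - np.log(alpha.sum(axis=1)))
        if kind == "poisson":
            a = p.a + arrs["s"][:K]
            b = p.b + n
            return -(
                gammaln(a + xm)
                - gammaln(a)
                - gammaln(xm + 1)
                + a * np.log(b / (b + 1.0))
                - xm * np.log(b + 1.0)
            )
        raise ValueError(kind)

    def posterior(self, arrs, k):
        n = arrs["n"][k]
        p = self.prior
        kind = self.kind
        if kind == "gaussian_spherical":
            var_k = 1.0 / (1.0 / p.var0 + n / p.var)
            mu_k = var_k * (p.mu0[0] / p.var0 + arrs["s"][k] / p.var)
            return SphericalGaussianPrior(np.array([mu_k]), float(var_k), p.var)
        if kind == "gaussian_full":
            kap = p.kappa0 + n
            nu = p.nu0 + n
            mn = (p.kappa0 * p.m0[0] + arrs["s"][k]) / kap
            Sn = p.S0[0, 0] + arrs["s2"][k] + p.kappa0 * p.m0[0] ** 2 - kap * mn * mn
            return NIWPrior(np.array([mn]), float(kap), float(nu), np.array([[Sn]]))
        if kind in ("bernoulli",):
            return BetaPrior(p.a + arrs["s"][k], p.b + n - arrs["s"][k])
        if kind == "binomial":
            nt = self.feature.n_trials
            return BetaPrior(p.a + arrs["s"][k], p.b + nt * n - arrs["s"][k])
        if kind == "categorical":
            return DirichletPrior(p.alpha + arrs["lvl"][k])
        if kind == "poisson":
            return GammaPrior(p.a + arrs["s"][k], p.b + n)
        raise ValueError(kind)

    def sample_prior(self, rng, size):
        p = self.prior
        kind = self.kind
        if kind == "gaussian_spherical":
            return rng.normal(p.mu0[0], np.sqrt(p.var0 + p.var), size=size)
        if kind == "gaussian_full":
            scale = p.S0[0, 0] * (p.kappa0 + 1) / (p.kappa0 * p.nu0)
            return p.m0[0] + np.sqrt(scale) * rng.standard_t(p.nu0, size=size)
        if kind == "bernoulli":
            return (rng.random(size) < p.a / (p.a + p.b)).astype(float)
        if kind == "binomial":
            lam = rng.beta(p.a, p.b, size=size)
            return rng.binomial(self.feature.n_trials, lam).astype(float)
        if kind == "categorical":
            probs = p.alpha / p.alpha.sum()
            return rng.choice(len(probs), p=probs, size=size).astype(float)
        if kind == "poisson":
            lam = rng.gamma(p.a, 1.0 / p.b, size=size)
            return rng.poisson(lam).astype(float)
        raise ValueError(kind)

    def mode(self, arrs, k, previous=None):
        """Posterior-predictive mode; discrete ties keep ``previous``."""
        hyper = self.posterior(arrs, k)
        kind = self.kind
        if kind in ("gaussian_spherical", "gaussian_full"):
            return float(hyper.m0[0]) if kind == "gaussian_full" else float(hyper.mu0[0])
        if kind == "bernoulli":
            p1 = hyper.a / (hyper.a + hyper.b)
            if p1 == 0.5 and previous is not None:
                return float(previous)
            return 1.0 if p1 > 0.5 else 0.0
        if kind == "binomial":
            fam = self.family
            vals = np.arange(self.feature.n_trials + 1)
            masses = np.array([fam.log_predictive(hyper, v) for v in vals])
            return float(vals[int(np.argmax(masses))])
        if kind == "categorical":
            return float(int(np.argmax(hyper.alpha)))
        if kind == "poisson":
            fam = self.family
            # negative-binomial mode: scan until mass decreases
            best_v, best_lp = 0, fam.log_predictive(hyper, 0)
            v = 1
            while True:
                lp = fam.log_predictive(hyper, v)
                if lp <= best_lp:
                    break
                best_v, best_lp = v, lp
                v += 1
            return float(best_v)
        raise ValueError(kind)


class EllipticalModel(ComponentModel):
    """Factorized mixed-type model: independent features, one family each.

    NaN entries are treated as missing: they are excluded from sufficient
    statistics and contribute nothing to assignment costs.
    """

    def __init__(self, schema: FeatureSchema, priors: Sequence):
        if len(priors) != len(schema):
            raise ValueError("need one prior per schema feature")
        self.schema = schema
        self.engines = [_FeatureEngine(f, p) for f, p in zip(schema, priors)]
        self.dim = len(schema)
        self._prior_stats = None

    def empty_stats(self, capacity: int = 8):
        arrays = {}
        for m, eng in enumerate(self.engines):
            for name, arr in eng.empty(capacity).items():
                arrays[f"{m}:{name}"] = arr
        return _Stats(capacity, arrays)

    def _view(self, stats, m):
        prefix = f"{m}:"
        return {name[len(prefix):]: arr for name, arr in stats.arrays.items() if name.startswith(prefix)}

    def add(self, stats, k, x):
        stats.counts[k] += 1
        for m, eng in enumerate(self.engines):
            if not np.isnan(x[m]):
                eng.add(self._view(stats, m), k, x[m], 1.0)

    def remove(self, stats, k, x):
        stats.counts[k] -= 1
        for m, eng in enumerate(self.engines):
            if not np.isnan(x[m]):
                eng.add(self._view(stats, m), k, x[m], -1.0)

    def new_cluster(self, stats):
        if stats.K == stats.capacity:
            stats.grow()
        k = stats.K
        stats.counts[k] = 0
        for arr in stats.arrays.values():
            arr[k] = 0.0
        stats.K += 1
        return k

    def drop(self, stats, k):
        K = stats.K
        stats.counts[k:K - 1] = stats.counts[k + 1:K]
        for arr in stats.arrays.values():
            arr[k:K - 1] = arr[k + 1:K]
        stats.K = K - 1

    def costs(self, stats, x):
        total = np.zeros(stats.K)
        for m, eng in enumerate(self.engines):
            if not np.isnan(x[m]):
                total += eng.costs(self._view(stats, m), stats.K, x[m])
        return total

    def cost_prior(self, x):
        if self._prior_stats is None:
            self._prior_stats = self.empty_stats(capacity=1)
            self.new_cluster(self._prior_stats)
        return float(self.costs(self._prior_stats, x)[0])

    def posterior(self, stats, k):
        return [eng.posterior(self._view(stats, m), k) for m, eng in enumerate(self.engines)]

    def sample_prior_feature(self, rng, m, size):
        return self.engines[m].sample_prior(rng, size)

    def predictive_modes(self, stats, k, previous=None):
        out = np.empty(self.dim)
        for m, eng in enumerate(self.engines):
            prev = None if previous is None else previous[m]
            out[m] = eng.mode(self._view(stats, m), k, previous=prev)
        return out

    def validate(self, X):
        super().validate(X)
        for m, eng in enumerate(self.engines):
            col = X[:, m]
            obs = col[~np.isnan(col)]
            name = self.schema[m].name
            if eng.kind in ("gaussian_spherical", "gaussian_full"):
                if not np.all(np.isfinite(obs)):
                    raise SupportError(f"non-finite value in Gaussian feature {name!r}")
                continue
            if obs.size and np.any(obs != np.round(obs)):
                raise SupportError(f"non-integer value in discrete feature {name!r}")
            lo, hi = 0, np.inf
            if eng.kind == "bernoulli":
                hi = 1
            elif eng.kind == "binomial":
                hi = self.schema[m].n_trials
            elif eng.kind == "categorical":
                hi = self.schema[m].n_levels - 1
            if obs.size and (obs.min() < lo or obs.max() > hi):
                raise SupportError(
                    f"value outside support in feature {name!r}: "
                    f"range [{obs.min()}, {obs.max()}] vs [{lo}, {hi}]"
                )
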