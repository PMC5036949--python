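"""K-means, Gaussian-mixture E-M, and BIC-over-K model selection.

These are the comparison methods for the synthetic benchmark.  K-means
is Lloyd's algorithm with k-means++ seeding; the E-M routine fits a
full-covariance Gaussian mixture; ``bic_select`` sweeps a range of K
with repeated randomized K-means fits and reports the K with the best
BIC score under the spherical-Gaussian likelihood implied by K-means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KMeansResult",
    "GmmResult",
    "kmeans_pp_init",
    "kmeans",
    "kmeans_best_of",
    "gmm_em",
    "bic_score",
    "bic_select",
]


@dataclass
class KMeansResult:
    centroids: np.ndarray
    assignments: np.ndarray
    objective: float  # E = half the total within-cluster squared distance
    iterations: int
    objective_trace: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclass
class GmmResult:
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    responsibilities: np.ndarray
    log_likelihood_trace: list[float] = field(default_factory=list)

    @property
    def assignments(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)


def _sq_dists(X, centroids):
    return ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)


def kmeans_pp_init(X, k: int, rng) -> np.ndarray:
    """k-means++ seeding: new seeds drawn with probability proportional to
    the squared distance from the nearest existing seed."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = X[rng.integers(n)]
        else:
            centroids[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centroids[j]) ** 2).sum(axis=1))
    return centroids


def kmeans(X, k: int, init="k-means++", epsilon: float = 1e-6, seed=None,
           max_iterations: int = 500, empty_action: str = "reseed") -> KMeansResult:
    """Lloyd's algorithm.

    ``init`` is ``"k-means++"``, ``"random"`` (uniform data points) or an
    explicit ``(k, D)`` centroid array.  An emptied cluster is either
    re-seeded at the farthest point (default) or dropped.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= N")
    if empty_action not in ("reseed", "drop"):
        raise ValueError("empty_action must be 'reseed' or 'drop'")
    rng = np.random.default_rng(seed)
    if isinstance(init, str):
        if init == "k-means++":
            centroids = kmeans_pp_init(X, k, rng)
        elif init == "random":
            centroids = X[rng.choice(n, size=k, replace=False)].copy()
        else:
            raise ValueError(init)
    else:
        centroids = np.array(init, float)
        if centroids.shape != (k, X.shape[1]):
            raise ValueError("explicit init has the wrong shape")
    e_prev = np.inf
    trace = []
    for it in range(1, max_iterations + 1):
        d2 = _sq_dists(X, centroids)
        z = np.argmin(d2, axis=1)
        e = 0.5 * float(d2[np.arange(n), z].sum())
        trace.append(e)
        for j in range(centroids.shape[0]):
            members = z == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
            elif empty_action == "reseed":
                far = int(np.argmax(d2[np.arange(n), z]))
                centroids[j] = X[far]
            # 'drop': leave the centroid; it simply stays empty
        if e_prev - e < epsilon:
            break
        e_prev = e
    d2 = _sq_dists(X, centroids)
    z = np.argmin(d2, axis=1)
    e = 0.5 * float(d2[np.arange(n), z].sum())
    return KMeansResult(centroids=centroids, assignments=z, objective=e,
                        iterations=it, objective_trace=trace)


def kmeans_best_of(X, k: int, restarts: int, seed=None, **kwargs) -> KMeansResult:
    """Lowest-objective result over ``restarts`` randomized fits."""
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        res = kmeans(X, k, seed=rng.integers(2**63), **kwargs)
        if best is None or res.objective < best.objective:
            best = res
    return best


def gmm_em(X, k: int, init="kmeans", epsilon: float = 1e-8, seed=None,
           max_iterations: int = 500, reg: float = 1e-6,
           spherical_sigma: float | None = None) -> GmmResult:
    """E-M for a full-covariance Gaussian mixture.

    ``init`` is ``"kmeans"`` (k-means++ means, global covariance, uniform
    weights) or an explicit ``(weights, means, covariances)`` tuple — the
    latter allows seeding with known generating parameters.  A small
    diagonal jitter regularizes near-singular covariances.

    With ``spherical_sigma`` set, covariances are frozen at that shared
    spherical value and only weights/means update; shrinking it towards
    zero reproduces the hard nearest-centroid assignments of K-means
    (the small-variance asymptotic limit).
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, d = X.shape
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < N")
    rng = np.random.default_rng(seed)
    if init == "kmeans":
        means = kmeans_pp_init(X, k, rng)
        cov = np.cov(X.T, bias=True).reshape(d, d)
        covs = np.repeat(cov[None], k, axis=0)
        weights = np.full(k, 1.0 / k)
    else:
        weights, means, covs = (np.array(a, float) for a in init)
    if spherical_sigma is not None:
        covs = np.repeat((spherical_sigma**2 * np.eye(d))[None], k, axis=0)
        reg = 0.0
    ll_prev = -np.inf
    trace = []
    gamma = np.full((n, k), 1.0 / k)
    for _ in range(max_iterations):
        # E-step
        log_resp = np.empty((n, k))
        for j in range(k):
            cov_j = covs[j] + reg * np.eye(d)
            sign, logdet = np.linalg.slogdet(cov_j)
            if sign <= 0:
                raise np.linalg.LinAlgError("covariance not positive definite")
            dev = X - means[j]
            sol = np.linalg.solve(cov_j, dev.T).T
            quad = np.einsum("nd,nd->n", dev, sol)
            log_resp[:, j] = np.log(weights[j]) - 0.5 * (quad + logdet + d * np.log(2 * np.pi))
        ll = float(logsumexp(log_resp, axis=1).sum())
        gamma = np.exp(log_resp - logsumexp(log_resp, axis=1, keepdims=True))
        trace.append(ll)
        if ll - ll_prev < epsilon and np.isfinite(ll_prev):
            break
        ll_prev = ll
        # M-step
        s = gamma.sum(axis=0)
        weights = s / n
        means = (gamma.T @ X) / s[:, None]
        if spherical_sigma is None:
            for j in range(k):
                dev = X - means[j]
                covs[j] = (gamma[:, j, None] * dev).T @ dev / s[j]
    return GmmResult(weights=weights, means=means, covariances=covs,
                     responsibilities=gamma, log_likelihood_trace=trace)


def bic_score(X, result: KMeansResult) -> float:
    """BIC (to be maximized) for a K-means fit.

    Scores the spherical Gaussian mixture implied by K-means: shared
    maximum-likelihood variance ``sigma^2 = SSE / (N D)``, mixing
    proportions ``N_k / N``, and the classification log likelihood

        sum_k N_k ln(N_k / N) - (N D / 2) (ln(2 pi sigma^2) + 1).

    Parameter count is ``K D + (K - 1) + 1`` (centroids, proportions,
    shared variance); ``bic = loglik - (p / 2) ln N``.  The proportion
    term is what stops the score from always preferring more clusters:
    a pure within-cluster likelihood cannot (splitting a cluster always
    shrinks the SSE).
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, d = X.shape
    sse = 2.0 * result.objective
    k = result.k
    if sse <= 0:
        return np.inf
    counts = np.bincount(result.assignments, minlength=k)
    counts = counts[counts > 0]
    sigma2 = sse / (n * d)
    loglik = float((counts * np.log(counts / n)).sum()) \
        - 0.5 * n * d * (np.log(2 * np.pi * sigma2) + 1.0)
    params = k * d + (k - 1) + 1
    return float(loglik - 0.5 * params * np.log(n))


def bic_select(X, k_range, cycles: int = 100, seed=None, epsilon: float = 1e-6):
    """Pick K by the best BIC over repeated randomized K-means fits.

    Each cycle fits K-means once per candidate K with a fresh random
    seeding; the returned K is the argmax of the BIC score over all
    (cycle, K) pairs.  Also returns the full score table as a list of
    ``{"cycle", "k", "bic", "objective"}`` rows.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    rng = np.random.default_rng(seed)
    table = []
    best_k, best_bic = None, -np.inf
    for cycle in range(cycles):
        for k in k_range:
            res = kmeans(X, k, seed=rng.integers(2**63), epsilon=epsilon)
            bic = bic_score(X, res)
            table.append({"cycle": cycle, "k": k, "bic": bic, "objective": res.objective})
            if bic > best_bic:
                best_bic, best_k = bic, k
    return best_k, table
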