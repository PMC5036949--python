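"""Hyperparameter estimation: empirical Bayes, MAP for the concentration,
greedy coordinate search, and cross-validation.

The default experimental protocol keeps the concentration fixed (at 3)
and sets the component prior hyperparameters from global data moments as
a maximum-likelihood stand-in for empirical Bayes; the routines here are
opt-in alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, polygamma

from . import core, prediction
from .exp_family import (
    BetaPrior,
    DirichletPrior,
    FeatureSchema,
    GammaPrior,
    NIWPrior,
    SphericalGaussianPrior,
)

__all__ = [
    "N0Prior",
    "empirical_bayes_theta0",
    "eb_niw",
    "eb_spherical",
    "map_n0",
    "greedy_restart_search",
    "cv_select",
]


@dataclass(frozen=True)
class N0Prior:
    """Gamma prior on the concentration parameter (shape ``a``, rate ``b``)."""

    a: float = 1.0
    b: float = 0.1

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Gamma prior parameters must be positive")


# ---------------------------------------------------------------------------
# Empirical Bayes (maximum-likelihood moment matching)
# ---------------------------------------------------------------------------

_EB_STRENGTH = 1.0  # unit-information default for the discrete families
_LEVEL_FLOOR = 0.01


def eb_niw(X, kappa0: float = 1.0, nu0: float | None = None) -> NIWPrior:
    """NIW prior centred on the global mean and covariance."""
    X = np.atleast_2d(np.asarray(X, float))
    d = X.shape[1]
    cov = np.cov(X.T, bias=True).reshape(d, d)
    if np.any(np.diag(cov) <= 0):
        raise ValueError("zero-variance feature; remove it or supply an explicit prior")
    if nu0 is None:
        nu0 = d + 2.0
    return NIWPrior(X.mean(axis=0), kappa0, nu0, cov)


def eb_spherical(X, var: float) -> SphericalGaussianPrior:
    """Known-variance spherical prior from global moments.

    ``var`` is the known within-cluster variance, which cannot be
    estimated from the pooled data and must be supplied.
    """
    X = np.atleast_2d(np.asarray(X, float))
    var0 = float(X.var(axis=0).mean())
    if var0 <= 0:
        raise ValueError("zero-variance feature; remove it or supply an explicit prior")
    return SphericalGaussianPrior(X.mean(axis=0), var0, var)


def empirical_bayes_theta0(X, schema: FeatureSchema, strength: float = _EB_STRENGTH) -> list:
    """Per-feature prior hyperparameters from global data moments.

    Gaussian features get moment-matched location/scale priors; the
    discrete families are matched to global frequencies or means with a
    total prior strength of ``strength`` pseudo-observations.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 0:
        raise ValueError("dataset is empty")
    if X.shape[1] != len(schema):
        raise ValueError("data width does not match schema")
    priors = []
    for m, feat in enumerate(schema):
        col = X[:, m]
        col = col[~np.isnan(col)]
        if col.size == 0:
            raise ValueError(f"feature {feat.name!r} has no observed values")
        if feat.kind == "gaussian_full":
            var = float(col.var())
            if var <= 0:
                raise ValueError(f"zero-variance feature {feat.name!r}; remove or override")
            priors.append(NIWPrior(np.array([col.mean()]), 1.0, 3.0, np.array([[var]])))
        elif feat.kind == "gaussian_spherical":
            var = float(col.var())
            if var <= 0:
                raise ValueError(f"zero-variance feature {feat.name!r}; remove or override")
            priors.append(SphericalGaussianPrior(np.array([col.mean()]), var, var))
        elif feat.kind == "bernoulli":
            p = float(col.mean())
            if p <= 0 or p >= 1:
                raise ValueError(f"degenerate Bernoulli feature {feat.name!r} (all equal)")
            priors.append(BetaPrior(strength * p, strength * (1 - p)))
        elif feat.kind == "binomial":
            p = float(col.mean()) / feat.n_trials
            if p <= 0 or p >= 1:
                raise ValueError(f"degenerate binomial feature {feat.name!r}")
            priors.append(BetaPrior(strength * p, strength * (1 - p)))
        elif feat.kind == "categorical":
            freqs = np.bincount(col.astype(int), minlength=feat.n_levels) / col.size
            alpha = strength * np.maximum(freqs, _LEVEL_FLOOR)
            priors.append(DirichletPrior(alpha))
        elif feat.kind == "poisson":
            mean = float(col.mean())
            if mean <= 0:
                raise ValueError(f"degenerate Poisson feature {feat.name!r} (all zero)")
            priors.append(GammaPrior(strength * mean, strength))
        else:  # pragma: no cover
            raise ValueError(feat.kind)
    return priors


# ---------------------------------------------------------------------------
# MAP estimate of the concentration
# ---------------------------------------------------------------------------


def _log_post_grad(t: float, n: int, k_plus: int, prior: N0Prior):
    """Log posterior of ln(n0) (up to a constant) and its first two derivatives."""
    n0 = np.exp(t)
    from scipy.special import gammaln

    lp = gammaln(n0) - gammaln(n0 + n) + (k_plus + prior.a - 1) * np.log(n0) - prior.b * n0
    dn0 = digamma(n0) - digamma(n0 + n) + (k_plus + prior.a - 1) / n0 - prior.b
    grad = dn0 * n0
    d2n0 = polygamma(1, n0) - polygamma(1, n0 + n) - (k_plus + prior.a - 1) / n0**2
    hess = d2n0 * n0**2 + grad
    return lp, grad, hess


def map_n0(n: int, k_plus: int, prior: N0Prior = N0Prior(), tol: float = 1e-8,
           max_newton: int = 100) -> float:
    """Mode of the concentration posterior given ``N`` and ``K+`` clusters.

    Newton iterations on ``ln n0`` (the objective is log-concave there),
    with a bracketed bisection fallback if Newton fails to settle.
    """
    if k_plus < 1:
        raise ValueError("k_plus must be >= 1")
    t = 0.0
    for _ in range(max_newton):
        _, g, h = _log_post_grad(t, n, k_plus, prior)
        if h >= 0:  # outside the concave basin; nudge along the gradient
            step = np.sign(g)
        else:
            step = -g / h
        step = np.clip(step, -2.0, 2.0)
        t_new = t + step
        if abs(t_new - t) < tol * max(1.0, abs(t)):
            return float(np.exp(t_new))
        t = t_new
    warnings.warn("Newton did not converge for map_n0; falling back to bisection")
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        _, g, _ = _log_post_grad(mid, n, k_plus, prior)
        if g > 0:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


# ---------------------------------------------------------------------------
# Search protocols
# ---------------------------------------------------------------------------


def greedy_restart_search(X, build_model, grids: dict, config: core.MapDpConfig):
    """Coordinate descent over finite hyperparameter grids.

    ``build_model(**params)`` must return a component model given one
    value per grid key (the key ``"n0"`` is routed to the fit config
    instead).  Each candidate is scored by the converged NLL *including*
    the partition-prior constant, so scores are comparable across
    different concentrations.  Returns ``(best_params, table)`` where
    the table lists every evaluated candidate and its score.
    """
    keys = list(grids)
    if any(len(grids[k]) == 0 for k in keys):
        raise ValueError("grids must be non-empty")
    current = {k: grids[k][0] for k in keys}
    table = []

    def score(params):
        cfg_kwargs = vars(config).copy()
        n0 = params.get("n0", config.n0)
        cfg_kwargs["n0"] = n0
        cfg = core.MapDpConfig(**cfg_kwargs)
        model = build_model(**{k: v for k, v in params.items() if k != "n0"})
        res = core.fit(X, model, cfg)
        val = res.final_nll - core.crp_constant(n0, X.shape[0])
        table.append({**params, "nll": val, "k": res.k})
        return val

    best_val = score(current)
    for key in keys:
        for cand in grids[key]:
            if cand == current[key]:
                continue
            trial = {**current, key: cand}
            val = score(trial)
            if val < best_val:
                best_val = val
                current = trial
    return current, table


def cv_select(X, build_model, candidates, folds: int, config: core.MapDpConfig, seed=None):
    """Pick hyperparameters by minimum mean held-out negative log likelihood.

    ``candidates`` is a sequence of parameter dicts in the same format
    as :func:`greedy_restart_search`.  Held-out rows are scored with the
    mixture predictive of the fit on the training rows.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, folds)
    if any(len(f) == 0 for f in fold_ids):
        raise ValueError("a fold has zero points; reduce folds")
    scores = []
    for params in candidates:
        n0 = params.get("n0", config.n0)
        cfg_kwargs = vars(config).copy()
        cfg_kwargs["n0"] = n0
        cfg = core.MapDpConfig(**cfg_kwargs)
        fold_scores = []
        for held in fold_ids:
            train = np.setdiff1d(np.arange(n), held)
            model = build_model(**{k: v for k, v in params.items() if k != "n0"})
            res = core.fit(X[train], model, cfg)
            ll = prediction.heldout_log_likelihood(X[held], res.state, model, n0)
            fold_scores.append(-ll / len(held))
        scores.append(float(np.mean(fold_scores)))
    best = int(np.argmin(scores))
    return candidates[best], scores
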