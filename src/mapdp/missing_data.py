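"""Missing feature values inside the clustering loop.

Masked entries (NaN) are excluded from all sufficient statistics, and
the factorized (elliptical) model marginalizes them out of every
assignment cost, so cluster updates use exactly the observed evidence.
Imputations are posterior-predictive modes: each missing entry is set to
the mode of its feature's predictive under the point's cluster, with the
point itself excluded.

``initialize_missing`` draws starting values from the per-feature prior
predictive, and ``update_missing`` performs the mode-imputation step of
the impute/assign alternation; both are usable on their own.  The
high-level :func:`fit_missing` instead fits directly on the masked data
(Rao-Blackwellized assignments) and imputes modes at convergence: the
alternating scheme can lock a point into whatever cluster its first
imputation suggested, because an imputed coordinate treated as observed
can outweigh the truly observed ones.
"""

from __future__ import annotations

import numpy as np

from .core import ClusterState, FitResult, MapDpConfig, fit as _fit
from .exp_family import ComponentModel

__all__ = ["missing_mask", "initialize_missing", "update_missing", "impute_modes", "fit_missing"]


def missing_mask(X) -> np.ndarray:
    """Boolean (row, feature) mask of NaN entries."""
    return np.isnan(np.asarray(X, float))


def initialize_missing(X, model: ComponentModel, seed=None) -> np.ndarray:
    """Fill each masked entry with a prior-predictive draw for its feature."""
    X = np.asarray(X, float).copy()
    rng = np.random.default_rng(seed)
    for m in range(X.shape[1]):
        idx = np.flatnonzero(np.isnan(X[:, m]))
        if idx.size:
            X[idx, m] = model.sample_prior_feature(rng, m, idx.size)
    return X


def _modes_excluding(state: ClusterState, i: int, model: ComponentModel, x, previous):
    """Per-feature predictive modes of cluster ``z_i`` with point ``i`` removed."""
    k = int(state.z[i])
    model.remove(state.stats, k, x)
    try:
        import inspect

        if "previous" in inspect.signature(model.predictive_modes).parameters:
            return np.atleast_1d(model.predictive_modes(state.stats, k, previous=previous))
        return np.atleast_1d(model.predictive_modes(state.stats, k))
    finally:
        model.add(state.stats, k, x)


def update_missing(state: ClusterState, completed: np.ndarray, mask: np.ndarray,
                   model: ComponentModel) -> np.ndarray:
    """Mode-imputation step: replace masked entries in ``completed``.

    ``completed`` must be the matrix the state's statistics were built
    from (imputed entries included); statistics are updated in place so
    they stay consistent with the new imputations.  Discrete ties keep
    the previous imputed value.
    """
    rows = np.flatnonzero(mask.any(axis=1))
    for i in rows:
        k = int(state.z[i])
        x = completed[i]
        modes = _modes_excluding(state, int(i), model, x, previous=x)
        x_new = x.copy()
        x_new[mask[i]] = modes[mask[i]]
        model.remove(state.stats, k, x)
        model.add(state.stats, k, x_new)
        completed[i] = x_new
    return completed


def impute_modes(state: ClusterState, X: np.ndarray, mask: np.ndarray,
                 model: ComponentModel) -> np.ndarray:
    """Completed copy of ``X`` with masked entries at their predictive modes.

    Unlike :func:`update_missing` this leaves the cluster statistics
    untouched (imputed values do not enter them).
    """
    completed = np.asarray(X, float).copy()
    for i in np.flatnonzero(mask.any(axis=1)):
        modes = _modes_excluding(state, int(i), model, X[i], previous=None)
        completed[i, mask[i]] = modes[mask[i]]
    return completed


def fit_missing(X, model: ComponentModel, config: MapDpConfig) -> tuple[FitResult, np.ndarray]:
    """Cluster data with missing entries and return (result, completed X).

    Requires a model whose costs and statistics tolerate NaN entries
    (the factorized elliptical model).  With zero missing entries this
    is identical to :func:`mapdp.core.fit`.
    """
    X = np.asarray(X, dtype=float)
    mask = missing_mask(X)
    if not mask.any():
        res = _fit(X, model, config)
        return res, res.state.X.copy()
    res = _fit(X, model, config)
    completed = impute_modes(res.state, X, mask, model)
    return res, completed
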