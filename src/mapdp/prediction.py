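"""Out-of-sample prediction for a fitted clustering.

A new observation either joins one of the ``K`` fitted clusters, with
prior probability proportional to the cluster count, or opens a new
cluster with probability proportional to the concentration ``n0``.  The
indicator can be integrated out (mixture predictive) or set to its MAP
value (modal predictive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import ClusterState
from .exp_family import ComponentModel

__all__ = ["PredictiveReport", "mixture_predictive", "map_predictive", "heldout_log_likelihood"]


@dataclass
class PredictiveReport:
    """Prediction summary for one new observation.

    ``weights`` are the indicator prior probabilities over the ``K``
    fitted clusters plus the new-cluster option (last entry); they sum
    to one.  ``posterior_probs`` additionally condition on the observed
    value.  ``log_components`` holds ``ln f(x | theta_k)`` in the same
    order.
    """

    weights: np.ndarray
    posterior_probs: np.ndarray
    log_components: np.ndarray
    mixture_log_density: float
    map_cluster: int
    map_log_density: float

    @property
    def k_options(self) -> int:
        return self.weights.shape[0]


def _report(x_new, state: ClusterState, model: ComponentModel, n0: float) -> PredictiveReport:
    x = np.atleast_1d(np.asarray(x_new, float))
    counts = state.counts.astype(float)
    weights = np.concatenate([counts, [n0]]) / (n0 + state.n)
    log_f = np.concatenate(
        [-model.costs(state.stats, x), [-model.cost_prior(x)]]
    )
    joint = np.log(weights) + log_f
    mix = float(logsumexp(joint))
    post = np.exp(joint - mix)
    # MAP indicator: minimize -ln f - ln p(z=k); ties to the lowest
    # cluster index with the new-cluster option last.
    k_map = int(np.argmin(-joint))
    return PredictiveReport(
        weights=weights,
        posterior_probs=post,
        log_components=log_f,
        mixture_log_density=mix,
        map_cluster=k_map,
        map_log_density=float(log_f[k_map]),
    )


def mixture_predictive(x_new, state: ClusterState, model: ComponentModel, n0: float) -> PredictiveReport:
    """Predictive with the cluster indicator integrated out."""
    return _report(x_new, state, model, n0)


def map_predictive(x_new, state: ClusterState, model: ComponentModel, n0: float) -> PredictiveReport:
    """Predictive at the MAP value of the cluster indicator."""
    return _report(x_new, state, model, n0)


def heldout_log_likelihood(X_new, state: ClusterState, model: ComponentModel, n0: float) -> float:
    """Sum of mixture-predictive log densities over held-out rows."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    return float(
        sum(mixture_predictive(x, state, model, n0).mixture_log_density for x in X_new)
    )
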