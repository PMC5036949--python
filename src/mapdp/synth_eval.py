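"""Synthetic benchmark: scenario generators, NMI scoring, experiment harness.

Six two-dimensional Gaussian-mixture scenarios (``s5_1`` .. ``s5_6``)
exercise the failure modes of fixed-K geometric clustering: unequal
radii, unequal densities, outliers, rotated ellipses, trivial
separation, and heavy overlap.  Generating parameters are frozen in
versioned YAML config files shipped with the package; each scenario's
qualitative constraints (separation, proportions, outlier structure)
are what the benchmark tests, not any particular parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from . import baselines, core, hyperparameters
from .exp_family import FullGaussianModel

__all__ = [
    "Scenario",
    "LabeledDataset",
    "SCENARIO_NAMES",
    "load_scenario",
    "generate",
    "nmi",
    "run_benchmark",
]

SCENARIO_NAMES = ("s5_1", "s5_2", "s5_3", "s5_4", "s5_5", "s5_6")


@dataclass(frozen=True)
class Scenario:
    """Generative description of one synthetic benchmark dataset."""

    name: str
    means: np.ndarray  # (K, D)
    covs: np.ndarray  # (K, D, D)
    weights: np.ndarray  # (K,)
    n: int = 4000
    outlier_groups: tuple = ()  # of (center, count, spread)
    description: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("mixing proportions must sum to 1")
        for cov in np.asarray(self.covs, float):
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError("component covariances must be positive definite")

    @property
    def k_true(self) -> int:
        """Number of distinct true labels (components plus outlier groups)."""
        return len(self.weights) + len(self.outlier_groups)


@dataclass(frozen=True)
class LabeledDataset:
    X: np.ndarray
    labels: np.ndarray
    scenario: str
    seed: int | None = None


def load_scenario(name: str, n: int | None = None) -> Scenario:
    """Load one of the packaged scenario configs by name."""
    if name not in SCENARIO_NAMES:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    path = resources.files("mapdp.scenarios").joinpath(f"{name}.yaml")
    cfg = yaml.safe_load(path.read_text())
    comps = cfg["components"]
    groups = tuple(
        (np.asarray(g["center"], float), int(g["n"]), float(g["spread"]))
        for g in cfg.get("outlier_groups", [])
    )
    return Scenario(
        name=cfg["name"],
        means=np.array([c["mean"] for c in comps], float),
        covs=np.array([c["cov"] for c in comps], float),
        weights=np.array([c["weight"] for c in comps], float),
        n=int(n if n is not None else cfg["n"]),
        outlier_groups=groups,
        description=cfg.get("description", ""),
    )


def _component_counts(weights: np.ndarray, n: int) -> np.ndarray:
    """Deterministic rounding of ``weights * n`` that sums to ``n``."""
    raw = weights * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(raw - counts)[::-1]
    counts[order[:short]] += 1
    return counts


def generate(scenario: Scenario, seed=None) -> LabeledDataset:
    """Draw a labelled dataset from the scenario's mixture.

    Outlier groups replace part of the total budget ``n`` and carry their
    own labels after the mixture components.
    """
    rng = np.random.default_rng(seed)
    n_outliers = sum(g[1] for g in scenario.outlier_groups)
    n_main = scenario.n - n_outliers
    counts = _component_counts(scenario.weights, n_main)
    xs, labels = [], []
    for j, (mean, cov, cnt) in enumerate(zip(scenario.means, scenario.covs, counts)):
        xs.append(rng.multivariate_normal(mean, cov, size=cnt))
        labels.append(np.full(cnt, j))
    for g, (center, cnt, spread) in enumerate(scenario.outlier_groups):
        xs.append(rng.normal(center, spread, size=(cnt, len(center))))
        labels.append(np.full(cnt, len(scenario.weights) + g))
    X = np.vstack(xs)
    y = np.concatenate(labels)
    perm = rng.permutation(X.shape[0])
    return LabeledDataset(X=X[perm], labels=y[perm], scenario=scenario.name, seed=seed)


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information with arithmetic-mean normalization.

    Label-permutation invariant; 1 iff the partitions agree up to
    relabeling, 0 when either partition is uninformative about the
    other (e.g. one of them is a single cluster).
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1.0)
    pij = table / n
    pa = pij.sum(axis=1)
    pb = pij.sum(axis=0)
    nz = pij > 0
    mi = float((pij[nz] * (np.log(pij[nz]) - np.log(np.outer(pa, pb)[nz]))).sum())
    ha = -float((pa[pa > 0] * np.log(pa[pa > 0])).sum())
    hb = -float((pb[pb > 0] * np.log(pb[pb > 0])).sum())
    if ha == 0.0 and hb == 0.0:
        return 1.0  # both trivial partitions, identical up to relabeling
    denom = 0.5 * (ha + hb)
    if denom == 0.0:
        return 0.0
    return max(0.0, min(1.0, mi / denom))


def mixed_schema():
    """Schema of the mixed-type validation dataset (Gaussian + binary + count)."""
    from .exp_family import Feature, FeatureSchema

    return FeatureSchema(
        [
            Feature("g1", "gaussian_full"),
            Feature("g2", "gaussian_full"),
            Feature("yes_no", "bernoulli"),
            Feature("count", "poisson"),
        ]
    )


# Generating parameters for the mixed-type clusters: well separated in
# every feature so that K and the partition are recoverable.
_MIXED_MEANS = np.array([[0.0, 0.0], [5.0, 4.0], [-4.0, 6.0]])
_MIXED_SD = 1.0
_MIXED_P = np.array([0.15, 0.5, 0.85])
_MIXED_LAM = np.array([2.0, 8.0, 16.0])
_MIXED_WEIGHTS = np.array([0.4, 0.35, 0.25])


def generate_mixed(n: int = 1000, seed=None) -> LabeledDataset:
    """Mixed-type dataset: two Gaussian features, one binary, one count.

    Three clusters, separated in location, response probability and rate.
    """
    rng = np.random.default_rng(seed)
    counts = _component_counts(_MIXED_WEIGHTS, n)
    xs, labels = [], []
    for j, cnt in enumerate(counts):
        g = rng.normal(_MIXED_MEANS[j], _MIXED_SD, size=(cnt, 2))
        b = rng.binomial(1, _MIXED_P[j], size=(cnt, 1))
        c = rng.poisson(_MIXED_LAM[j], size=(cnt, 1))
        xs.append(np.hstack([g, b, c]).astype(float))
        labels.append(np.full(cnt, j))
    X = np.vstack(xs)
    y = np.concatenate(labels)
    perm = rng.permutation(n)
    return LabeledDataset(X=X[perm], labels=y[perm], scenario="mixed", seed=seed)


def make_mapdp_model(X) -> FullGaussianModel:
    """Benchmark component model: full Gaussian, empirical-Bayes prior."""
    return FullGaussianModel(hyperparameters.eb_niw(X))


def run_benchmark(scenario_names=SCENARIO_NAMES, methods=("kmeans", "em", "mapdp"),
                  seed: int = 0, n0: float = 3.0, mapdp_restarts: int = 9,
                  kmeans_restarts: int = 100, n: int | None = None) -> list[dict]:
    """Fit each method on each scenario and score NMI against the truth.

    K-means and E-M are given the true component count; the DP mixture
    estimates K itself (concentration ``n0``, empirical-Bayes component
    prior, ``mapdp_restarts`` extra visit-order permutations).  Returns
    one row per scenario/method pair.
    """
    bad = set(methods) - {"kmeans", "em", "mapdp"}
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    rows = []
    for name in scenario_names:
        scenario = load_scenario(name, n=n)
        data = generate(scenario, seed=seed)
        k_comp = len(scenario.weights)
        for method in methods:
            if method == "kmeans":
                res = baselines.kmeans_best_of(data.X, k_comp, kmeans_restarts, seed=seed)
                score = nmi(data.labels, res.assignments)
                row = {"iterations": res.iterations, "k": k_comp}
            elif method == "em":
                res = baselines.gmm_em(data.X, k_comp, seed=seed)
                score = nmi(data.labels, res.assignments)
                row = {"iterations": len(res.log_likelihood_trace), "k": k_comp}
            else:
                model = make_mapdp_model(data.X)
                cfg = core.MapDpConfig(n0=n0, restarts=mapdp_restarts, seed=seed)
                res = core.fit(data.X, model, cfg)
                score = nmi(data.labels, res.assignments)
                row = {"iterations": res.n_iterations, "k": res.k}
            rows.append({"scenario": name, "method": method, "nmi": score, **row})
    return rows
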