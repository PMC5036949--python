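"""Chinese restaurant process partition prior.

Sequential seating rule, exact partition probability, sampling, and the
expected number of occupied tables.  Partitions are kept in canonical
form: labels are non-negative integers in order of first appearance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Partition",
    "canonicalize",
    "seating_probabilities",
    "partition_log_prob",
    "sample_partition",
    "expected_clusters",
]


@dataclass(frozen=True)
class Partition:
    """A partition of ``n`` items into ``k`` labelled groups."""

    assignments: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.assignments, dtype=np.int64)
        object.__setattr__(self, "assignments", z)
        if z.ndim != 1:
            raise ValueError("assignments must be a 1-D label vector")
        if z.size:
            k = z.max() + 1
            sizes = np.bincount(z, minlength=k)
            if np.any(sizes == 0):
                raise ValueError("every label up to the max must be occupied")
            # canonical form: labels appear in increasing order of first use
            first = [np.argmax(z == j) for j in range(k)]
            if any(first[j] > first[j + 1] for j in range(k - 1)):
                raise ValueError("labels must be ordered by first appearance; see canonicalize()")

    @property
    def n(self) -> int:
        return self.assignments.size

    @property
    def k(self) -> int:
        return 0 if self.n == 0 else int(self.assignments.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def canonicalize(labels) -> Partition:
    """Relabel an arbitrary label vector into order-of-first-appearance form."""
    labels = np.asarray(labels)
    mapping: dict = {}
    out = np.empty(labels.size, dtype=np.int64)
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(lab, len(mapping))
    return Partition(out)


def _check_n0(n0: float) -> float:
    n0 = float(n0)
    if not n0 > 0:
        raise ValueError("concentration (prior count) must be positive")
    return n0


def seating_probabilities(sizes, n0: float) -> np.ndarray:
    """Probability that the next customer joins each table, or a new one.

    Parameters
    ----------
    sizes : array-like of int
        Current table occupancies (may be empty).
    n0 : float
        Concentration / prior count.

    Returns
    -------
    ndarray of length ``len(sizes) + 1``; the last entry is the
    new-table probability.  Entries sum to 1.
    """
    n0 = _check_n0(n0)
    sizes = np.asarray(sizes, dtype=float)
    i = sizes.sum()
    denom = n0 + i
    return np.concatenate([sizes / denom, [n0 / denom]])


def partition_log_prob(partition: Partition, n0: float) -> float:
    """Exact log probability of a canonical partition under the seating process.

    Equals ``K ln n0 - [ln G(n0+N) - ln G(n0)] + sum_k ln G(N_k)`` with
    the rising factorial evaluated through log-gamma, and coincides with
    the product of sequential seating probabilities.
    """
    n0 = _check_n0(n0)
    if partition.n == 0:
        raise ValueError("partition log probability is undefined for zero items")
    sizes = partition.sizes
    log_rising = gammaln(n0 + partition.n) - gammaln(n0)
    return float(partition.k * np.log(n0) - log_rising + gammaln(sizes).sum())


def sample_partition(n: int, n0: float, seed=None) -> Partition:
    """Draw a partition of ``n`` items by sequential seating."""
    n0 = _check_n0(n0)
    if n < 1:
        raise ValueError("need at least one item")
    rng = np.random.default_rng(seed)
    z = np.zeros(n, dtype=np.int64)
    sizes = [1]
    for i in range(1, n):
        probs = seating_probabilities(sizes, n0)
        choice = rng.choice(len(probs), p=probs)
        if choice == len(sizes):
            sizes.append(1)
        else:
            sizes[choice] += 1
        z[i] = choice
    return Partition(z)


def expected_clusters(n: int, n0: float) -> float:
    """Exact expected number of occupied tables after ``n`` customers.

    ``sum_{i=0}^{n-1} n0 / (n0 + i)``; approximately ``n0 log n`` for
    large ``n``.
    """
    n0 = _check_n0(n0)
    if n < 1:
        raise ValueError("need at least one item")
    i = np.arange(n, dtype=float)
    return float(np.sum(n0 / (n0 + i)))
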