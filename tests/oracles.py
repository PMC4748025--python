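"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: modularity by
the literal double sum over all node pairs, community search by full
partition enumeration, and Friedman p-values by direct enumeration of all
within-block orderings.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps


def modularity_double_sum(nodes, weight_of, labels) -> float:
    """Q via the literal (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i,c_j)."""
    n = len(nodes)
    a = np.zeros((n, n))
    idx = {node: i for i, node in enumerate(nodes)}
    for (u, v), w in weight_of.items():
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[nodes[i]] == labels[nodes[j]]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def iter_partitions(items):
    """All set partitions of a list (restricted-growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in iter_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def best_partition_exhaustive(nodes, weight_of):
    """(max Q, labels) over every partition of the node set."""
    best_q, best_labels = -2.0, None
    for part in iter_partitions(nodes):
        labels = {n: i for i, grp in enumerate(part) for n in grp}
        q = modularity_double_sum(nodes, weight_of, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def friedman_statistic_reference(data: np.ndarray) -> float:
    """Tie-corrected Friedman statistic computed independently."""
    n, k = data.shape
    ranks = np.vstack([sps.rankdata(row) for row in data])
    col_sums = ranks.sum(axis=0)
    raw = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0
    return raw / c


def friedman_exact_p_enumeration(data: np.ndarray) -> float:
    """Exact permutation p by looping over all (k!)^N within-block orders."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    obs = friedman_statistic_reference(data)
    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for combo in itertools.product(perms, repeat=n):
        table = np.vstack([data[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if friedman_statistic_reference(table) >= obs - 1e-9:
            hits += 1
    return hits / total
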