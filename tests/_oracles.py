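"""Naive reference implementations used to cross-check the resampling tests.

These deliberately avoid the package's vectorised code paths: medians are
computed by sorting, induced edge counts by iterating over pairs.  They
consume the same documented RNG stream as the production implementations so
exceedance counts can be compared exactly.
"""

from __future__ import annotations

import numpy as np


def naive_median(values) -> float:
    s = sorted(float(v) for v in values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def naive_bootstrap_median_test(values_a, values_b, n_resamples: int, seed: int) -> int:
    """Exceedance count k of the paired bootstrap median comparison."""
    a = [float(v) for v in values_a]
    b = [float(v) for v in values_b]
    if naive_median(a) <= naive_median(b):
        low, high = a, b
    else:
        low, high = b, a
    rng = np.random.default_rng(seed)
    low_meds = []
    for _ in range(n_resamples):
        idx = rng.integers(0, len(low), size=len(low))
        low_meds.append(naive_median([low[i] for i in idx]))
    high_meds = []
    for _ in range(n_resamples):
        idx = rng.integers(0, len(high), size=len(high))
        high_meds.append(naive_median([high[i] for i in idx]))
    return sum(1 for lo, hi in zip(low_meds, high_meds) if lo >= hi)


def naive_induced_edges(nodes, edge_set) -> int:
    """Edge count among ``nodes`` by pair enumeration, self-loops excluded."""
    nodes = list(nodes)
    count = 0
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            pair = frozenset((nodes[i], nodes[j]))
            if len(pair) == 2 and pair in edge_set:
                count += 1
    return count


def naive_network_permutation_test(network, group, n_resamples: int, seed: int) -> int:
    """Exceedance count k of the network permutation test."""
    nodes = network.nodes  # sorted
    edge_set = {frozenset((u, v)) for u, v in network.graph.edges if u != v}
    members = [g for g in set(group) if network.has_interaction(g)]
    observed = naive_induced_edges(set(group) & set(nodes), edge_set)
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_resamples):
        sample = rng.choice(len(nodes), size=len(members), replace=False)
        if naive_induced_edges([nodes[i] for i in sample], edge_set) >= observed:
            k += 1
    return k
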