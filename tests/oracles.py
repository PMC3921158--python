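"""Independent brute-force oracles used by the graph-metric tests.

These deliberately re-derive the quantities by exhaustive loops and
path enumeration, staying independent of the vectorized implementations
they validate.
"""

import itertools

import numpy as np


def clustering_oracle(w: np.ndarray, i: int) -> float:
    """Naive triple-loop evaluation of the weighted clustering ratio."""
    n = w.shape[0]
    num = den = 0.0
    for k in range(n):
        for l in range(n):
            if k == l or k == i or l == i:
                continue
            num += w[i, k] * w[i, l] * w[k, l]
            den += w[i, k] * w[i, l]
    return num / den if den > 0 else 0.0


def path_length_oracle(w: np.ndarray) -> float:
    """Exhaustive shortest-path enumeration; feasible for n <= 7."""
    n = w.shape[0]
    nodes = range(n)
    dist = np.full((n, n), np.inf)
    for i, j in itertools.combinations(nodes, 2):
        best = np.inf
        inner = [k for k in nodes if k not in (i, j)]
        for r in range(len(inner) + 1):
            for mid in itertools.permutations(inner, r):
                path = (i, *mid, j)
                cost = 0.0
                for a, b in zip(path, path[1:]):
                    cost = cost + (1.0 / w[a, b] if w[a, b] > 0 else np.inf)
                best = min(best, cost)
        dist[i, j] = dist[j, i] = best
    off = ~np.eye(n, dtype=bool)
    return float(np.mean(dist[off]))


def random_symmetric_graph(rng: np.random.Generator, n: int,
                           allow_zero: bool = False) -> np.ndarray:
    w = rng.uniform(0.05, 1.0, size=(n, n))
    if allow_zero:
        w[rng.uniform(size=(n, n)) < 0.1] = 0.0
    w = np.triu(w, 1)
    return w + w.T
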