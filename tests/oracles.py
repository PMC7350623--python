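"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy.cluster / sklearn.metrics so that the
package's fast paths are validated against naive O(n^3) / O(n^2)
computations written straight from the definitions.
"""

from __future__ import annotations

import itertools

import numpy as np


def upgma_merge_heights(X: np.ndarray) -> list[float]:
    """Average-linkage (UPGMA) merge heights by exhaustive search.

    X is samples x features. At every step the pair of clusters with the
    smallest average pairwise Euclidean distance (over *original* points)
    is merged; the merge height is that average distance.
    """
    n = X.shape[0]
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights: list[float] = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = float(
                np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the fraction of positive>negative score pairs (ties = 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
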