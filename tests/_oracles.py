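"""Independent oracles used by the tests.

Deliberately naive implementations: correctness over speed, and no code
shared with the package internals they check.
"""

from __future__ import annotations

import numpy as np


def exact_1d_kmeans_sse(values, K: int) -> float:
    """Minimal within-cluster SSE of 1-D K-means by brute dynamic programming.

    Optimal 1-D clusters are contiguous runs of the sorted values, so the
    optimum follows from an O(n^2 K) DP on the raw (unweighted) value list.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def cost(i: int, j: int) -> float:  # SSE of x[i:j] about its mean
        s, s2, m = pre[j] - pre[i], pre2[j] - pre2[i], j - i
        return s2 - s * s / m

    INF = float("inf")
    D = [[INF] * (n + 1) for _ in range(K + 1)]
    D[0][0] = 0.0
    for k in range(1, K + 1):
        for j in range(k, n + 1):
            D[k][j] = min(D[k - 1][i] + cost(i, j) for i in range(k - 1, j))
    return D[K][n]


def fcm_memberships_oracle(values, centroids, m: float) -> np.ndarray:
    """Textbook FCM membership rule, element by element."""
    values = np.asarray(values, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    u = np.zeros((len(values), len(centroids)))
    for i, v in enumerate(values):
        d = np.abs(v - centroids)
        if np.any(d == 0):
            u[i, int(np.argmin(d))] = 1.0
            continue
        for k in range(len(centroids)):
            u[i, k] = 1.0 / np.sum((d[k] / d) ** (2.0 / (m - 1.0)))
    return u


def numeric_gradient(f, params: list[np.ndarray], eps: float = 1e-6) -> list[np.ndarray]:
    """Central finite-difference gradient of scalar f w.r.t. a list of arrays."""
    grads = []
    for arr in params:
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            hi = f()
            arr[idx] = orig - eps
            lo = f()
            arr[idx] = orig
            g[idx] = (hi - lo) / (2 * eps)
            it.iternext()
        grads.append(g)
    return grads
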