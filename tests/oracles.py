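"""Independent brute-force reference implementations used as test oracles."""

import numpy as np


def surf_reference(X, y):
    """Quadratic-loop SURF weights, written independently of the package.

    Min-max scales features, takes the mean of all unordered pairwise
    Euclidean distances as the neighbor threshold, and accumulates
    per-feature weights: +|diff|/(n*m_i) over different-class neighbors,
    -|diff|/(n*h_i) over same-class neighbors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, f = X.shape
    Xs = np.empty_like(X)
    for j in range(f):
        lo, hi = X[:, j].min(), X[:, j].max()
        Xs[:, j] = 0.0 if hi == lo else (X[:, j] - lo) / (hi - lo)

    dists = np.zeros((n, n))
    pair_d = []
    for i in range(n):
        for j in range(i + 1, n):
            d = np.sqrt(((Xs[i] - Xs[j]) ** 2).sum())
            dists[i, j] = dists[j, i] = d
            pair_d.append(d)
    threshold = float(np.mean(pair_d))

    w = np.zeros(f)
    for i in range(n):
        hits = [j for j in range(n) if j != i and dists[i, j] < threshold and y[j] == y[i]]
        misses = [j for j in range(n) if j != i and dists[i, j] < threshold and y[j] != y[i]]
        for feat in range(f):
            for j in misses:
                w[feat] += abs(Xs[i, feat] - Xs[j, feat]) / (n * len(misses))
            for j in hits:
                w[feat] -= abs(Xs[i, feat] - Xs[j, feat]) / (n * len(hits))
    return w
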