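"""Independent brute-force oracles for the dynamic-programming distances.

Both enumerate every monotone path from (0, 0) to (M-1, N-1) with steps
(1,0), (0,1), (1,1) — exactly the warping paths / couplings the
recurrences optimize over — and aggregate the local costs by sum (DTW)
or max (discrete Fréchet).  Exponential, so only usable for tiny series.
"""

from __future__ import annotations

import numpy as np


def _enumerate_paths(m: int, n: int):
    """Yield every monotone index path from (0, 0) to (m-1, n-1)."""
    stack = [((0, 0),)]
    while stack:
        path = stack.pop()
        i, j = path[-1]
        if (i, j) == (m - 1, n - 1):
            yield path
            continue
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < m and nj < n:
                stack.append(path + ((ni, nj),))


def brute_force_dtw(x, y) -> float:
    """Minimum over all monotone warping paths of the summed |.| cost."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = np.inf
    for path in _enumerate_paths(len(x), len(y)):
        cost = sum(abs(x[i] - y[j]) for i, j in path)
        best = min(best, cost)
    return float(best)


def brute_force_frechet(p, q) -> float:
    """Minimum over all couplings of the maximum link distance."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    best = np.inf
    for path in _enumerate_paths(len(p), len(q)):
        length = max(abs(p[i] - q[j]) for i, j in path)
        best = min(best, length)
    return float(best)


def random_series_pairs(n_pairs: int, seed: int, max_len: int = 6, values=(0, 1, 2)):
    """Seeded random integer-valued series pairs for oracle comparisons."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        la, lb = rng.integers(1, max_len + 1, size=2)
        pairs.append((rng.choice(values, size=la).astype(float),
                      rng.choice(values, size=lb).astype(float)))
    return pairs
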