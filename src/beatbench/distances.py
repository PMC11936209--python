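"""Time-series similarity measures: DTW, discrete Fréchet, Euclidean.

All three map a pair of 1-D amplitude series to a non-negative scalar.

* ``dtw_distance`` — total accumulated cost ``D[M, N]`` of the classic
  warping recurrence ``D[i,j] = |x_i - y_j| + min(D[i-1,j], D[i,j-1],
  D[i-1,j-1])``, unconstrained (no Sakoe-Chiba window), symmetric steps,
  local cost = absolute difference.
* ``frechet_distance`` — the discrete Fréchet distance: the minimum over
  all monotone couplings of the maximum link distance, computed by the
  analogous max/min dynamic program.  Unlike DTW and Euclidean it is a
  true metric (triangle inequality holds).
* ``euclidean_distance`` — plain L2 distance; defined only for
  equal-length series.

The O(M*N) dynamic programs are JIT-compiled with numba; a pure-numpy
fallback keeps the module importable without it.
"""

from __future__ import annotations

import numpy as np

from .core import BeatSet

__all__ = [
    "dtw_distance",
    "frechet_distance",
    "euclidean_distance",
    "get_metric",
    "pairwise_distances",
    "METRICS",
]

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False)
def _dtw_kernel(x: np.ndarray, y: np.ndarray) -> float:
    m, n = x.shape[0], y.shape[0]
    prev = np.empty(n)
    cur = np.empty(n)
    for j in range(n):
        c = abs(x[0] - y[j])
        prev[j] = c if j == 0 else prev[j - 1] + c
    for i in range(1, m):
        cur[0] = prev[0] + abs(x[i] - y[0])
        for j in range(1, n):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = abs(x[i] - y[j]) + best
        prev, cur = cur, prev
    return prev[n - 1]


@njit(cache=False)
def _frechet_kernel(x: np.ndarray, y: np.ndarray) -> float:
    m, n = x.shape[0], y.shape[0]
    prev = np.empty(n)
    cur = np.empty(n)
    for j in range(n):
        c = abs(x[0] - y[j])
        prev[j] = c if j == 0 else max(prev[j - 1], c)
    for i in range(1, m):
        cur[0] = max(prev[0], abs(x[i] - y[0]))
        for j in range(1, n):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            c = abs(x[i] - y[j])
            cur[j] = c if c > best else best
        prev, cur = cur, prev
    return prev[n - 1]


@njit(cache=False)
def _pairwise_kernel(a: np.ndarray, b: np.ndarray, which: int) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    out = np.empty((na, nb))
    for i in range(na):
        for j in range(nb):
            if which == 0:
                out[i, j] = _dtw_kernel(a[i], b[j])
            else:
                out[i, j] = _frechet_kernel(a[i], b[j])
    return out


def _as_series(x, name: str) -> np.ndarray:
    arr = np.asarray(getattr(x, "samples", x), dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def dtw_distance(x, y) -> float:
    """Dynamic-time-warping distance (accumulated |.|-cost, unconstrained)."""
    return float(_dtw_kernel(_as_series(x, "x"), _as_series(y, "y")))


def frechet_distance(p, q) -> float:
    """Discrete Fréchet distance (min over couplings of the max link)."""
    return float(_frechet_kernel(_as_series(p, "p"), _as_series(q, "q")))


def euclidean_distance(x, y) -> float:
    """L2 distance between equal-length series."""
    a, b = _as_series(x, "x"), _as_series(y, "y")
    if a.size != b.size:
        raise ValueError(f"euclidean distance needs equal lengths, got {a.size} and {b.size}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


METRICS = {
    "dtw": dtw_distance,
    "frechet": frechet_distance,
    "euclidean": euclidean_distance,
}


def get_metric(name: str):
    try:
        return METRICS[name]
    except KeyError:
        raise KeyError(f"unknown distance {name!r}; available: {sorted(METRICS)}") from None


def pairwise_distances(a: "BeatSet | np.ndarray", b: "BeatSet | np.ndarray", metric: str = "dtw") -> np.ndarray:
    """Distance table between two beat sets, shape ``(len(a), len(b))``."""
    da = a.data if isinstance(a, BeatSet) else np.asarray(a, dtype=float)
    db = b.data if isinstance(b, BeatSet) else np.asarray(b, dtype=float)
    if da.ndim != 2 or db.ndim != 2 or not da.size or not db.size:
        raise ValueError("pairwise_distances needs two non-empty 2-D sets")
    if metric == "euclidean":
        if da.shape[1] != db.shape[1]:
            raise ValueError("euclidean distance needs equal beat lengths")
        diff = da[:, None, :] - db[None, :, :]
        return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if metric == "dtw":
        which = 0
    elif metric == "frechet":
        which = 1
    else:
        raise KeyError(f"unknown distance {metric!r}")
    if _HAVE_NUMBA:
        return np.asarray(_pairwise_kernel(np.ascontiguousarray(da), np.ascontiguousarray(db), which))
    fn = METRICS[metric]  # pragma: no cover - numba fallback
    return np.array([[fn(u, v) for v in db] for u in da])


def pairwise_table(a: BeatSet, b: BeatSet, metric: str = "dtw"):
    """Pairwise distances as a pandas DataFrame indexed by beat indices."""
    import pandas as pd

    mat = pairwise_distances(a, b, metric)
    return pd.DataFrame(mat, index=np.arange(len(a)), columns=np.arange(len(b)))
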