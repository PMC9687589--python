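"""Kraskov-Stoegbauer-Grassberger (KSG) mutual-information estimator.

Estimator I(1) of Kraskov et al. with Chebyshev (max-norm) balls: for each
sample the distance to its k-th nearest neighbour in the joint (x, y) space
sets a radius; the marginal neighbour counts inside that radius enter the
digamma correction.  Implemented as a tight numba kernel evaluated for many
channel pairs of one epoch at once (the per-pair kNN problem is tiny --
a few hundred samples -- so brute force beats tree structures here).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import digamma


@njit(fastmath=True, cache=True)
def _ksg_pairs(data, pairs, k, psi):  # pragma: no cover - numba kernel
    n_pairs = pairs.shape[0]
    n = data.shape[1]
    out = np.empty(n_pairs)
    n_ch = data.shape[0]
    D = np.empty((n_ch, n, n))
    for c in range(n_ch):
        x = data[c]
        for i in range(n):
            for j in range(n):
                D[c, i, j] = abs(x[i] - x[j])
    for p in range(n_pairs):
        a, b = pairs[p, 0], pairs[p, 1]
        Da = D[a]
        Db = D[b]
        s = 0.0
        for i in range(n):
            # k smallest joint Chebyshev distances, excluding self (k <= 3)
            e0 = 1e300
            e1 = 1e300
            e2 = 1e300
            for j in range(n):
                if j == i:
                    continue
                d = Da[i, j]
                if Db[i, j] > d:
                    d = Db[i, j]
                if d < e2:
                    if d < e1:
                        e2 = e1
                        if d < e0:
                            e1 = e0
                            e0 = d
                        else:
                            e1 = d
                    else:
                        e2 = d
            if k == 1:
                eps = e0
            elif k == 2:
                eps = e1
            else:
                eps = e2
            nx = 0
            ny = 0
            for j in range(n):
                if Da[i, j] < eps:
                    nx += 1
                if Db[i, j] < eps:
                    ny += 1
            # counts include the point itself, supplying the +1 of psi(n+1)
            s += psi[nx] + psi[ny]
        out[p] = psi[k] + psi[n] - s / n
    return out


def ksg_mutual_information(
    data: np.ndarray, pairs: np.ndarray, k: int = 3
) -> np.ndarray:
    """MI (nats) for each channel pair of one epoch.

    Parameters
    ----------
    data : (n_channels, n_samples) array
    pairs : (n_pairs, 2) integer array of channel index pairs
    k : neighbour count of the KSG estimator (1..3)
    """
    data = np.ascontiguousarray(data, dtype=np.float64)
    pairs = np.ascontiguousarray(pairs, dtype=np.int64)
    if not 1 <= k <= 3:
        raise ValueError("k must be between 1 and 3")
    n = data.shape[1]
    if n <= k:
        raise ValueError("need more samples than neighbours")
    # psi[m] = digamma(m); index 0 unused but keeps addressing direct
    psi = np.concatenate(([0.0], digamma(np.arange(1, n + 2))))
    return _ksg_pairs(data, pairs, k, psi)
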