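"""Shared statistical kernels.

The hypergeometric upper tail backs both the per-sample gene co-occurrence
test and the Fisher-exact TF overlap test; Benjamini-Hochberg step-up backs
every multiple-testing family in the package. Keeping them here gives a
single source of truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Inclusive upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of marked items, n the number of
    draws, k the observed overlap. Symmetric in (K, n).
    """
    k, N, K, n = int(k), int(N), int(K), int(n)
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"invalid hypergeometric margins N={N}, K={K}, n={n}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(
            f"overlap k={k} outside support [{max(0, K + n - N)}, {min(K, n)}] "
            f"for N={N}, K={K}, n={n}"
        )
    if k <= max(0, K + n - N):
        return 1.0  # certain event (also covers the empty-population edge)
    # sf is exclusive: sf(k-1) = P(X >= k)
    return float(np.clip(hypergeom.sf(k - 1, N, K, n), 0.0, 1.0))


def bh_adjust(pvals, groups=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Implemented definitionally: within each group, sort ascending, multiply
    p_(i) by m/i, enforce monotonicity by a reverse cumulative minimum, and
    cap at 1. NaN entries are ignored (returned as NaN) and do not count
    toward the family size.

    Parameters
    ----------
    pvals : array-like of float in [0, 1]
    groups : optional array-like of hashables, same length; each distinct
        value defines an independent correction family.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")

    adj = np.full_like(p, np.nan)
    if groups is None:
        group_ids = np.zeros(p.shape[0])
    else:
        group_ids = np.asarray(pd.factorize(np.asarray(groups))[0])
        if group_ids.shape[0] != p.shape[0]:
            raise ValueError("groups length must match pvals length")

    for g in np.unique(group_ids):
        idx = np.where((group_ids == g) & finite)[0]
        m = idx.size
        if m == 0:
            continue
        order = np.argsort(p[idx], kind="stable")
        ranked = p[idx][order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        adj[idx] = out
    return adj
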