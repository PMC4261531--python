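"""Numerical kernel for postorder pruning.

The likelihood of a discrete character on a tree is evaluated millions of
times inside the MCMC, so the inner loop is written in plain loops and
JIT-compiled with numba when available; the same function runs (slowly) as
pure Python otherwise.  Per-node rescaling keeps partial likelihoods in range
on deep trees.
"""

from __future__ import annotations

import numpy as np


def _prune_impl(post_internal, child_ptr, child_idx, P, L, root, prior):
    S = L.shape[1]
    tmp = np.empty(S)
    logscale = 0.0
    for idx in range(post_internal.shape[0]):
        n = post_internal[idx]
        for s in range(S):
            L[n, s] = 1.0
        for e in range(child_ptr[n], child_ptr[n + 1]):
            c = child_idx[e]
            for i in range(S):
                acc = 0.0
                for j in range(S):
                    acc += P[c, i, j] * L[c, j]
                tmp[i] = acc
            for i in range(S):
                L[n, i] *= tmp[i]
        m = 0.0
        for i in range(S):
            if L[n, i] > m:
                m = L[n, i]
        if m <= 0.0:
            return -np.inf
        for i in range(S):
            L[n, i] /= m
        logscale += np.log(m)
    tot = 0.0
    for i in range(S):
        tot += prior[i] * L[root, i]
    if tot <= 0.0:
        return -np.inf
    return np.log(tot) + logscale


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    prune = njit(cache=False, fastmath=False)(_prune_impl)
except ImportError:  # pragma: no cover
    prune = _prune_impl
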