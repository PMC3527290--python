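"""Numba kernel for the run-length-encoded forward recursion.

Same algorithm as the pure-numpy path in :mod:`imcoal.hmm`: per symbol s
the update matrix is M_s = T diag(E[:, s]); a run of k identical symbols
applies M_s^k through binary powers, each power renormalised by its max
entry with the log factor accumulated, so arbitrarily long runs cannot
underflow.  Returns -inf if the forward mass vanishes (caller raises).
"""

import numpy as np
from numba import njit

__all__ = ["rle_forward"]


@njit(cache=True)
def rle_forward(pi, T, E, run_symbols, run_lengths):
    n = pi.shape[0]
    n_sym = E.shape[1]
    maxlen = 0
    for k in run_lengths:
        if k > maxlen:
            maxlen = k
    nbits = 1
    while (1 << nbits) <= maxlen:
        nbits += 1

    pows = np.empty((n_sym, nbits, n, n))
    plog = np.zeros((n_sym, nbits))
    have = np.zeros(n_sym, np.bool_)

    loglik = 0.0
    alpha = pi * E[:, run_symbols[0]]
    tot = alpha.sum()
    if tot <= 0.0:
        return -np.inf
    loglik += np.log(tot)
    alpha = alpha / tot

    for r in range(run_symbols.shape[0]):
        s = run_symbols[r]
        k = run_lengths[r]
        if r == 0:
            k -= 1
            if k == 0:
                continue
        if not have[s]:
            for i in range(n):
                for j in range(n):
                    pows[s, 0, i, j] = T[i, j] * E[j, s]
            plog[s, 0] = 0.0
            for b in range(1, nbits):
                M = pows[s, b - 1] @ pows[s, b - 1]
                m = M.max()
                if m <= 0.0:
                    return -np.inf
                pows[s, b] = M / m
                plog[s, b] = 2.0 * plog[s, b - 1] + np.log(m)
            have[s] = True
        b = 0
        kk = k
        while kk > 0:
            if kk & 1:
                alpha = alpha @ pows[s, b]
                loglik += plog[s, b]
            kk >>= 1
            b += 1
        tot = alpha.sum()
        if tot <= 0.0:
            return -np.inf
        loglik += np.log(tot)
        alpha = alpha / tot
    return loglik
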