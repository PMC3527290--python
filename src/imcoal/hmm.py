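"""Numerically stable forward likelihood and posterior decoding.

The forward recursion is scaled (normalised forward vectors with the log
normalisers accumulated) rather than computed in log space, so the inner
loop is vector-matrix products.  Because the column alphabet has only
three symbols and real alignments are dominated by long runs of identical
columns, the likelihood is evaluated over a run-length encoding of the
sequence: a run of k columns of symbol s advances the forward vector by
the matrix (T diag(e_s))^k, applied through cached, individually
renormalised binary powers.  This is exact (up to floating point) and
makes the cost scale with the number of runs rather than the number of
columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .symbols import N_SYMBOLS

try:  # compiled inner loop; the numpy path below is the fallback
    from ._forward_numba import rle_forward as _rle_forward_jit
except ImportError:  # pragma: no cover
    _rle_forward_jit = None

__all__ = ["LikelihoodResult", "PosteriorTrack", "forward_loglik", "posterior_decode"]


@dataclass(frozen=True)
class LikelihoodResult:
    loglik: float
    n_columns: int


@dataclass
class PosteriorTrack:
    """Posterior state probabilities per column; ``tmrca`` is the posterior
    mean coalescence time when interval means are supplied."""

    gamma: np.ndarray  # (L, n)
    map_state: np.ndarray  # (L,)
    tmrca: np.ndarray | None = None


def _check(pi: np.ndarray, T: np.ndarray, E: np.ndarray, columns: np.ndarray) -> np.ndarray:
    columns = np.asarray(columns)
    n = len(pi)
    if T.shape != (n, n) or E.shape[0] != n or E.shape[1] != N_SYMBOLS:
        raise ValueError("dimension mismatch between pi, T and E")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("T is not row-stochastic")
    if columns.ndim != 1 or len(columns) < 1:
        raise ValueError("need a non-empty 1-d column sequence")
    return columns.astype(np.int64, copy=False)


def _run_lengths(columns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(columns)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(columns)]])
    return columns[starts], ends - starts


class _PowerCache:
    """Binary powers of a non-negative matrix, each renormalised by its max
    entry with the log factor kept separately (avoids underflow for long
    runs)."""

    def __init__(self, M: np.ndarray):
        self.mats = [M]
        self.logs = [0.0]

    def _extend(self, nbits: int) -> None:
        while len(self.mats) < nbits:
            P = self.mats[-1]
            sq = P @ P
            m = sq.max()
            if m <= 0:
                raise FloatingPointError("forward recursion lost all probability mass")
            self.mats.append(sq / m)
            self.logs.append(2.0 * self.logs[-1] + np.log(m))

    def apply(self, alpha: np.ndarray, k: int) -> tuple[np.ndarray, float]:
        """Return (alpha @ M^k unnormalised-modulo-log, accumulated log)."""
        self._extend(k.bit_length())
        logc = 0.0
        bit = 0
        while k:
            if k & 1:
                alpha = alpha @ self.mats[bit]
                logc += self.logs[bit]
            k >>= 1
            bit += 1
        return alpha, logc


def forward_loglik(
    pi: np.ndarray,
    T: np.ndarray,
    E: np.ndarray,
    columns: np.ndarray,
    method: str = "rle",
) -> LikelihoodResult:
    """Natural-log likelihood of the column sequence under the HMM.

    ``method="rle"`` (default) uses run-length matrix powers;
    ``method="scan"`` is the plain per-position scaled recursion, kept as
    a straightforward reference path.
    """
    columns = _check(pi, T, E, columns)
    if method == "scan":
        return _forward_scan(pi, T, E, columns)
    if method != "rle":
        raise ValueError("method must be 'rle' or 'scan'")
    symbols, lengths = _run_lengths(columns)
    if _rle_forward_jit is not None:
        ll = _rle_forward_jit(
            np.ascontiguousarray(pi, dtype=np.float64),
            np.ascontiguousarray(T, dtype=np.float64),
            np.ascontiguousarray(E, dtype=np.float64),
            symbols.astype(np.int64),
            lengths.astype(np.int64),
        )
        if not np.isfinite(ll):
            raise FloatingPointError("forward recursion underflowed to zero")
        return LikelihoodResult(loglik=float(ll), n_columns=len(columns))
    caches: dict[int, _PowerCache] = {}
    loglik = 0.0
    alpha = pi * E[:, symbols[0]]
    s0 = alpha.sum()
    if s0 <= 0:
        raise FloatingPointError("zero likelihood at first column")
    loglik += np.log(s0)
    alpha = alpha / s0
    first = True
    for s, k in zip(symbols, lengths):
        k = int(k)
        if first:
            k -= 1  # the first column of the first run is already absorbed
            first = False
        if k == 0:
            continue
        cache = caches.get(int(s))
        if cache is None:
            cache = caches[int(s)] = _PowerCache(T * E[:, s][None, :])
        alpha, logc = cache.apply(alpha, k)
        tot = alpha.sum()
        if tot <= 0:
            raise FloatingPointError("forward recursion underflowed to zero")
        loglik += logc + np.log(tot)
        alpha = alpha / tot
    return LikelihoodResult(loglik=float(loglik), n_columns=len(columns))


def _forward_scan(pi, T, E, columns) -> LikelihoodResult:
    alpha = pi * E[:, columns[0]]
    c = alpha.sum()
    loglik = np.log(c)
    alpha /= c
    for s in columns[1:]:
        alpha = (alpha @ T) * E[:, s]
        c = alpha.sum()
        if c <= 0:
            raise FloatingPointError("forward recursion underflowed to zero")
        loglik += np.log(c)
        alpha /= c
    return LikelihoodResult(loglik=float(loglik), n_columns=len(columns))


def posterior_decode(
    pi: np.ndarray,
    T: np.ndarray,
    E: np.ndarray,
    columns: np.ndarray,
    means: np.ndarray | None = None,
) -> PosteriorTrack:
    """Scaled forward-backward posteriors per column.  When the interval
    means are given, the per-column posterior-mean TMRCA is attached."""
    columns = _check(pi, T, E, columns)
    L = len(columns)
    n = len(pi)
    Emat = E[:, columns].T  # (L, n)
    alpha = np.empty((L, n))
    scale = np.empty(L)
    a = pi * Emat[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, L):
        a = (alpha[t - 1] @ T) * Emat[t]
        c = a.sum()
        if c <= 0:
            raise FloatingPointError("forward recursion underflowed to zero")
        scale[t] = c
        alpha[t] = a / c
    beta = np.empty((L, n))
    beta[-1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[t] = (T @ (Emat[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    tmrca = gamma @ means if means is not None else None
    return PosteriorTrack(gamma=gamma, map_state=gamma.argmax(axis=1), tmrca=tmrca)
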