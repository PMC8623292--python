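"""Dynamic-programming fill kernels shared by the alignment engines.

Plain nested-loop implementations over integer numpy arrays, JIT-compiled
with numba when available (pure-Python fallback otherwise, identical
results). Tracebacks live in :mod:`modumap.align`; the kernels only fill the
score matrices and locate the deterministic best cell (first maximum in
row-major order, i.e. smallest (query, target) end coordinate).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

#: effectively -infinity for int64 DP without overflow on addition
NEG = -(10 ** 12)


@njit(cache=True)
def fill_local(a, b, scores, gap_open, gap_extend, forbidden):
    """Gotoh local (Smith-Waterman affine) fill with a forbidden-pair mask.

    ``forbidden[i, j]`` disables the match transition pairing a[i] with b[j]
    (the Waterman-Eggert declumping constraint). Returns (H, E, F, best
    score, best i, best j); H floors at 0.
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            if forbidden[i - 1, j - 1]:
                sub = NEG
            else:
                sub = scores[a[i - 1], b[j - 1]]
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def fill_global_free_ends(a, b, scores, gap_open, gap_extend):
    """Affine global fill with free leading/trailing gaps on both sequences.

    Leading gaps are free via zero-initialised H borders; the best score is
    the maximum over the last row and column (trailing gaps free). The best
    edge cell is the lexicographically smallest (i, j) among maxima.
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            h = H[i - 1, j - 1] + scores[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    # the empty-overlap arrangement (both sequences entirely in free end
    # gaps) is a valid free-end-gap alignment of score 0
    best = np.int64(0)
    bi = 0
    bj = n
    for i in range(1, m + 1):
        if i < m:
            if H[i, n] > best:
                best = H[i, n]
                bi = i
                bj = n
        else:
            for j in range(1, n + 1):
                if H[m, j] > best:
                    best = H[m, j]
                    bi = m
                    bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def fill_ungapped(a, b, scores):
    """Ungapped local fill (per-diagonal positive-run maxima).

    Used by the consensus scan, which disables gap transitions entirely.
    Returns (D, best score, best i, best j).
    """
    m = a.shape[0]
    n = b.shape[0]
    D = np.zeros((m + 1, n + 1), dtype=np.int64)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d = D[i - 1, j - 1] + scores[a[i - 1], b[j - 1]]
            if d < 0:
                d = 0
            D[i, j] = d
            if d > best:
                best = d
                bi = i
                bj = j
    return D, best, bi, bj


@njit(cache=True)
def best_local_scores_shuffled(a, b, scores, gap_open, gap_extend, perms):
    """Best local score of ``a`` against each row-permutation of ``b``.

    ``perms`` is an (n_shuffles, len(b)) int array of permutation indices;
    used by the empirical E-value null. Only scores are needed, so no
    traceback matrices are retained.
    """
    n_shuffles = perms.shape[0]
    out = np.zeros(n_shuffles, dtype=np.int64)
    forbidden = np.zeros((a.shape[0], b.shape[0]), dtype=np.bool_)
    for k in range(n_shuffles):
        bs = b[perms[k]]
        _, _, _, best, _, _ = fill_local(a, bs, scores, gap_open, gap_extend,
                                         forbidden)
        out[k] = best
    return out
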