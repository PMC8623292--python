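"""Independent oracles for the alignment engines.

The brute-force local aligner enumerates every increasing chain of aligned
residue pairs ((i1,j1) < (i2,j2) < ... strictly in both coordinates) and
charges the unaligned residues between consecutive pairs as affine gap runs
(open + (L-1)*extend per run; a chain of k pairs is the only increasing
matching of its row and column sets, so this enumeration is exhaustive over
all local alignments). It shares no DP machinery with the implementation.
With free end gaps on both sequences the optimal score coincides with the
local optimum (leading/trailing residues are free in both formulations), so
the same oracle checks both modes. A forbidden-pair mask makes it an oracle
for Waterman-Eggert declumping as well.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _chain_extend(a, b, scores, gap_open, gap_extend, forbidden, i, j, acc):
    """Best total over all chains extending a chain ending at pair (i, j)."""
    best = acc
    m = a.shape[0]
    n = b.shape[0]
    for k in range(i + 1, m):
        for l in range(j + 1, n):
            if forbidden[k, l]:
                continue
            gap = 0
            dq = k - i - 1
            if dq > 0:
                gap += gap_open + (dq - 1) * gap_extend
            dt = l - j - 1
            if dt > 0:
                gap += gap_open + (dt - 1) * gap_extend
            s = _chain_extend(a, b, scores, gap_open, gap_extend, forbidden,
                              k, l, acc + gap + scores[a[k], b[l]])
            if s > best:
                best = s
    return best


@njit(cache=True)
def brute_force_best_score(a, b, scores, gap_open, gap_extend, forbidden):
    """Best local alignment score by exhaustive chain enumeration (>= 0)."""
    best = np.int64(0)
    m = a.shape[0]
    n = b.shape[0]
    for i in range(m):
        for j in range(n):
            if forbidden[i, j]:
                continue
            s = _chain_extend(a, b, scores, gap_open, gap_extend, forbidden,
                              i, j, np.int64(scores[a[i], b[j]]))
            if s > best:
                best = s
    return best


def brute_force_local(seq_a, seq_b, params, forbidden=None):
    """Best local score for two ProteinSequence operands."""
    a = seq_a.encoded()
    b = seq_b.encoded()
    if forbidden is None:
        forbidden = np.zeros((len(a), len(b)), dtype=np.bool_)
    return int(brute_force_best_score(a, b, params.matrix.scores,
                                      params.gap_open, params.gap_extend,
                                      forbidden))
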