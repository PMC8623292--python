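"""Pairwise alignment engines.

Three modes drive the whole analysis:

* optimal local alignment (Smith-Waterman with affine gaps),
* declumped sub-optimal local alignments (the Waterman-Eggert procedure:
  each reported alignment forbids re-use of its aligned residue pairs, and
  the DP is re-run in full for the next one),
* global alignment with free end gaps on both sequences ("global without
  endpoint penalty"), used for receptor-vs-receptor comparisons.

The affine gap model charges ``gap_open`` for the first gapped residue and
``gap_extend`` for each further one: a gap of length L costs
``gap_open + (L-1)*gap_extend``, matching the FASTA/LALIGN convention for
the -10/-2 (local) and -12/-2 (global) presets. Traceback ties prefer
match/mismatch over a gap in the target over a gap in the query, and the
smallest (query, target) end coordinate among equal-scoring cells, so every
result is deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from ._kernels import NEG
from .seqio import GAP, ProteinSequence, SubstitutionMatrix, _CODE


class Mode(str, enum.Enum):
    LOCAL = "local"
    GLOBAL_FREE_ENDS = "global_free_ends"


class ColumnClass(str, enum.Enum):
    """Per-column match class.

    identity: equal residues (``X`` never counts); similar: unequal residues
    with a positive substitution score; gap: either side gapped; dissimilar
    otherwise.
    """

    IDENTITY = "identity"
    SIMILAR = "similar"
    DISSIMILAR = "dissimilar"
    GAP = "gap"


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for one alignment run."""

    matrix: SubstitutionMatrix
    gap_open: int = -10
    gap_extend: int = -2
    mode: Mode = Mode.LOCAL

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError(
                f"require gap_open <= gap_extend <= 0, got "
                f"{self.gap_open}/{self.gap_extend}"
            )
        object.__setattr__(self, "mode", Mode(self.mode))


@dataclass(frozen=True)
class PairwiseAlignment:
    """An alignment as an ordered list of (query, target) columns.

    ``score`` is the Waterman-Eggert score of the alignment; it always
    equals recomputation from the columns under ``params`` (asserted at
    construction). Spans are 1-based inclusive and match the non-gap column
    content. An empty alignment (no columns, score 0) represents "no
    positive-scoring local match".
    """

    query_id: str
    target_id: str
    columns: tuple[tuple[str, str], ...]
    score: int
    mode: Mode
    query_span: tuple[int, int] | None
    target_span: tuple[int, int] | None
    params: AlignmentParams

    def __post_init__(self) -> None:
        for q, t in self.columns:
            if q == GAP and t == GAP:
                raise ValueError("gap-vs-gap column")
        nq = sum(1 for q, _ in self.columns if q != GAP)
        nt = sum(1 for _, t in self.columns if t != GAP)
        for span, count, name in ((self.query_span, nq, "query"),
                                  (self.target_span, nt, "target")):
            if span is None:
                if count:
                    raise ValueError(f"{name}_span missing for non-empty alignment")
            elif span[1] - span[0] + 1 != count:
                raise ValueError(f"{name}_span {span} inconsistent with columns")
        recomputed = score_columns(self.columns, self.params, self.mode)
        if recomputed != self.score:
            raise ValueError(
                f"stored score {self.score} != recomputed {recomputed}"
            )

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def aligned_pairs(self) -> set[tuple[int, int]]:
        """0-based (query, target) residue index pairs of match columns."""
        pairs = set()
        qi = self.query_span[0] - 1 if self.query_span else 0
        ti = self.target_span[0] - 1 if self.target_span else 0
        for q, t in self.columns:
            if q != GAP and t != GAP:
                pairs.add((qi, ti))
            if q != GAP:
                qi += 1
            if t != GAP:
                ti += 1
        return pairs


def score_columns(columns: Sequence[tuple[str, str]], params: AlignmentParams,
                  mode: Mode) -> int:
    """Recompute an alignment score from its columns.

    Gap runs are charged gap_open + (L-1)*gap_extend per maximal
    single-sided run; in free-end-gap global mode, runs lying entirely
    before the first or after the last match column are free.
    """
    match_idx = [k for k, (q, t) in enumerate(columns) if q != GAP and t != GAP]
    if not match_idx:
        return 0
    first, last = match_idx[0], match_idx[-1]
    total = 0
    run_side = None  # 'q' or 't' for the sequence currently gapped
    for k, (q, t) in enumerate(columns):
        if q != GAP and t != GAP:
            total += params.matrix.score(q, t)
            run_side = None
            continue
        side = "q" if q == GAP else "t"
        free = mode is Mode.GLOBAL_FREE_ENDS and (k < first or k > last)
        if not free:
            total += params.gap_open if side != run_side else params.gap_extend
        run_side = side
    return total


def _encode(seq: ProteinSequence) -> np.ndarray:
    return seq.encoded()


def _traceback_local(a, b, scores, go, ge, forbidden, H, E, F, bi, bj):
    """Shared affine traceback; returns columns plus 0-based start (i, j)."""
    cols: list[tuple[str, str]] = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = NEG if forbidden[i - 1, j - 1] else scores[a[i - 1], b[j - 1]]
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub:
                cols.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP invariant
                raise AssertionError("broken traceback")
        elif state == "F":  # gap in target: consume query residue
            cols.append((i - 1, -1))
            if F[i, j] == H[i - 1, j] + go:
                state = "H"
            i -= 1
        else:  # gap in query: consume target residue
            cols.append((-1, j - 1))
            if E[i, j] == H[i, j - 1] + go:
                state = "H"
            j -= 1
    cols.reverse()
    return cols, i, j


def _columns_to_strings(cols, qa: str, ta: str):
    return tuple(
        (qa[qi] if qi >= 0 else GAP, ta[tj] if tj >= 0 else GAP)
        for qi, tj in cols
    )


def local_align(a: ProteinSequence, b: ProteinSequence,
                params: AlignmentParams,
                _forbidden: np.ndarray | None = None) -> PairwiseAlignment:
    """Maximum-scoring local alignment of ``a`` (query) vs ``b`` (target).

    Returns an empty alignment (score 0) when no positive-scoring residue
    pairing exists.
    """
    if params.mode is not Mode.LOCAL:
        raise ValueError("local_align requires mode=local params")
    ea, eb = _encode(a), _encode(b)
    forbidden = (_forbidden if _forbidden is not None
                 else np.zeros((len(a), len(b)), dtype=bool))
    H, E, F, best, bi, bj = _kernels.fill_local(
        ea, eb, params.matrix.scores, params.gap_open, params.gap_extend,
        forbidden)
    if best <= 0:
        return PairwiseAlignment(a.id, b.id, (), 0, Mode.LOCAL, None, None,
                                 params)
    cols, si, sj = _traceback_local(ea, eb, params.matrix.scores,
                                    params.gap_open, params.gap_extend,
                                    forbidden, H, E, F, bi, bj)
    return PairwiseAlignment(
        query_id=a.id, target_id=b.id,
        columns=_columns_to_strings(cols, a.residues, b.residues),
        score=int(best), mode=Mode.LOCAL,
        query_span=(si + 1, bi), target_span=(sj + 1, bj), params=params)


def suboptimal_alignments(a: ProteinSequence, b: ProteinSequence,
                          params: AlignmentParams,
                          max_alignments: int = 20,
                          min_score: int = 1) -> list[PairwiseAlignment]:
    """Waterman-Eggert declumped sub-optimal local alignments.

    Alignments come in non-increasing score order, each scoring at least
    ``min_score``; no two share an aligned residue pair. After each
    alignment its pairs are forbidden on the match transition and the DP is
    re-run in full (correctness over speed; inputs are desk-scale).
    """
    if max_alignments < 1:
        raise ValueError("max_alignments must be >= 1")
    forbidden = np.zeros((len(a), len(b)), dtype=bool)
    out: list[PairwiseAlignment] = []
    floor = max(min_score, 1)
    while len(out) < max_alignments:
        aln = local_align(a, b, params, _forbidden=forbidden)
        if aln.score < floor or not aln.columns:
            break
        out.append(aln)
        for qi, ti in aln.aligned_pairs:
            forbidden[qi, ti] = True
    return out


def global_align_free_ends(a: ProteinSequence, b: ProteinSequence,
                           params: AlignmentParams) -> PairwiseAlignment:
    """Global alignment with zero-cost leading/trailing gaps on both sides.

    Every residue of both sequences appears in exactly one column; overhangs
    are represented as gap columns but charged nothing. Internal gaps are
    charged per ``params``.
    """
    if params.mode is not Mode.GLOBAL_FREE_ENDS:
        raise ValueError("global_align_free_ends requires mode=global_free_ends")
    ea, eb = _encode(a), _encode(b)
    m, n = len(a), len(b)
    H, E, F, best, bi, bj = _kernels.fill_global_free_ends(
        ea, eb, params.matrix.scores, params.gap_open, params.gap_extend)
    forbidden = np.zeros((m, n), dtype=bool)
    cols, si, sj = _traceback_global(ea, eb, params.matrix.scores,
                                     params.gap_open, params.gap_extend,
                                     H, E, F, bi, bj)
    full = []
    full.extend((qi, -1) for qi in range(si))
    full.extend((-1, tj) for tj in range(sj))
    full.extend(cols)
    full.extend((qi, -1) for qi in range(bi, m))
    full.extend((-1, tj) for tj in range(bj, n))
    return PairwiseAlignment(
        query_id=a.id, target_id=b.id,
        columns=_columns_to_strings(full, a.residues, b.residues),
        score=int(best), mode=Mode.GLOBAL_FREE_ENDS,
        query_span=(1, m), target_span=(1, n), params=params)


def _traceback_global(a, b, scores, go, ge, H, E, F, bi, bj):
    cols: list[tuple[int, int]] = []
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            sub = scores[a[i - 1], b[j - 1]]
            if H[i, j] == H[i - 1, j - 1] + sub:
                cols.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP invariant
                raise AssertionError("broken traceback")
        elif state == "F":
            cols.append((i - 1, -1))
            if F[i, j] == H[i - 1, j] + go:
                state = "H"
            i -= 1
        else:
            cols.append((-1, j - 1))
            if E[i, j] == H[i, j - 1] + go:
                state = "H"
            j -= 1
    cols.reverse()
    return cols, i, j


def classify_columns(aln: PairwiseAlignment) -> list[ColumnClass]:
    """Per-column match classes under the alignment's own matrix.

    Similarity means a positive substitution score between unequal
    residues; ``X`` never counts as identity or similarity.
    """
    matrix = aln.params.matrix
    out = []
    for q, t in aln.columns:
        if q == GAP or t == GAP:
            out.append(ColumnClass.GAP)
        elif q == "X" or t == "X":
            out.append(ColumnClass.DISSIMILAR)
        elif q == t:
            out.append(ColumnClass.IDENTITY)
        elif matrix.score(q, t) > 0:
            out.append(ColumnClass.SIMILAR)
        else:
            out.append(ColumnClass.DISSIMILAR)
    return out
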