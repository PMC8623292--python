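"""Significance criteria for module-homology hits.

Two criteria are applied simultaneously to each candidate alignment (the
"dual criterion"): a Waterman-Eggert score of at least 35, and at least 5
equivalent identities within a 10-column stretch, where a pair of similar
(positively scoring) substitutions counts as one identity. A seeded
shuffling/extreme-value fit supplies empirical E-values, and a
ligand-by-receptor permutation grid calibrates the per-comparison pass rate
of the dual criterion on unrelated sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .align import (AlignmentParams, ColumnClass, Mode, PairwiseAlignment,
                    classify_columns, local_align)
from .seqio import ProteinSequence


@dataclass(frozen=True)
class SignificanceParams:
    """Thresholds of the dual criterion.

    ``similarity_weight`` = 0.5 encodes "a pair of similarities equals one
    identity". Fractional equivalents are not rounded: 4 identities + 1
    similarity = 4.5 fails the default threshold of 5.
    """

    we_threshold: int = 35
    window: int = 10
    min_equivalents: float = 5.0
    similarity_weight: float = 0.5
    evalue_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 <= self.similarity_weight <= 1:
            raise ValueError("similarity_weight must be in [0, 1]")
        if self.we_threshold < 0:
            raise ValueError("we_threshold must be >= 0")


@dataclass(frozen=True)
class WindowResult:
    best_start: int  # 0-based column index of the best window
    identities: int
    similarities: int
    equivalent_identities: float
    passes: bool


@dataclass(frozen=True)
class EvalueFit:
    """Gumbel (extreme-value) fit to a shuffled-sequence score null."""

    lam: float
    K: float
    n_shuffles: int
    seed: int
    search_space: int  # m * n

    def evalue(self, score: float) -> float:
        """Expected number of chance alignments scoring >= ``score``."""
        return self.K * self.search_space * float(np.exp(-self.lam * score))


@dataclass(frozen=True)
class NullCalibration:
    n_ligands: int
    n_receptors: int
    n_comparisons: int
    pass_fraction: float
    per_pair: pd.DataFrame  # ligand_id, receptor_id, score, window, passes
    seed: int | None


def window_identity_test(aln: PairwiseAlignment,
                         params: SignificanceParams) -> WindowResult:
    """Best sliding window of equivalent identities over alignment columns.

    Gap columns occupy window slots and contribute nothing (the stricter
    reading of "10 amino acid stretch"); alignments shorter than the window
    are evaluated over their full length. Ties go to the smallest start.
    """
    if not aln.columns:
        raise ValueError("alignment has no columns")
    classes = classify_columns(aln)
    ident = np.fromiter((c is ColumnClass.IDENTITY for c in classes),
                        dtype=np.int64, count=len(classes))
    simil = np.fromiter((c is ColumnClass.SIMILAR for c in classes),
                        dtype=np.int64, count=len(classes))
    w = min(params.window, len(classes))
    ci = np.concatenate(([0], np.cumsum(ident)))
    cs = np.concatenate(([0], np.cumsum(simil)))
    wid = ci[w:] - ci[:-w]
    wsim = cs[w:] - cs[:-w]
    equiv = wid + params.similarity_weight * wsim
    best = int(np.argmax(equiv))  # argmax keeps the smallest start on ties
    return WindowResult(
        best_start=best,
        identities=int(wid[best]),
        similarities=int(wsim[best]),
        equivalent_identities=float(equiv[best]),
        passes=bool(equiv[best] >= params.min_equivalents),
    )


def dual_criterion(aln: PairwiseAlignment,
                   params: SignificanceParams | None = None) -> bool:
    """True iff score >= we_threshold AND the windowed identity test passes."""
    params = params or SignificanceParams()
    if not aln.columns:
        return False
    if aln.score < params.we_threshold:
        return False
    return window_identity_test(aln, params).passes


def empirical_evalue(aln: PairwiseAlignment, params: AlignmentParams,
                     n_shuffles: int = 500, seed: int = 0,
                     ) -> tuple[float, EvalueFit]:
    """Empirical E-value of a local alignment score via target shuffling.

    The target composition is preserved (seeded Fisher-Yates shuffles), the
    best local score is recomputed for each shuffle, and a Gumbel
    distribution is fitted by maximum likelihood. The E-value is
    ``K * m * n * exp(-lambda * S)``. This substitutes for LALIGN's internal
    statistics; only order-of-magnitude agreement with published E-values is
    expected.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    query, target = _sequences_from_alignment(aln)
    rng = np.random.default_rng(seed)
    n = len(target)
    perms = np.empty((n_shuffles, n), dtype=np.int64)
    for k in range(n_shuffles):
        perms[k] = rng.permutation(n)
    scores = _kernels.best_local_scores_shuffled(
        query.encoded(), target.encoded(), params.matrix.scores,
        params.gap_open, params.gap_extend, perms)
    if np.all(scores == scores[0]):
        raise ValueError("cannot fit extreme-value distribution: "
                         "degenerate null (all shuffled scores equal)")
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    m = len(query)
    K = float(np.exp(loc / scale)) / (m * n)
    fit = EvalueFit(lam=lam, K=K, n_shuffles=n_shuffles, seed=seed,
                    search_space=m * n)
    return fit.evalue(aln.score), fit


def _sequences_from_alignment(aln: PairwiseAlignment):
    ctx = getattr(aln, "_context", None)
    if ctx is not None:
        return ctx
    # fall back to the aligned content itself
    q = "".join(q for q, _ in aln.columns if q != "-")
    t = "".join(t for _, t in aln.columns if t != "-")
    return (ProteinSequence(aln.query_id, q),
            ProteinSequence(aln.target_id, t))


def attach_context(aln: PairwiseAlignment, query: ProteinSequence,
                   target: ProteinSequence) -> PairwiseAlignment:
    """Attach the full operand sequences so E-values use the true m*n."""
    object.__setattr__(aln, "_context", (query, target))
    return aln


def permutation_null(ligands: list[ProteinSequence],
                     receptors: list[ProteinSequence],
                     align_params: AlignmentParams,
                     sig_params: SignificanceParams | None = None,
                     seed: int | None = None,
                     all_alignments: bool = False,
                     max_alignments: int = 20) -> NullCalibration:
    """Dual-criterion pass rate over a full ligand x receptor grid.

    By default only the best local alignment per pair is judged; with
    ``all_alignments`` every declumped sub-optimal alignment is, and a pair
    passes if any of its alignments does. The pass fraction is the empirical
    per-comparison significance level of the dual criterion.
    """
    from .align import suboptimal_alignments  # local import, avoids cycle noise
    if not ligands or not receptors:
        raise ValueError("ligand and receptor lists must be non-empty")
    sig_params = sig_params or SignificanceParams()
    rows = []
    for lig in ligands:
        for rec in receptors:
            if all_alignments:
                alns = suboptimal_alignments(lig, rec, align_params,
                                             max_alignments=max_alignments,
                                             min_score=1)
            else:
                alns = [local_align(lig, rec, align_params)]
            best = alns[0] if alns else None
            passed = any(dual_criterion(a, sig_params) for a in alns)
            rows.append({
                "ligand_id": lig.id,
                "receptor_id": rec.id,
                "score": best.score if best else 0,
                "passes": passed,
            })
    per_pair = pd.DataFrame(rows)
    n = len(per_pair)
    return NullCalibration(
        n_ligands=len(ligands), n_receptors=len(receptors), n_comparisons=n,
        pass_fraction=float(per_pair["passes"].mean()),
        per_pair=per_pair, seed=seed)


def combined_probability(p_single: float, n_matches: int) -> float:
    """The study's stated combination rule: ``p_single / n_matches``.

    This divides the single-comparison pass probability by the number of
    qualifying homologies, as printed in the source analysis (0.036/17 =
    0.0021). It is that analysis's own rule, not a standard multiple-testing
    correction; summaries report it to 2 significant figures.
    """
    if not 0 < p_single <= 1:
        raise ValueError("p_single must be in (0, 1]")
    if n_matches < 1:
        raise ValueError("n_matches must be a positive integer")
    return p_single / n_matches


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report formatting helper)."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
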