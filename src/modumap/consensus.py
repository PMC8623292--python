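"""Region stacking, position frequency matrices and consensus extraction.

Homologous region subsequences (e.g. every receptor's EC2) are stacked into
a small multiple alignment by a center-star merge of pairwise free-end-gap
alignments, from which per-position residue frequencies (the logo-plot
substrate), a modal-residue consensus, and invariant positions (frequency
exactly 1 across all members) are derived. A consensus can then be scanned,
ungapped, against any protein collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .align import (AlignmentParams, Mode, PairwiseAlignment,
                    global_align_free_ends)
from .seqio import (ALPHABET, GAP, ProteinSequence, TopologyAnnotation)
from .significance import SignificanceParams, dual_criterion


@dataclass(frozen=True)
class RegionStack:
    """Rectangular gapped alignment of one region across receptors."""

    region: str
    members: tuple[tuple[str, str], ...]  # (sequence_id, region_sequence)
    msa: tuple[str, ...]  # one gapped row per member, equal lengths

    def __post_init__(self) -> None:
        widths = {len(row) for row in self.msa}
        if len(widths) > 1:
            raise ValueError("msa rows differ in length")
        for (sid, seq), row in zip(self.members, self.msa):
            if row.replace(GAP, "") != seq:
                raise ValueError(f"msa row for {sid!r} does not ungap to its input")

    @property
    def width(self) -> int:
        return len(self.msa[0]) if self.msa else 0


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position residue counts/frequencies over a region stack.

    The frequency denominator is the number of members, so a column
    containing gaps sums below 1 — the logo occupancy convention ("zero
    being never and one being always").
    """

    region: str
    counts: np.ndarray  # (length, 21) ints over ALPHABET
    n_members: int

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_members

    def to_frame(self) -> pd.DataFrame:
        """positions x residues frequency table, 1-based position index."""
        df = pd.DataFrame(self.frequencies, columns=list(ALPHABET))
        df.index = np.arange(1, self.length + 1)
        df.index.name = "position"
        return df


@dataclass(frozen=True)
class ConsensusResult:
    region: str
    consensus: str
    invariant_positions: tuple[tuple[int, str], ...]  # (1-based msa column, residue)


def _center_star_merge(center_gapped_msa: list[str], rows: list[str],
                       center_pw: str, member_pw: str) -> None:
    """Merge one pairwise alignment into the growing MSA, in place.

    ``center_gapped_msa[0]`` is the center row accumulated so far; a gap
    inserted into the center stays forever ("once a gap, always a gap").
    """
    old_center = center_gapped_msa[0]
    new_center = []
    new_rows = [[] for _ in rows]
    new_member = []
    i = j = 0
    while i < len(old_center) or j < len(center_pw):
        old_gap = i < len(old_center) and old_center[i] == GAP
        pw_gap = j < len(center_pw) and center_pw[j] == GAP
        if i < len(old_center) and j < len(center_pw) and not old_gap and not pw_gap:
            new_center.append(old_center[i])
            for r, row in enumerate(rows):
                new_rows[r].append(row[i])
            new_member.append(member_pw[j])
            i += 1
            j += 1
        elif old_gap:
            new_center.append(GAP)
            for r, row in enumerate(rows):
                new_rows[r].append(row[i])
            new_member.append(GAP)
            i += 1
        else:  # gap in the pairwise center: insert a fresh column
            new_center.append(GAP)
            for r in range(len(rows)):
                new_rows[r].append(GAP)
            new_member.append(member_pw[j])
            j += 1
    center_gapped_msa[0] = "".join(new_center)
    for r in range(len(rows)):
        rows[r] = "".join(new_rows[r])
    rows.append("".join(new_member))


def build_region_stack(region: str,
                       receptors: list[tuple[ProteinSequence, TopologyAnnotation]],
                       align_params: AlignmentParams) -> RegionStack:
    """Extract and stack one region across receptors (center-star MSA).

    The center is the member maximising the summed pairwise free-end-gap
    scores (equivalently minimising summed distances); every other member is
    merged against it with "once a gap, always a gap". Deterministic; ties
    on the center go to input order.
    """
    if align_params.mode is not Mode.GLOBAL_FREE_ENDS:
        raise ValueError("build_region_stack requires global_free_ends params")
    members = []
    for seq, topo in receptors:
        if topo.sequence_id != seq.id:
            raise ValueError(f"topology {topo.sequence_id!r} does not annotate "
                             f"{seq.id!r}")
        start, end = topo.segment(region)  # raises if the region is absent
        members.append((seq.id, seq.residues[start - 1:end]))
    segs = [ProteinSequence(sid, s) for sid, s in members]
    if len(segs) == 1:
        return RegionStack(region, tuple(members), (segs[0].residues,))
    total = np.zeros(len(segs))
    pairwise: dict[tuple[int, int], PairwiseAlignment] = {}
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            aln = global_align_free_ends(segs[i], segs[j], align_params)
            pairwise[(i, j)] = aln
            total[i] += aln.score
            total[j] += aln.score
    center = int(np.argmax(total))
    msa_center = [segs[center].residues]
    rows: list[str] = []
    for k in range(len(segs)):
        if k == center:
            continue
        i, j = (center, k) if center < k else (k, center)
        aln = pairwise[(i, j)]
        if i == center:
            c_pw = "".join(q for q, _ in aln.columns)
            m_pw = "".join(t for _, t in aln.columns)
        else:
            c_pw = "".join(t for _, t in aln.columns)
            m_pw = "".join(q for q, _ in aln.columns)
        _center_star_merge(msa_center, rows, c_pw, m_pw)
    # restore input order
    order = [center] + [k for k in range(len(segs)) if k != center]
    merged = {orig: row for orig, row in zip(order, msa_center + rows)}
    msa = tuple(merged[k] for k in range(len(segs)))
    return RegionStack(region, tuple(members), msa)


def position_frequency_matrix(stack: RegionStack) -> PositionFrequencyMatrix:
    """Per-column residue counts; gaps excluded from the numerator."""
    if not stack.msa:
        raise ValueError("empty stack")
    counts = np.zeros((stack.width, len(ALPHABET)), dtype=np.int64)
    code = {aa: k for k, aa in enumerate(ALPHABET)}
    for row in stack.msa:
        for pos, ch in enumerate(row):
            if ch != GAP:
                counts[pos, code[ch]] += 1
    return PositionFrequencyMatrix(region=stack.region, counts=counts,
                                   n_members=len(stack.msa))


def consensus(pfm: PositionFrequencyMatrix) -> ConsensusResult:
    """Modal-residue consensus with alphabetical tie-break.

    Columns where gaps outnumber the modal residue are dropped from the
    consensus string; invariant positions (reported against 1-based msa
    columns) are those where one residue is present in every member.
    """
    if pfm.length == 0:
        raise ValueError("empty frequency matrix")
    letters: list[str] = []
    invariant: list[tuple[int, str]] = []
    for pos in range(pfm.length):
        col = pfm.counts[pos]
        top = int(np.argmax(col))  # ALPHABET is sorted, argmax tie -> alphabetical
        n_gaps = pfm.n_members - int(col.sum())
        if col[top] == 0 or n_gaps > col[top]:
            continue
        letters.append(ALPHABET[top])
        if col[top] == pfm.n_members:
            invariant.append((pos + 1, ALPHABET[top]))
    return ConsensusResult(region=pfm.region, consensus="".join(letters),
                           invariant_positions=tuple(invariant))


def consensus_scan(result: ConsensusResult, proteome: list[ProteinSequence],
                   align_params: AlignmentParams,
                   sig_params: SignificanceParams | None = None):
    """Ungapped local scan of a consensus against a protein collection.

    A local substitute for a no-gap BLAST census: the best ungapped local
    alignment of the consensus against every target, ranked by score, each
    with its dual-criterion verdict. Returns a list of
    :class:`modumap.scan.HomologyHit`.
    """
    from .scan import HomologyHit
    if not result.consensus:
        raise ValueError("empty consensus")
    sig_params = sig_params or SignificanceParams()
    query = ProteinSequence(f"consensus|{result.region}", result.consensus)
    hits = []
    for target in proteome:
        D, best, bi, bj = _kernels.fill_ungapped(
            query.encoded(), target.encoded(), align_params.matrix.scores)
        if best <= 0:
            continue
        length = 0
        i, j = bi, bj
        while D[i, j] > 0:
            i -= 1
            j -= 1
            length += 1
        cols = tuple(
            (query.residues[bi - length + k], target.residues[bj - length + k])
            for k in range(length)
        )
        aln = PairwiseAlignment(
            query_id=query.id, target_id=target.id, columns=cols,
            score=int(best), mode=Mode.LOCAL,
            query_span=(bi - length + 1, bi), target_span=(bj - length + 1, bj),
            params=align_params)
        hits.append(HomologyHit(
            peptide_id=query.id, receptor_id=target.id, alignment=aln,
            we_score=aln.score, evalue=float("nan"),
            passes=dual_criterion(aln, sig_params), regions=()))
    hits.sort(key=lambda h: (-h.we_score, h.receptor_id))
    return hits


def plot_logo(pfm: PositionFrequencyMatrix, path=None):
    """Render a simple frequency logo (stacked letters) with matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, pfm.length * 0.4), 2.5))
    freqs = pfm.frequencies
    for pos in range(pfm.length):
        bottom = 0.0
        order = np.argsort(freqs[pos])
        for k in order:
            f = freqs[pos, k]
            if f <= 0:
                continue
            ax.text(pos + 1, bottom + f / 2, ALPHABET[k],
                    ha="center", va="center", fontsize=6 + 14 * f)
            bottom += f
    ax.set_xlim(0.5, pfm.length + 0.5)
    ax.set_ylim(0, 1)
    ax.set_xlabel("position")
    ax.set_ylabel("frequency")
    ax.set_title(f"{pfm.region} ({pfm.n_members} members)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
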