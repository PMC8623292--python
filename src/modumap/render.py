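"""Text rendering of pairwise alignments.

Three-line blocks per 60 columns — query, marker line, target — with '|'
for identities, ':' for similar substitutions and spaces elsewhere, flanked
by 1-based residue coordinates.
"""

from __future__ import annotations

from .align import ColumnClass, PairwiseAlignment, classify_columns
from .seqio import GAP

_MARK = {ColumnClass.IDENTITY: "|", ColumnClass.SIMILAR: ":",
         ColumnClass.DISSIMILAR: " ", ColumnClass.GAP: " "}


def render_alignment_text(aln: PairwiseAlignment, width: int = 60) -> str:
    if not aln.columns:
        return f"{aln.query_id} vs {aln.target_id}: no alignment (score 0)\n"
    classes = classify_columns(aln)
    qname = aln.query_id[:14]
    tname = aln.target_id[:14]
    pad = max(len(qname), len(tname))
    qpos = aln.query_span[0]
    tpos = aln.target_span[0]
    blocks = []
    header = (f"{aln.query_id} vs {aln.target_id}  "
              f"score={aln.score} mode={aln.mode.value}\n")
    for off in range(0, len(aln.columns), width):
        chunk = aln.columns[off:off + width]
        marks = classes[off:off + width]
        qline = "".join(q for q, _ in chunk)
        tline = "".join(t for _, t in chunk)
        mline = "".join(_MARK[c] for c in marks)
        nq = sum(1 for c in qline if c != GAP)
        nt = sum(1 for c in tline if c != GAP)
        q_end = qpos + nq - 1 if nq else qpos
        t_end = tpos + nt - 1 if nt else tpos
        blocks.append(
            f"{qname:<{pad}} {qpos:>5} {qline} {q_end}\n"
            f"{'':<{pad}} {'':>5} {mline}\n"
            f"{tname:<{pad}} {tpos:>5} {tline} {t_end}\n"
        )
        qpos += nq
        tpos += nt
    return header + "\n".join(blocks)
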