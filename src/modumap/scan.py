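"""Peptide-module scans against receptor sequences.

The headline analysis: each opioid-peptide precursor is scanned against a
receptor with declumped sub-optimal local alignments (up to 20, BLOSUM80,
-10/-2 by default), every alignment is judged by the dual significance
criterion, passing hits are mapped onto the receptor's EC/TM/IC regions,
and per-receptor module architecture summaries are assembled.

Two named presets mirror the two parameter sets used throughout the
analysis: ``peptide-scan`` (local, -10/-2, 20 best matches) for
peptide-vs-receptor scans and ``receptor-compare`` (global free ends,
-12/-2) for receptor-vs-receptor comparisons, both on BLOSUM80.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .align import (AlignmentParams, Mode, PairwiseAlignment,
                    suboptimal_alignments)
from .conservation import ConservationSummary
from .seqio import ProteinSequence, TopologyAnnotation, load_matrix
from .significance import (SignificanceParams, attach_context, dual_criterion,
                           empirical_evalue)

#: default number of declumped alignments per peptide/receptor pair
MAX_ALIGNMENTS = 20
#: minimum receptor-residue overlap for attributing a hit to a region
MIN_OVERLAP = 3


def preset_params(name: str) -> AlignmentParams:
    """Named parameter presets for the two scan flavours."""
    if name == "peptide-scan":
        return AlignmentParams(matrix=load_matrix("BLOSUM80"), gap_open=-10,
                               gap_extend=-2, mode=Mode.LOCAL)
    if name == "receptor-compare":
        return AlignmentParams(matrix=load_matrix("BLOSUM80"), gap_open=-12,
                               gap_extend=-2, mode=Mode.GLOBAL_FREE_ENDS)
    raise ValueError(f"unknown preset {name!r}; "
                     "available: peptide-scan, receptor-compare")


@dataclass(frozen=True)
class HomologyHit:
    """One candidate module homology between a peptide and a receptor."""

    peptide_id: str
    receptor_id: str
    alignment: PairwiseAlignment
    we_score: int
    evalue: float
    passes: bool
    regions: tuple[tuple[str, int], ...]  # (region label, overlap residues)


@dataclass(frozen=True)
class ArchitectureSummary:
    """Per-region module presence joined with conservation classes."""

    receptor_id: str
    module_present: dict[str, bool]
    conservation_class: dict[str, str]
    hits: tuple[HomologyHit, ...]


def map_hit_to_regions(hit: HomologyHit, topology: TopologyAnnotation,
                       min_overlap: int = MIN_OVERLAP,
                       ) -> list[tuple[str, int]]:
    """Regions intersecting the hit's receptor span by >= ``min_overlap``.

    Intervals are 1-based inclusive; overlap lengths are exact residue
    counts, so with ``min_overlap=1`` they sum to the span length.
    """
    span = hit.alignment.target_span
    if span is None:
        return []
    if span[0] < 1 or span[1] > topology.length:
        raise ValueError(
            f"hit span {span} outside topology 1..{topology.length} "
            f"of {topology.sequence_id!r}"
        )
    out = []
    for label, start, end in topology.segments:
        overlap = min(span[1], end) - max(span[0], start) + 1
        if overlap >= min_overlap:
            out.append((label, overlap))
    return out


def scan_peptides(peptides: list[ProteinSequence],
                  receptor: ProteinSequence,
                  topology: TopologyAnnotation | None = None,
                  align_params: AlignmentParams | None = None,
                  sig_params: SignificanceParams | None = None,
                  max_alignments: int = MAX_ALIGNMENTS,
                  min_overlap: int = MIN_OVERLAP,
                  n_shuffles: int = 0,
                  seed: int = 0) -> list[HomologyHit]:
    """Scan peptide precursors against one receptor.

    For each peptide, up to ``max_alignments`` declumped sub-optimal local
    alignments become :class:`HomologyHit` records carrying the
    dual-criterion verdict, an empirical E-value (one shuffle null per
    peptide/receptor pair when ``n_shuffles`` > 0, NaN otherwise) and the
    overlapped receptor regions. Hits are sorted by (passes desc, score
    desc); per-peptide results are independent of peptide input order.
    """
    if not peptides:
        raise ValueError("no peptides supplied")
    if topology is not None and topology.sequence_id != receptor.id:
        raise ValueError(
            f"topology {topology.sequence_id!r} does not annotate "
            f"receptor {receptor.id!r}"
        )
    align_params = align_params or preset_params("peptide-scan")
    sig_params = sig_params or SignificanceParams()
    hits: list[HomologyHit] = []
    for peptide in peptides:
        alns = suboptimal_alignments(peptide, receptor, align_params,
                                     max_alignments=max_alignments,
                                     min_score=1)
        fit = None
        if alns and n_shuffles > 0:
            best = attach_context(alns[0], peptide, receptor)
            _, fit = empirical_evalue(best, align_params,
                                      n_shuffles=n_shuffles, seed=seed)
        for aln in alns:
            evalue = fit.evalue(aln.score) if fit is not None else math.nan
            hit = HomologyHit(
                peptide_id=peptide.id, receptor_id=receptor.id,
                alignment=aln, we_score=aln.score, evalue=evalue,
                passes=dual_criterion(aln, sig_params), regions=())
            if topology is not None:
                regions = tuple(map_hit_to_regions(hit, topology,
                                                   min_overlap=min_overlap))
                hit = replace(hit, regions=regions)
            hits.append(hit)
    hits.sort(key=lambda h: (not h.passes, -h.we_score,
                             h.peptide_id, h.receptor_id))
    return hits


def architecture_summary(hits: list[HomologyHit],
                         topology: TopologyAnnotation,
                         conservation: ConservationSummary | None = None,
                         ) -> ArchitectureSummary:
    """Join per-region module presence with conservation classes.

    A region carries a module iff at least one passing hit overlaps it (by
    the ``min_overlap`` already applied during region mapping).
    """
    receptor_ids = {h.receptor_id for h in hits}
    if receptor_ids and receptor_ids != {topology.sequence_id}:
        raise ValueError(
            f"hits refer to {sorted(receptor_ids)} but topology annotates "
            f"{topology.sequence_id!r}"
        )
    present = {label: False for label, _, _ in topology.segments}
    for hit in hits:
        if not hit.passes:
            continue
        for region, _ in hit.regions:
            present[region] = True
    classes = dict(conservation.classes) if conservation is not None else {}
    return ArchitectureSummary(
        receptor_id=topology.sequence_id, module_present=present,
        conservation_class=classes, hits=tuple(hits))
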