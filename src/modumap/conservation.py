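"""Topology-partitioned conservation scoring for receptor pairs.

Given a free-end-gap global alignment of two receptors and the 15-segment
EC/TM/IC topology of the reference receptor (by convention the opioid
receptor of each pair), each region gets a conserved/total fraction, where
"conserved" counts reference residues aligned to an identical or similar
(positively scoring) residue. Fractions are averaged across pairs as a mean
of per-pair fractions, reported as whole percents rounded half-up, and
classed as high (>= 70%), moderate (60-69%) or poor (<= 59%).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import ColumnClass, Mode, PairwiseAlignment, classify_columns
from .seqio import GAP, REGION_LABELS, TopologyAnnotation

CLASS_HIGH = "high"
CLASS_MODERATE = "moderate"
CLASS_POOR = "poor"


@dataclass(frozen=True)
class RegionConservationRow:
    pair_id: str
    region: str
    conserved: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.conserved <= self.total:
            raise ValueError(
                f"{self.pair_id}/{self.region}: conserved {self.conserved} "
                f"outside 0..{self.total}"
            )

    @property
    def fraction(self) -> float:
        return self.conserved / self.total


@dataclass(frozen=True)
class ConservationSummary:
    """Per-(pair, region) rows plus cross-pair percent averages and classes."""

    rows: tuple[RegionConservationRow, ...]
    averages: dict[str, int]  # region -> mean fraction as rounded percent
    classes: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        """Table shaped like a pairs x regions conservation summary."""
        df = pd.DataFrame(
            [{"pair_id": r.pair_id, "region": r.region,
              "cell": f"{r.conserved}/{r.total}"} for r in self.rows]
        ).pivot(index="pair_id", columns="region", values="cell")
        df = df[list(REGION_LABELS)]
        footer = pd.DataFrame(
            [{reg: f"{self.averages[reg]}%" for reg in REGION_LABELS},
             {reg: self.classes[reg] for reg in REGION_LABELS}],
            index=["Avg. Cons.", "class"])
        return pd.concat([df, footer])


def region_conservation(aln: PairwiseAlignment,
                        ref_topology: TopologyAnnotation,
                        pair_id: str | None = None,
                        ) -> list[RegionConservationRow]:
    """Conserved/total counts per region for one receptor pair.

    The alignment must be a free-end-gap global alignment whose query is the
    reference receptor annotated by ``ref_topology`` (so every reference
    residue occupies exactly one column); totals are the reference region
    lengths.
    """
    if aln.mode is not Mode.GLOBAL_FREE_ENDS:
        raise ValueError("region_conservation expects a global_free_ends alignment")
    n_ref = sum(1 for q, _ in aln.columns if q != GAP)
    if n_ref != ref_topology.length:
        raise ValueError(
            f"topology covers 1..{ref_topology.length} but alignment query "
            f"{aln.query_id!r} has {n_ref} residues"
        )
    pair_id = pair_id or f"{aln.query_id}|{aln.target_id}"
    conserved = {lbl: 0 for lbl in REGION_LABELS}
    classes = classify_columns(aln)
    pos = 0  # 1-based reference residue coordinate
    for (q, _), cls in zip(aln.columns, classes):
        if q == GAP:
            continue
        pos += 1
        if cls in (ColumnClass.IDENTITY, ColumnClass.SIMILAR):
            conserved[ref_topology.region_of(pos)] += 1
    lengths = ref_topology.region_lengths()
    return [RegionConservationRow(pair_id, lbl, conserved[lbl], lengths[lbl])
            for lbl in REGION_LABELS]


def _round_half_up_percent(fraction: float) -> int:
    from decimal import ROUND_HALF_UP, Decimal
    return int(Decimal(repr(fraction * 100)).quantize(Decimal("1"), ROUND_HALF_UP))


def average_conservation(rows: list[RegionConservationRow],
                         ) -> ConservationSummary:
    """Cross-pair summary: mean of per-pair fractions per region.

    Every pair must contribute all 15 regions. Averages are expressed as
    whole percents (half-up rounding) and classed on the rounded value.
    """
    by_pair: dict[str, dict[str, RegionConservationRow]] = {}
    for row in rows:
        by_pair.setdefault(row.pair_id, {})[row.region] = row
    for pair_id, regs in by_pair.items():
        missing = set(REGION_LABELS) - set(regs)
        if missing:
            raise ValueError(f"pair {pair_id!r} missing regions {sorted(missing)}")
    averages = {}
    for lbl in REGION_LABELS:
        fracs = [regs[lbl].fraction for regs in by_pair.values()]
        averages[lbl] = _round_half_up_percent(sum(fracs) / len(fracs))
    summary = ConservationSummary(rows=tuple(rows), averages=averages,
                                  classes={})
    object.__setattr__(summary, "classes", classify_regions(summary))
    return summary


def classify_regions(summary: ConservationSummary) -> dict[str, str]:
    """high >= 70%, moderate 60-69%, poor otherwise (on rounded percents)."""
    out = {}
    for region, pct in summary.averages.items():
        if pct >= 70:
            out[region] = CLASS_HIGH
        elif pct >= 60:
            out[region] = CLASS_MODERATE
        else:
            out[region] = CLASS_POOR
    return out
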