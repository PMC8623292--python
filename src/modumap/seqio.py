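"""Sequence, topology and substitution-matrix I/O.

Everything downstream assumes validated inputs: uppercase 20-letter protein
sequences (plus the ambiguity code ``X``), a fixed 15-segment EC/TM/IC
partition per receptor, and integer substitution matrices on the NCBI scale.
Coordinates are 1-based inclusive throughout, matching UniProt feature
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: alphabet used by the alignment kernels; index 20 is the ambiguity code
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

#: canonical order of the 15 receptor segments: EC1 is the N-terminal
#: extracellular tail, EC2-EC4 the three extracellular loops, TM1-TM7 the
#: seven transmembrane helices, IC1-IC3 the intracellular loops and IC4 the
#: C-terminal tail.
REGION_LABELS = (
    "EC1", "TM1", "IC1", "TM2", "EC2", "TM3", "IC2", "TM4",
    "EC3", "TM5", "IC3", "TM6", "EC4", "TM7", "IC4",
)

BUNDLED_MATRICES = ("BLOSUM80", "BLOSUM62", "BLOSUM50")

_CODE = {aa: i for i, aa in enumerate(ALPHABET)}


class SequenceError(ValueError):
    """Raised for malformed sequences, topologies or matrix requests."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence record."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _CODE:
                raise SequenceError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """Residues as int codes over :data:`ALPHABET` (X = 20)."""
        return np.fromiter(
            (_CODE[c] for c in self.residues), dtype=np.int64, count=len(self.residues)
        )


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Integer substitution scores over the 20 amino acids plus ``X``.

    ``X`` scores 0 against everything (including itself) so database
    ambiguity codes can never inflate identity or similarity statistics.
    """

    name: str
    scores: np.ndarray  # (21, 21) int64, symmetric

    def __post_init__(self) -> None:
        s = self.scores
        if s.shape != (21, 21):
            raise SequenceError("substitution matrix must be 21x21")
        if not np.array_equal(s, s.T):
            raise SequenceError(f"{self.name}: matrix not symmetric")
        if not np.all(np.diag(s)[:20] > 0):
            raise SequenceError(f"{self.name}: non-positive diagonal entry")
        if np.any(s[20, :] != 0) or np.any(s[:, 20] != 0):
            raise SequenceError(f"{self.name}: X rows must score 0")

    def score(self, a: str, b: str) -> int:
        return int(self.scores[_CODE[a], _CODE[b]])


@dataclass(frozen=True)
class TopologyAnnotation:
    """Ordered 15-segment EC/TM/IC partition of a receptor.

    Segments are (label, start, end) with 1-based inclusive coordinates,
    contiguous, non-overlapping, in the canonical order of
    :data:`REGION_LABELS`, and covering 1..length.
    """

    sequence_id: str
    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        labels = tuple(lbl for lbl, _, _ in self.segments)
        if labels != REGION_LABELS:
            raise SequenceError(
                f"topology for {self.sequence_id!r}: segments must be exactly "
                f"{REGION_LABELS} in order, got {labels}"
            )
        expected_start = 1
        for lbl, start, end in self.segments:
            if start != expected_start:
                raise SequenceError(
                    f"topology for {self.sequence_id!r}: segment {lbl} starts at "
                    f"{start}, expected {expected_start} (gap or overlap)"
                )
            if end < start:
                raise SequenceError(
                    f"topology for {self.sequence_id!r}: segment {lbl} has end "
                    f"{end} < start {start}"
                )
            expected_start = end + 1

    @property
    def length(self) -> int:
        return self.segments[-1][2]

    def segment(self, label: str) -> tuple[int, int]:
        """(start, end) of a region, 1-based inclusive."""
        for lbl, start, end in self.segments:
            if lbl == label:
                return start, end
        raise SequenceError(f"unknown region label {label!r}")

    def region_of(self, position: int) -> str:
        """Region label containing a 1-based residue position."""
        for lbl, start, end in self.segments:
            if start <= position <= end:
                return lbl
        raise SequenceError(
            f"position {position} outside topology of {self.sequence_id!r} "
            f"(1..{self.length})"
        )

    def region_lengths(self) -> dict[str, int]:
        return {lbl: end - start + 1 for lbl, start, end in self.segments}


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a multi-record FASTA file, order preserved.

    Record ids are the header up to the first whitespace; the remainder
    becomes the description. Raises on an empty file or on residues outside
    the 20-letter alphabet plus ``X``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no records")
    out = []
    for rec in records:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper(),
                                   description=desc))
    return out


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path,
                width: int = 60) -> None:
    """Write sequences as wrapped FASTA; round-trips through read_fasta."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in sequences
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)


def read_topology(path: str | Path,
                  sequence_lengths: Mapping[str, int] | None = None,
                  ) -> dict[str, TopologyAnnotation]:
    """Read a topology TSV with columns sequence_id, label, start, end.

    Rows for each sequence must appear in canonical segment order; all
    :class:`TopologyAnnotation` invariants are checked. When
    ``sequence_lengths`` is given, each annotation must cover exactly
    1..length of its sequence.
    """
    path = Path(path)
    groups: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["sequence_id", "label", "start", "end"]:
            raise SequenceError(
                f"{path}: expected header sequence_id/label/start/end, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise SequenceError(f"{path}:{lineno}: expected 4 columns")
            sid, label, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
            groups.setdefault(sid, []).append((label, start, end))
    out = {}
    for sid, segs in groups.items():
        ann = TopologyAnnotation(sequence_id=sid, segments=tuple(segs))
        if sequence_lengths is not None and sid in sequence_lengths:
            if ann.length != sequence_lengths[sid]:
                raise SequenceError(
                    f"topology for {sid!r} covers 1..{ann.length} but sequence "
                    f"has length {sequence_lengths[sid]}"
                )
        out[sid] = ann
    return out


def write_topology(annotations: Iterable[TopologyAnnotation],
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tlabel\tstart\tend\n")
        for ann in annotations:
            for label, start, end in ann.segments:
                fh.write(f"{ann.sequence_id}\t{label}\t{start}\t{end}\n")


def load_matrix(name: str) -> SubstitutionMatrix:
    """Load a bundled NCBI-format substitution matrix.

    The bundled set is BLOSUM80 (the primary matrix for all scans), BLOSUM62
    and BLOSUM50, bit-exact to the NCBI distribution (half-bit scale for
    BLOSUM80/62: e.g. BLOSUM80 W/W = 11).
    """
    if name not in BUNDLED_MATRICES:
        raise SequenceError(
            f"unknown matrix {name!r}; available: {', '.join(BUNDLED_MATRICES)}"
        )
    text = (resources.files("modumap") / "matrices" / name).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    cols = lines[0].split()
    raw: dict[str, dict[str, int]] = {}
    for line in lines[1:]:
        parts = line.split()
        raw[parts[0]] = dict(zip(cols, (int(x) for x in parts[1:])))
    scores = np.zeros((21, 21), dtype=np.int64)
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            scores[_CODE[a], _CODE[b]] = raw[a][b]
    # X row/column forced to 0 regardless of the file's B/Z/X conventions
    return SubstitutionMatrix(name=name, scores=scores)
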