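"""Synthetic class-A-GPCR-like inputs for end-to-end testing.

Generates 7TM receptor-like random sequences with the canonical 15-segment
EC/TM/IC architecture (default segment lengths on the scale of real
opioid/adrenergic receptor regions), embeds short peptide "modules" into
chosen segments at a controlled per-site divergence, and produces random
ligand x receptor grids for null calibration. Everything is bit-reproducible
given a seed. The default residue background is uniform over the 20 amino
acids so analytic collision rates are exact; a Robinson-Robinson natural
composition is available for harder nulls. Modules diverge by substitution
only (no indels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import (AMINO_ACIDS, ProteinSequence, REGION_LABELS,
                    TopologyAnnotation)

#: default region lengths (residues), on the scale of real receptor regions
DEFAULT_SEGMENT_LENGTHS: dict[str, int] = {
    "EC1": 50, "EC2": 15, "EC3": 24, "EC4": 13,
    "TM1": 27, "TM2": 24, "TM3": 22, "TM4": 22, "TM5": 25, "TM6": 26,
    "TM7": 23,
    "IC1": 11, "IC2": 19, "IC3": 55, "IC4": 70,
}

#: Robinson-Robinson amino-acid frequencies (order of seqio.AMINO_ACIDS)
ROBINSON_ROBINSON = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.052, "K": 0.057, "L": 0.090,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.059, "V": 0.064, "W": 0.013, "Y": 0.032,
}


def _background_vector(background) -> np.ndarray:
    if background is None or background == "uniform":
        vec = np.full(20, 1 / 20)
    elif background == "robinson":
        vec = np.array([ROBINSON_ROBINSON[aa] for aa in AMINO_ACIDS])
    else:
        vec = np.asarray(background, dtype=float)
        if vec.shape != (20,):
            raise ValueError("background must be a length-20 frequency vector")
    vec = vec / vec.sum()
    if np.any(vec < 0):
        raise ValueError("background frequencies must be non-negative")
    return vec


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic receptor."""

    segment_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_LENGTHS))
    background: object = None  # None/"uniform", "robinson", or 20-vector
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(REGION_LABELS) - set(self.segment_lengths)
        if missing:
            raise ValueError(f"segment_lengths missing {sorted(missing)}")
        if any(v < 1 for v in self.segment_lengths.values()):
            raise ValueError("segment lengths must be >= 1")

    @property
    def total_length(self) -> int:
        return sum(self.segment_lengths[lbl] for lbl in REGION_LABELS)


@dataclass(frozen=True)
class EmbedSpec:
    """Recipe for planting a diverged module copy into a receptor region."""

    module: ProteinSequence
    region: str
    offset: int = 0  # 0-based offset within the region
    divergence: float = 0.0  # per-site substitution probability
    seed: int = 0
    #: mutate exactly round(divergence * len(module)) positions instead of
    #: per-site sampling; controls the realised mutation fraction exactly,
    #: which matters for recovery curves on short modules where binomial
    #: variance conflates divergence levels
    exact_count: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0, 1]")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


def generate_receptor(spec: SyntheticSpec,
                      seq_id: str | None = None,
                      ) -> tuple[ProteinSequence, TopologyAnnotation]:
    """A random receptor-like sequence plus its 15-segment topology."""
    rng = np.random.default_rng(spec.seed)
    vec = _background_vector(spec.background)
    n = spec.total_length
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=n, p=vec))
    seq_id = seq_id or f"synthR{spec.seed}"
    segments = []
    pos = 1
    for lbl in REGION_LABELS:
        length = spec.segment_lengths[lbl]
        segments.append((lbl, pos, pos + length - 1))
        pos += length
    return (ProteinSequence(seq_id, residues),
            TopologyAnnotation(seq_id, tuple(segments)))


def embed_module(receptor: ProteinSequence, topology: TopologyAnnotation,
                 embed: EmbedSpec,
                 background=None,
                 ) -> tuple[ProteinSequence, tuple[int, int]]:
    """Plant a diverged copy of a module into one region.

    The module is copied into the region at the given offset, then each
    module position is independently replaced with probability
    ``divergence`` by a background residue drawn excluding the original
    (so divergence 1 leaves only background collisions). With
    ``exact_count`` set, exactly ``round(divergence * len(module))``
    positions (seeded choice) are replaced instead. Nothing outside the
    module span changes. Returns the new sequence and the 1-based inclusive
    ground-truth span in receptor coordinates.
    """
    start_r, end_r = topology.segment(embed.region)
    mod = embed.module.residues
    start = start_r + embed.offset
    end = start + len(mod) - 1
    if end > end_r:
        raise ValueError(
            f"module of length {len(mod)} at offset {embed.offset} does not "
            f"fit region {embed.region} ({start_r}..{end_r})"
        )
    rng = np.random.default_rng(embed.seed)
    vec = _background_vector(background)
    if embed.exact_count:
        n_mut = round(embed.divergence * len(mod))
        mutate = np.zeros(len(mod), dtype=bool)
        mutate[rng.choice(len(mod), size=n_mut, replace=False)] = True
    else:
        mutate = rng.random(len(mod)) < embed.divergence
    planted = []
    for k, original in enumerate(mod):
        if mutate[k]:
            weights = vec.copy()
            idx = AMINO_ACIDS.find(original)
            if idx >= 0:
                weights[idx] = 0.0
            weights = weights / weights.sum()
            planted.append(rng.choice(list(AMINO_ACIDS), p=weights))
        else:
            planted.append(original)
    residues = (receptor.residues[:start - 1] + "".join(planted)
                + receptor.residues[end:])
    return ProteinSequence(receptor.id, residues,
                           receptor.description), (start, end)


def generate_peptide(length: int, seed: int = 0, background=None,
                     pep_id: str | None = None) -> ProteinSequence:
    """One random peptide from the background composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    vec = _background_vector(background)
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=length, p=vec))
    return ProteinSequence(pep_id or f"synthP{seed}", residues)


def generate_null_grid(n_ligands: int, ligand_length: int, n_receptors: int,
                       spec: SyntheticSpec | None = None, seed: int = 0,
                       ) -> tuple[list[ProteinSequence], list[ProteinSequence]]:
    """Random ligand and receptor sets for permutation-null calibration.

    Shapes mirror the 13-ligand x 25-receptor calibration grid of the
    original study; contents are synthetic. Child seeds are spawned
    deterministically from ``seed``.
    """
    if n_ligands < 1 or n_receptors < 1 or ligand_length < 1:
        raise ValueError("grid dimensions must be positive")
    spec = spec or SyntheticSpec()
    ss = np.random.SeedSequence(seed)
    lig_seeds, rec_seeds = ss.spawn(2)
    ligands = [
        generate_peptide(ligand_length,
                         seed=child,
                         background=spec.background,
                         pep_id=f"nullL{k}")
        for k, child in enumerate(lig_seeds.spawn(n_ligands))
    ]
    receptors = []
    for k, child in enumerate(rec_seeds.spawn(n_receptors)):
        rng = np.random.default_rng(child)
        vec = _background_vector(spec.background)
        residues = "".join(rng.choice(list(AMINO_ACIDS),
                                      size=spec.total_length, p=vec))
        receptors.append(ProteinSequence(f"nullR{k}", residues))
    return ligands, receptors
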