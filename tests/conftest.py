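import numpy as np
import pytest

import modumap as mm


@pytest.fixture(scope="session")
def blosum80():
    return mm.load_matrix("BLOSUM80")


@pytest.fixture(scope="session")
def local_params(blosum80):
    """The peptide-scan parameter set: BLOSUM80, -10/-2, local."""
    return mm.AlignmentParams(matrix=blosum80, gap_open=-10, gap_extend=-2,
                              mode=mm.Mode.LOCAL)


@pytest.fixture(scope="session")
def global_params(blosum80):
    """The receptor-compare parameter set: BLOSUM80, -12/-2, free ends."""
    return mm.AlignmentParams(matrix=blosum80, gap_open=-12, gap_extend=-2,
                              mode=mm.Mode.GLOBAL_FREE_ENDS)


@pytest.fixture(scope="session")
def synth_receptor():
    """One default synthetic receptor with its topology (seed 1)."""
    return mm.generate_receptor(mm.SyntheticSpec(seed=1))


def random_protein(rng: np.random.Generator, length: int,
                   seq_id: str = "r") -> mm.ProteinSequence:
    residues = "".join(rng.choice(list(mm.AMINO_ACIDS), size=length))
    return mm.ProteinSequence(seq_id, residues)


def make_alignment(columns, params, mode=mm.Mode.LOCAL,
                   query_id="q", target_id="t"):
    """Construct a PairwiseAlignment from explicit columns.

    The score is derived from the columns (the construction invariant
    requires exact agreement), and spans are anchored at residue 1.
    """
    from modumap.align import score_columns
    nq = sum(1 for q, _ in columns if q != mm.GAP)
    nt = sum(1 for _, t in columns if t != mm.GAP)
    return mm.PairwiseAlignment(
        query_id=query_id, target_id=target_id, columns=tuple(columns),
        score=score_columns(columns, params, mode), mode=mode,
        query_span=(1, nq) if nq else None,
        target_span=(1, nt) if nt else None,
        params=params)
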