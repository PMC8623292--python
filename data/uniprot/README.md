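# User-supplied UniProt data

Two checks in the test suite compare against results computed from real
UniProt sequences. The package ships no third-party sequence data and has
no retrieval client, so these inputs must be downloaded by the user into
this directory; until they exist, the corresponding tests report failures
(deliberately not skips) with pointers here.

## Receptor-pair global score

Download the canonical FASTA records:

    curl -o P48146.fasta https://rest.uniprot.org/uniprotkb/P48146.fasta
    curl -o P35372.fasta https://rest.uniprot.org/uniprotkb/P35372.fasta

`tests/test_acceptance.py::test_receptor_pair_global_score` then aligns
NPBW2_HUMAN against OPRM_HUMAN with the receptor-compare preset (BLOSUM80,
-12/-2, global free ends) and checks the score against the published value
(778; the property fallback accepts > 700, since the original LALIGN
parameterization is not fully specified).

## Fourteen-receptor consensus

`test_study_receptor_consensus` needs the seven opioid + seven adrenergic
receptors of the original cross-species comparison:

- `study_receptors.fasta` — 14 records (zebrafish KOR + beta-2 ADR;
  stickleback MOR + alpha-1A ADR; African clawed toad MOR + alpha-1A ADR;
  mallard MOR + alpha-1A ADR; mouse KOR + beta-2 ADR; human MOR +
  alpha-1A ADR; human KOR + beta-2 ADR)
- `study_topology.tsv` — their 15-segment EC/TM/IC partitions
  (tab-separated columns `sequence_id  label  start  end`, segments in the
  order EC1, TM1, IC1, TM2, EC2, TM3, IC2, TM4, EC3, TM5, IC3, TM6, EC4,
  TM7, IC4, from the UniProtKB topology features)

The exact accession numbers appear only in figure images of the source
publication, not in its text, so accession selection is left to the user.
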