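# Methods

## Alignment model

All alignments are dynamic-programming alignments over the 20-letter amino
acid alphabet plus the ambiguity code `X`, scored with integer substitution
matrices on the NCBI scale (BLOSUM80 by default; BLOSUM62 and BLOSUM50 are
bundled). `X` scores 0 against everything and never counts as an identity
or a similarity, so database ambiguity codes cannot inflate any statistic.

The affine gap model charges `gap_open` for the first residue of a gap and
`gap_extend` for each further residue (a gap of length L costs
`gap_open + (L-1)*gap_extend`). This is the FASTA/LALIGN convention, under
which the two standard parameter sets are −10/−2 (peptide scans, local
mode) and −12/−2 (receptor comparisons, global mode with free end gaps).

Three engines share one kernel family:

* **Local (Smith–Waterman).** Gotoh three-matrix recursion with a zero
  floor; an empty alignment (score 0) is returned when no positive-scoring
  pairing exists.
* **Sub-optimal local (Waterman–Eggert declumping).** After each reported
  alignment, its aligned residue pairs — not its residues — are forbidden
  on the match transition and the full DP is re-run. This is the plain
  quadratic formulation: correctness and auditability were preferred over
  the linear-space or incremental-rescan refinements because all intended
  inputs are desk-scale (peptides ≤ ~270 aa, receptors ≤ ~500 aa).
* **Global with free end gaps.** Leading and trailing gap runs on either
  sequence cost nothing; every residue of both sequences appears in
  exactly one column (overhangs are explicit gap columns), which the
  conservation stage relies on. The degenerate arrangement in which the
  two sequences do not overlap at all is a valid free-end-gap alignment of
  score 0 and is returned when every overlapping arrangement scores below
  it.

Determinism: traceback ties prefer match/mismatch over gap-in-target over
gap-in-query, and the best cell is the first maximum in row-major order
(smallest (query, target) end coordinate). Swapping query and target
always preserves the optimal score (matrix and gap symmetry); the traced
path itself can differ on ties because the tie-break order is intentionally
asymmetric, so only score symmetry is asserted.

Every `PairwiseAlignment` recomputes its score from its own columns at
construction and rejects any mismatch, so a corrupted alignment cannot
propagate.

The DP fill loops are JIT-compiled with numba when it is importable and run
as identical pure-Python/numpy code otherwise; results are bit-equal either
way.

## Significance

A candidate hit passes the **dual criterion** iff

1. its Waterman–Eggert score is ≥ 35 (`we_threshold`), and
2. its best window of 10 consecutive alignment columns contains at least 5
   *equivalent identities*, where an identity counts 1 and a similar pair
   (unequal residues, positive substitution score) counts 0.5.

Two readings of the window were possible; the stricter one is the default:
gap columns occupy window slots and contribute nothing, so gap padding
cannot stretch the window. Fractional equivalents are compared unrounded
(4 identities + 1 similarity = 4.5 fails). Alignments shorter than the
window are evaluated over their full length.

**Empirical E-values.** The published scans relied on LALIGN's internal
extreme-value statistics, whose exact parameterization is not public. Here
the target sequence is shuffled `n_shuffles` times (composition-preserving,
seeded), the best local score is recomputed for each shuffle, and a Gumbel
distribution is fitted by maximum likelihood (`scipy.stats.gumbel_r.fit`).
With fitted location μ and scale β, λ = 1/β and K = e^{μ/β}/(mn), and
E(S) = K·m·n·e^{−λS}. Only order-of-magnitude agreement with published
E-values is expected, and E-values are reported as metadata; they do not
participate in the dual criterion. A degenerate null (all shuffled scores
equal) raises rather than fitting.

**Null calibration.** `permutation_null` runs the scan over every
(ligand, receptor) pair of a grid and reports the fraction of comparisons
with a passing hit — the empirical per-comparison significance level. By
default only the best local alignment per pair is judged (the prior
325-comparison study did not state whether sub-optimal alignments were
included; a flag enables judging all of them). Ligand composition is
preserved by default; a uniform-composition option exists.

**Combined probability.** `combined_probability(p, n) = p / n` implements
the source analysis's stated combination rule verbatim (0.036/17 = 0.0021,
reported to 2 significant figures). It is that analysis's own rule, not a
standard multiple-testing correction, and is documented as such.

## Conservation and regions

Receptor topologies are taken from user-supplied annotation files (the
15-segment EC/TM/IC partition with 1-based inclusive coordinates, matching
UniProt feature conventions); there is no built-in TM prediction, because
the analysis this package reproduces took boundaries from UniProtKB.

For a receptor pair, the reference receptor (by convention the opioid
receptor, listed first) anchors the denominators: each region's `total` is
its length on the reference, and `conserved` counts reference residues
aligned to an identity or a similar residue in the free-end-gap global
alignment. Columns pairing the reference residue with `X` count as
dissimilar.

Cross-pair averaging is the arithmetic mean of per-pair fractions,
expressed as a whole percent with half-up rounding; conservation classes
(high ≥ 70, moderate 60–69, poor otherwise) apply to the rounded percent.
On the published seven-pair table this reproduces 9 of 15 printed bottom-row
averages exactly and all 15 within 2 percentage points; pooled-count
averaging matches a different, equally incomplete subset, and the original
rounding rule is not recoverable from the printed data. The four regions
the analysis highlights (EC2 70%, TM2, TM6 76%, IC1 70%) are reproduced
under the mean-of-fractions rule.

## Consensus extraction

Region stacks are built by center-star multiple alignment: the member with
the greatest summed pairwise free-end-gap score to the others is the
center, and every other member is merged against it under "once a gap,
always a gap". For 8–30-residue segments at the conservation levels in
scope, this deterministic scheme is adequate; no iterative refinement is
attempted. Logo positions are 1-based MSA columns.

Position frequency matrices divide per-column residue counts by the number
of members (not the number of non-gap residues), mirroring logo occupancy
semantics: a column with gaps sums below 1. The consensus takes the modal
residue per column with alphabetical tie-break and drops columns where
gaps outnumber the modal residue; invariant positions are those where one
residue appears in every member. The consensus scan is ungapped (gap
transitions disabled), substituting a local alignment census for the
original proteome-wide no-gap BLAST search, which is out of scope.

## Synthetic data

The generator emulates exactly what the analysis consumes: receptor-like
sequences with the canonical 15-segment architecture (default lengths
EC1 50, EC2 15, EC3 24, EC4 13, TM1 27, TM2 24, TM3 22, TM4 22, TM5 25,
TM6 26, TM7 23, IC1 11, IC2 19, IC3 55, IC4 70 — 426 residues, on the
scale of the real receptor regions in the published comparison), embedded
peptide modules with known ground-truth spans, and ligand × receptor null
grids shaped like the 13 × 25 calibration study.

The residue background is uniform by default so collision rates are
analytically exact in tests; a Robinson–Robinson natural-composition
option provides harder nulls. Module divergence substitutes uniformly
among the other 19 residues (never the original), keeping expected
identity analytically tractable; a per-site probability is the default,
and an `exact_count` option mutates exactly `round(d·n)` positions
instead. The exact-count variant exists because, for a 15-mer, binomial
per-site mutation at nominal divergence 0.6 leaves 4–8 positions intact in
a substantial fraction of replicates — those replicates are *really* at
27–53% divergence, and recovery experiments that intend "60% of positions
mutated" would otherwise conflate divergence levels through sampling
variance. The parameter-recovery experiment in the acceptance suite uses
exact counts for this reason; with them, a planted 15-mer is recovered in
100/100 replicates at 20% mutation and 1/100 at 60% under the default scan
parameters.

What the generator does **not** emulate: indels within modules, positional
composition biases of real TM helices (hydrophobicity), phylogenetic
correlation between receptors, and real GPCR sequence motifs. Passing
synthetic tests therefore demonstrates the machinery's behaviour under the
stated statistical model, not performance on real receptor families; the
download-dependent checks against real UniProt sequences exist for the
latter and require user-supplied data (`data/uniprot/README.md`).

## Numerical and design choices

* Integer scoring throughout; −10¹² serves as −∞ in the DP (no float
  round-off in scores).
* Half-up rounding (via `decimal`) for percent averages, because banker's
  rounding would silently disagree with hand-computed published tables.
* Region attribution requires ≥ 3 residues of overlap by default
  (`min_overlap`), suppressing 1–2-residue boundary spillover; overlaps
  sum exactly to the span length at `min_overlap = 1`.
* Hit E-values reuse one Gumbel fit per peptide/receptor pair (the null
  depends only on the operand pair, not on the individual sub-alignment).
* All randomness flows from a single top-level seed; per-stage seeds are
  the first 31 bits of SHA-256 over `"<seed>:<stage>"`.
* The two named presets (`peptide-scan`: BLOSUM80 −10/−2 local, 20
  matches; `receptor-compare`: BLOSUM80 −12/−2 global free ends) pin the
  two parameter sets used throughout the original analysis.

## Known limitations

* The receptor-pair score check against the published value 778 depends on
  matrix/gap conventions of the original LALIGN runs that are not fully
  documented; the acceptance check therefore accepts > 700 as the property
  fallback and reports the delta.
* E-values are calibrated per pair by simulation; they are not
  Karlin–Altschul analytical values and should not be compared across
  different search spaces.
* The center-star MSA is not a general-purpose aligner; for long or highly
  diverged regions a dedicated MSA tool would be preferable.
* No nucleotide support, no linear-space DP, no proteome-scale search.
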