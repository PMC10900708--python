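# Methods

## The scoring model

The aligner treats pairwise protein alignment as the classical affine-gap
dynamic program, with one substitution: instead of a 20×20 log-odds table,
the match score of residues `x_i` and `y_j` is

    δ(x_i, y_j) = scale · cosine(Emb(x_i), Emb(y_j)),

with `scale = 10` by default. `Emb(·)` is a per-residue contextual vector
from a protein language model: the same residue letter scores differently
depending on its sequence context, which is what makes the score
informative for homolog pairs whose letters have diverged past the reach
of substitution statistics. Scores are kept in full floating precision —
no rounding or truncation happens before the DP. Cosine values are
clamped to [−1, 1] against floating-point drift; a zero-norm embedding
row (impossible for real language-model output, but reachable through
corrupted input files) scores 0 against everything rather than raising.

Substitution scoring over the same DP is retained as the baseline path:
tables load either by built-in name (the BLOSUM family, via Biopython's
canonical matrix data) or from any NCBI-style matrix text file. Residue
codes absent from a table (e.g. `J`) fall back to the `X` wildcard row.

## Embedding contract

An embedder adapter maps a residue string to an L×d matrix, one row per
residue — adapters must strip padding/special tokens, and the package
enforces this row-count contract at every boundary (adapter output,
embedding file loading against a known sequence length). Declared widths:
ProtT5-XL-U50 1024, ESM2-T36-3B 2560 (final layer by default; the ESM-2
adapter exposes the layer as a parameter). The model adapters are
optional plugins: the core library, CLI and test suite run entirely on
precomputed embedding files, the deterministic mock adapter, or the
synthetic generator. A known quirk of ProtT5 embeddings — anomalously
high cosine similarity among the first few residues of any two sequences
— is deliberately left uncorrected: raw cosine is used at every position,
and no positional masking or hybrid scoring is applied.

On disk, embeddings are HDF5 containers (datasets keyed by sequence id,
`model_tag` stored as an attribute) or bare whitespace text matrices as a
lowest-common-denominator interchange format.

## Dynamic programming

Both modes use the three-state Gotoh recurrence (match state plus one
insertion state per sequence). A gap of length k costs
`|open| + (k−1)·|extend|`, i.e. the opening charge covers the first
gapped position; defaults are open −11, extend −1. The implementation
permits direct transitions between the two insertion states (a gap in
one sequence immediately followed by a gap in the other, each paying an
opening charge), so the DP's path space coincides exactly with the space
of monotone aligned-pair sets — the representation the exhaustive test
oracle enumerates. Alternative conventions (opening charge *plus* a
first extension, i.e. 11 + k) are a one-line change in
`GapPenalties.run_cost`.

Local alignments start and end with an aligned pair (never a gap), and
the empty alignment with score 0 is returned when no cell is positive.
Global alignments penalize end gaps exactly like interior gaps (a true
global alignment, no semi-global variant).

### Deterministic tie-breaking

Optimal alignments are frequently non-unique, especially with
integer-valued substitution scores. Rather than leaving the choice to
implementation accident, the package defines a total order on optimal
alignments and implements it twice, independently:

1. maximize the DP score;
2. (local only) prefer the end cell with the smallest i+j, then the
   smallest i;
3. prefer the alignment whose move string read from the end backwards is
   lexicographically greatest under diagonal > up (query residue against
   a gap) > left (reference residue against a gap), with "the alignment
   starts here" ranking above diagonal — so local tracebacks stop at the
   first cell whose value is fully explained by its own pair, and
   equal-cost interleavings of adjacent gap runs canonicalize to the
   left-run-before-up-run order.

The Gotoh traceback realizes this order greedily (predecessor-state
preference M > gap-in-reference > gap-in-query, checked in that order
with exact float equality against the stored cell values); the
brute-force oracle realizes it by explicit maximization over all
enumerated candidates. The two agree on every instance tested, including
the exhaustive sweep of all 3×3 matrices with entries in {−11, 0, 10}
(a deliberately tie-saturated family). Note that exact float equality in
the traceback is sound because the traceback re-performs the identical
arithmetic operations as the fill.

The oracle enumerates strictly-increasing pair sets (a chain is a row
subset plus a column subset of equal size, matched in sorted order), so
its cost is Σ_k C(m,k)·C(n,k); it is guarded to m·n ≤ 36.

Every emitted alignment also passes a *score audit*: the score is
recomputed from the pair list and gap-run structure alone and compared to
the DP's reported score.

## Synthetic study conditions

The synthetic generator exists so that every stage — scoring, DP,
evaluation, CLI — is testable with a known ground truth and no model
download. A pair specification plants aligned residue pairs: each
planted pair (i, j) shares a latent unit vector z, and the two rows are
`normalize(z + ε)` with ε components i.i.d. N(0, σ/√d), giving an
expected planted cosine of roughly 1/(1+σ²) (≈0.96 at σ=0.2, ≈0.8 at
σ=0.5). All other rows are independent uniform random directions, whose
pairwise cosines concentrate around 0 with spread ~1/√d. Residue letters
are drawn uniformly and deliberately carry no signal about the planted
structure — the synthetic pair emulates twilight-zone homologs, which is
exactly the regime where the embedding scorer should beat a substitution
table run on the same letters.

Default conditions: 100 planted pairs, dimension 256, noise σ=0.2. The
planted pair layout comes from an indel-run process — three unaligned
runs per sequence with geometric lengths of mean 3, inserted into a
matched core — because real homolog indels cluster in loops rather than
scattering uniformly; this yields sequences of ~105–115 residues. The
noise sweep used in the recovery checks evaluates σ ∈ {0, 0.25, 0.5,
0.75, 1.0} with the same ten generator seeds at every level (common
random numbers, so the monotone-degradation comparison is paired).

What the synthetic data does *not* emulate: the heavy-tailed length
distribution of real benchmark alignments, positional correlation of
embedding noise (real language-model errors are not isotropic), the
ProtT5 first-residue anomaly, and conserved-motif letter structure.
Passing the synthetic recovery checks therefore demonstrates the
correctness of the machinery — scoring, DP, extraction, metrics — under
controlled homology, not the empirical accuracy of any particular
language model on real proteins; the latter requires the external
benchmark pipeline (BAliBASE plus a model checkpoint).

## Evaluation machinery

Benchmark MSAs (gapped FASTA, or GCG MSF as parsed by Biopython) are
decomposed into all k(k−1)/2 pairwise references in row order. Columns
where both rows hold gaps are dropped at extraction, so each reference
contains exactly the residues of its two sequences; single-gap columns
are retained. Percent identity is 100 × (identical gapless columns) /
(gapless columns) — the denominator is the gapless column count of the
reference, not the shorter sequence length, matching the "aligned
residue pairs" reading; an alignment with no gapless column has identity
0 by convention (with a warning).

Sum-of-Pairs score is |test ∩ ref| / |ref| over aligned residue index
pairs (gap columns excluded) — the reference-denominator, recall-style
definition, under which SP equals the Total Column score for pairwise
alignments. F1 is the harmonic mean of that recall and of precision
|test ∩ ref| / |test|, 0 for an empty test alignment. Evaluating against
an empty reference is an error, not a 0.

Binned summaries group per-pair results by identity (default bins
[0,10), [10,20), … percent) or by reference alignment length in columns,
residues and gaps (default bins [0,500), [500,1000), …). Bins holding
fewer than 10 alignments are flagged suppressed and report no mean, so
sparse bins cannot print skewed values; out-of-range values clamp into
the edge bins with a warning. Per-pair tables carry an `sp_is_zero`
column so complete-failure cases can be counted without a special code
path.

The score-distribution sampler contrasts aligned and random residue
pairs: per MSA, up to 100 aligned pairs sampled from the first five
pairwise alignments, and random residues (four from each of five random
sequence pairs) scored all-against-all — the two samples whose
distributions separate under embedding scoring but not under
substitution scoring on twilight-zone data.

## Numerical and interface choices

- Coordinates are 0-based, half-open everywhere internally; 1-based only
  in human-readable output. Gap characters `-` and `.` are accepted on
  input; only `-` is emitted.
- Identity/length bin edges are half-open on the left, so 9.99% falls in
  the first identity bin and 10.0% in the second.
- `GapPenalties` requires open ≤ extend ≤ 0.
- The CLI defaults reproduce the reference configuration: embedding
  scorer, scale 10, open −11, extend −1, local mode. Exit codes: 0
  success, 1 usage error, 2 data error; logs to stderr, results to files.
- Problem sizes in the test suite and acceptance script (5×5 oracle
  instances, ~110-residue synthetic pairs, 10–20 seeds per estimate) were
  chosen as the smallest sizes at which each property is sharply
  distinguishable from noise.

## Known limitations

- Real-model embedding (ProtT5/ESM-2 adapters) is declared but requires
  the optional heavy dependencies; the adapters are untested against live
  checkpoints here.
- `PFASUM60` has no built-in loader; supply it as an NCBI-style matrix
  file.
- The DP is a readable O(mn) Python implementation, adequate for
  benchmark-scale pairs (hundreds of residues), not a striped/vectorized
  aligner for database search.
- When multiple optima tie, the emitted alignment follows this package's
  declared tie-breaking; other aligners with the same objective may emit
  a different member of the optimal set (SP/F1 against a reference are
  unaffected in the generic, tie-free case).
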