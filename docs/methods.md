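# Methods

This note documents the models, conventions and design choices behind
`concatkit`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the tests do and do not
demonstrate.

## Data model and name matching

A dataset is an ordered list of marker blocks over a sparse sample
universe: a sample need not be sequenced for every marker. Samples are
matched across markers by **exact, case-sensitive string equality** of
their names. Fuzzy matching is intentionally absent — two names one edit
apart may be distinct specimens, and a silent merge cannot be audited.
The validation layer (below) exists to surface the damage that
near-miss names actually cause.

Marker and sample names are restricted to the token alphabet
`[A-Za-z0-9_.-]+`. This is the largest set that survives unquoted
round trips through relaxed Phylip and NEXUS; anything else (FASTA
descriptions, metadata-derived display names) is sanitized to it with
`_` replacements. Residues are upper-cased on ingestion and checked
against the IUPAC nucleotide alphabet plus gap `-` and missing `?`.

"Missing nucleotides" in the per-marker overview counts `?`, `N` and
`-` together; because the term is ambiguous (should alignment gaps
count?), the three counts are also reported separately so any narrower
convention is recoverable from the same table.

## Concatenation

Markers must be uniform-length (aligned) before concatenation; a ragged
marker is a hard error pointing the user at the alignment step rather
than being silently padded. The fill character for absent sample×marker
cells defaults to `?` (the NEXUS MISSING symbol) and may be `N` or `-`;
`?` is preferred because it keeps "never sequenced" distinguishable from
a sequenced ambiguous base.

Output sample order is first-appearance order across markers, refined by
a stable topological merge of the per-marker record orders: the merge
equals plain first appearance whenever the first marker contains every
sample, is deterministic always, and — unlike plain first appearance —
restricts back to each marker's own record order. That restriction
property is what makes de-concatenation an exact inverse: slicing the
supermatrix by its charsets and dropping the all-`?`/`N` padding rows
reproduces the input blocks, records and order included, for any matrix
whose per-marker orders are mutually consistent (all generated fixtures
are; hand-built matrices that order the same samples differently in
different markers round-trip to the merged order instead). A
lexicographic sort flag is available when a canonical order matters more
than input order.

Codon-position charsets for a protein-coding marker with columns
`start..end` and reading-frame offset `f ∈ {1,2,3}` are the three step-3
sets starting at `start + ((f − 1 + k − 1) mod 3)` for position `k`;
they partition the marker's columns exactly for any width ≥ 3 (widths
not divisible by 3 just give unequal cardinalities; widths < 3 are
rejected since an empty step-3 set has no `start-end` representation).
In partition command files the codon sets *replace* their marker's
whole-marker set so the emitted partition always tiles the alignment
disjointly, which is what model-selection tools require; the NEXUS SETS
block written with an alignment carries both (whole-marker sets define
the markers, codon sets annotate them).

## File formats

All writers emit `\n` line endings and a trailing newline, making
outputs byte-stable — the golden-file tests compare exact bytes.
Conventions:

* **FASTA** — header token up to the first whitespace is the sample
  name (parsing via Bio.SeqIO); configurable line wrap, 0 = unwrapped.
* **Phylip** — relaxed dialect: full-length name token terminated by
  whitespace, `ntax nchar` header. Reads auto-detect layout: an
  interleaved interpretation (names in the first block, later blocks
  cycling over taxa) is tried first, then a sequential one (sequences
  spanning lines); a file consistent under both interpretations parses
  identically either way. Strict 10-character Phylip is not written
  because it would truncate the names concatenation matches on.
* **NEXUS** — DATA/CHARACTERS block parsed with Bio.Nexus (keyword
  case-insensitivity, interleaving and FORMAT-line MISSING/GAP symbols
  honored, then normalized to `?`/`-`); the SETS block is parsed
  in-package because the `start-end\3` step notation must survive
  round trips. Charsets that overlap raise an error; uncovered columns
  raise unless explicitly kept as `unassigned_<i>` markers.
* **tsv** — spreadsheet curation format: a header row, one designated
  identifier column (default `specimen_voucher`), free-form metadata
  columns, and one `sequence_<marker>` column per marker (prefix
  configurable). Empty cells mean the sample lacks the marker — records
  are omitted, never padded. Metadata fields can be joined (separator
  `_`, empty fields skipped, sanitized, uniqueness enforced) into
  display names for the concatenated output.
* **Partition files** — IQ-TREE nexus-sets style and RAxML `DNA,`
  lines, 1-based inclusive coordinates. Reading reconstructs
  whole-marker ranges from `<name>_pos1..3` codon triples so a
  codon-partitioned sidecar suffices for de-concatenation.

Format detection sniffs content (leading `>`, `#NEXUS`, numeric
`ntax nchar` header, `DNA,` lines, tab-containing header row); the file
extension is only a tie-breaker when content is inconclusive.

## Validation

**Outlier sequences.** Column Shannon entropy is taken over the five
counted states A, C, G, T, `-`; `?`, `N` and the remaining IUPAC
ambiguity codes are treated as absence of signal and excluded (gaps are
alignment signal, ambiguity is not). The pairwise cost of two sequences
sums column entropies where both carry counted states that differ
(gap-vs-base is a mismatch, any excluded character skips the column).
Each sequence's score is the median of its costs against all other
sequences — full pairwise analysis, no sampling — and the flag threshold
is `Q3 + k·(Q3 − Q1)` over the per-sequence scores with
linear-interpolation ("type 7") quartiles. `k` defaults to 20
(conservative, suited to conserved protein-coding barcoding loci) and
can be lowered to 1 for highly variable alignments. Blocks with fewer
than four sequences are skipped (quartiles undefined). Detection is
report-only; sequences are never removed automatically, and the method
assumes outliers are rare — it degrades when a large fraction of an
alignment is misaligned.

The fence is a Tukey-style rule on an empirical distribution, so at
sensitive coefficients it has a non-trivial false-positive rate by
construction: with ~20 sequences whose mutation counts vary
binomially, `k = 1` places the fence roughly two standard deviations
above the median score, and one borderline normal sequence crosses it
in a substantial fraction of datasets *regardless of how low the
divergence is* (the exceedance probability is scale-free). A planted
wrong-locus sequence is reliably flagged and reliably carries the
maximum score; uniqueness of the flag at `k = 1` is not guaranteed and
is reported as a measured rate by the acceptance script rather than
asserted.

**Non-overlapping blocks.** The sample graph has an edge only when two
samples actually share a non-missing column in some marker — mere
co-membership in a marker is not enough, because the motivating failure
(misspelled names) produces rows that never overlap even inside one
file. Connected components (via networkx) are reported in decreasing
size; more than one component is the warning condition.

## Synthetic data

The generator fabricates datasets under a star phylogeny: per marker an
ancestral sequence is drawn uniformly over ACGT and each sample mutates
it independently per site with probability `divergence` (substituting
one of the three other bases uniformly). Whole sample×marker cells are
removed with probability `missing_fraction` (a marker is never left
empty; one record is retained). Planted defects carry truth labels:
outliers are uniformly re-drawn sequences in the first marker
(mimicking wrong-locus contamination), and split blocks rename a
fraction of samples (`X` → `X_2`) in the second half of the markers,
with only the renamed copies present there — the construction that
actually yields disjoint components. Component truth labels assume no
additional missingness.

Randomness derives from one integer seed via stable per-(marker,
sample) hashing, so adding a marker or sample never reshuffles
previously generated sequences. The generator deliberately omits
tree-structured evolution, rate heterogeneity, indel processes and
real-world name chaos; passing tests demonstrate correctness of the
bookkeeping and the detection statistics under the stated model, not
recall on real alignments.

## Problem sizes

The test suite and acceptance script use 200 matrices for format round
trips, 40 sparse matrices (up to 90% missing cells) for the
concatenation algebra, 1,000 random charset/frame pairs for codon
partitioning, 50 random blocks for oracle equivalence, 20 replicates of
20×300 for planted-outlier recovery, and a 1,000-marker × 50-sample
supermatrix (L = 100,000) for the scale run — a deliberate scaled-down
stand-in for the tens of thousands of markers the in-memory design
accommodates. The whole acceptance script completes in a few seconds on
one CPU. Entire datasets are held in memory by design; the practical
limit is the machine's RAM, not a streaming window.

## External programs

Alignment and exploratory tree building are embeddings of third-party
programs, not re-implementations: thin subprocess adapters call an
externally installed MAFFT (strategies: fast = FFT-NS-1, thorough =
G-INS-i, auto lets MAFFT choose) and FastTree, and fail with a clear
message when the binaries are absent. No test depends on them.
Reverse-complement auto-correction, protein translation, morphological
matrices and model selection are out of scope.
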