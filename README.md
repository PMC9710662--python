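# concatkit

Concatenate, partition, de-concatenate and validate multi-marker DNA
sequence datasets.

Phylogenetic projects in systematics and taxonomy routinely combine
several genetic markers — sequenced for partly overlapping sets of
specimens, curated in different files and formats — into one partitioned
*supermatrix* for combined analysis, and need to go back the other way to
run per-locus analyses. `concatkit` is a library (with a thin CLI) that
does exactly that step of the workflow:

* **import** single-marker FASTA and relaxed Phylip files, multi-marker
  NEXUS files with charset information, and tab-delimited spreadsheets
  with metadata columns plus one `sequence_<marker>` column per locus;
* **transform** the marker stream: delete, reorder and rename markers,
  and attach codon-position information to protein-coding loci;
* **concatenate** into a supermatrix, matching samples by exact
  (case-sensitive) name and padding missing markers with `?`, with
  charsets recording every marker's column range; **de-concatenate** a
  partitioned supermatrix back into per-marker files;
* **export** as FASTA, relaxed Phylip (sequential or interleaved), NEXUS
  with a SETS block, tsv, and partition command files for downstream
  model selection (IQ-TREE nexus-sets or RAxML style, with `start-end\3`
  codon sets);
* **validate** the result: per-marker outlier sequences via an
  entropy-weighted distance with an interquartile-range fence, and
  detection of non-overlapping sample blocks (the typical footprint of
  misspelled sample names).

Fuzzy sample-name matching is deliberately not offered: names that
differ by one character are sometimes genuinely different samples, and a
silent merge would be unauditable. The validation tools exist to catch
those near-misses instead.

## The statistics at the core

**Outlier sequences.** For an aligned marker with columns
\(j = 1..L\), each column gets a Shannon entropy over the counted states
{A, C, G, T, `-`} (ambiguity codes and `?` are excluded):

    H_j = − Σ_c p_cj · log2 p_cj

The cost between two sequences is `Σ_j H_j` over the columns where both
carry counted states that differ; a sequence's score is the **median**
of its pairwise costs against all other sequences (full pairwise
analysis, no sampling); and a sequence is flagged when its score exceeds

    Q3 + k · (Q3 − Q1)

of the per-sequence score distribution (quartiles by linear
interpolation). The coefficient `k` defaults to **20**, appropriate for
conserved protein-coding barcoding data; lower it toward 1 for highly
variable alignments such as rRNA loci of divergent taxa.

**Non-overlapping blocks.** Samples are nodes of a graph with an edge
whenever some marker holds records for both samples with at least one
shared column where both carry a counted state. More than one connected
component means subsets of the data share no sequence information at
all — concatenated analyses cannot relate them, and misspelled names are
the usual cause.

## Worked example

```python
from concatkit import (MarkerBlock, SequenceRecord, make_matrix,
                       marker_overview, concatenate, write_partition_file)

m1 = MarkerBlock("M1", [SequenceRecord("A", "ACGTA"), SequenceRecord("B", "AC-TA")])
m2 = MarkerBlock("M2", [SequenceRecord("B", "GGT"), SequenceRecord("C", "GCT")])
matrix = make_matrix([m1, m2])
print(marker_overview(matrix).to_string(index=False))
alignment = concatenate(matrix, fill_char="?")
for rec in alignment.records:
    print(rec.sample_name, rec.residues)
print(write_partition_file(alignment, "raxml"))
```

prints

```
marker  n_samples length  pct_missing  n_question  n_N  n_gap
    M1          2      5         10.0           0    0      1
    M2          2      3          0.0           0    0      0
A ACGTA???
B AC-TAGGT
C ?????GCT
DNA, M1 = 1-5
DNA, M2 = 6-8
```

Three samples appear in the union: A was never sequenced for M2 and C
never for M1, so those stretches are `?` padding (10% of M1's residues
are "missing" because of B's alignment gap). The partition file records
that columns 1–5 are M1 and 6–8 are M2, ready for model selection.

The `examples/` directory has one short narrative script per capability
(concatenation, format round trips, codon partitioning +
de-concatenation, validation). The same pipeline is available from the
shell:

```bash
concatkit info 16S.fasta COI.fasta
concatkit concat 16S.fasta COI.fasta --out run/ --codon COI=1
concatkit deconcat run/concatenated.nex --out loci/
concatkit validate data.tsv --iqr 1
```

Exit codes: 0 clean, 1 validation findings, 2 usage/input errors.

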