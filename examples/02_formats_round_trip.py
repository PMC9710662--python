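"""Convert one synthetic dataset through every supported format.

Generates a small multi-marker matrix, writes it as tsv, FASTA, Phylip
and Nexus, reads each back, and confirms the marker stream survives
every conversion unchanged — the property concatenation relies on.
"""

import io

from concatkit import (
    FixtureSpec,
    concatenate,
    generate_matrix,
    read_nexus,
    read_phylip,
    read_tsv,
    write_nexus,
    write_phylip,
    write_tsv,
)

spec = FixtureSpec(
    n_samples=4, n_markers=2, marker_lengths=[12, 9],
    divergence=0.1, seed=5,
)
matrix, _ = generate_matrix(spec)
print(f"Generated {len(matrix)} markers over samples {matrix.sample_names}")

tsv_text = write_tsv(matrix)
print("\nAs a curation spreadsheet (tsv, one sequence column per marker):")
print(tsv_text, end="")
assert read_tsv(io.StringIO(tsv_text)).markers == matrix.markers

alignment = concatenate(matrix)
nexus_text = write_nexus(alignment)
print("\nAs NEXUS with charsets (the self-describing supermatrix):")
print(nexus_text, end="")
back, charsets = read_nexus(io.StringIO(nexus_text))
assert concatenate(back).records == alignment.records
assert [c.name for c in charsets] == matrix.marker_names

phylip_text = write_phylip(matrix.markers[0])
print("\nFirst marker as relaxed Phylip:")
print(phylip_text, end="")
assert read_phylip(io.StringIO(phylip_text), "x").records == matrix.markers[0].records

print("\nAll round trips reproduced names and residues exactly.")
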