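"""Concatenation, de-concatenation and codon subsetting.

Concatenation joins aligned marker blocks side by side into one
supermatrix.  Samples are matched by exact name across markers; a sample
missing from a marker is padded with a fill character (default ``?``, the
Nexus MISSING symbol) over that marker's full width, so 'never sequenced'
stays distinguishable from a sequenced ambiguous base ``N``.

De-concatenation is the inverse: the whole-marker charsets slice the
supermatrix back into per-marker blocks, optionally dropping the padded
all-missing rows so no fabricated records end up in single-gene exports.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .datamodel import (
    CharSet,
    ConcatenatedAlignment,
    DataMatrix,
    MarkerBlock,
    SequenceRecord,
    merged_sample_order,
)
from .errors import (
    EmptyInputError,
    NameCollisionError,
    NotAlignedError,
)

FILL_CHARS = ("?", "N", "-")


def concatenate(
    matrix: DataMatrix,
    fill_char: str = "?",
    sort_samples: bool = False,
) -> ConcatenatedAlignment:
    """Concatenate all markers of *matrix* into one supermatrix.

    Every marker must already be uniform-length (aligned).  The output
    sample order is first-appearance order across markers, refined so it
    stays consistent with every marker's own record order (or
    lexicographic with ``sort_samples``); charsets record each marker's
    column range as running offsets, so total length L = sum of marker
    lengths.

    Raises
    ------
    NotAlignedError
        naming the first ragged marker — align it first.
    EmptyInputError
        for a matrix with no markers.
    """
    if fill_char not in FILL_CHARS:
        raise ValueError(f"fill_char must be one of {FILL_CHARS}, got {fill_char!r}")
    if not matrix.markers:
        raise EmptyInputError("cannot concatenate a matrix with no markers")
    for block in matrix:
        if not block.is_uniform_length or block.length is None:
            raise NotAlignedError(
                f"marker {block.marker_name!r} is not aligned (ragged or "
                "empty); align it before concatenating"
            )
    samples = merged_sample_order(matrix)
    if sort_samples:
        samples = sorted(samples)
    charsets: list[CharSet] = []
    offset = 0
    for block in matrix:
        charsets.append(
            CharSet(block.marker_name, offset + 1, offset + block.length)
        )
        offset += block.length
    parts: dict[str, list[str]] = {s: [] for s in samples}
    for block in matrix:
        pad = fill_char * block.length
        present = {rec.sample_name: rec.residues for rec in block.records}
        for s in samples:
            parts[s].append(present.get(s, pad))
    records = [SequenceRecord(s, "".join(parts[s])) for s in samples]
    return ConcatenatedAlignment(records, charsets)


def deconcatenate(
    alignment: ConcatenatedAlignment, drop_empty: bool = True
) -> DataMatrix:
    """Slice a supermatrix back into per-marker blocks.

    With ``drop_empty`` (the default) records consisting entirely of
    missing symbols (``?``/``N``) are omitted from a marker's block — they
    are concatenation padding, not data.
    """
    blocks = []
    for cs in alignment.charsets:
        records = []
        for rec in alignment.records:
            piece = rec.residues[cs.start - 1 : cs.end]
            if drop_empty and piece and set(piece) <= {"?", "N"}:
                continue
            records.append(SequenceRecord(rec.sample_name, piece))
        blocks.append(MarkerBlock(cs.name, records))
    return DataMatrix(blocks)


def codon_subsets(
    marker_name: str,
    marker_charset: CharSet,
    reading_frame_offset: int = 1,
) -> list[CharSet]:
    """Split a marker's column range into three codon-position charsets.

    ``reading_frame_offset`` f in {1,2,3} places codon position 1 on
    column ``start + (f - 1)``; positions cycle with period 3 and wrap
    around the marker start.  The three step-3 sets (named
    ``<marker>_pos1..3``) always partition the marker's columns exactly;
    widths not divisible by 3 simply give sets of unequal cardinality.
    Markers narrower than one codon are rejected.
    """
    if reading_frame_offset not in (1, 2, 3):
        raise ValueError("reading_frame_offset must be 1, 2 or 3")
    start, end = marker_charset.start, marker_charset.end
    if end - start + 1 < 3:
        from .errors import PartitionError

        raise PartitionError(
            f"marker {marker_name!r} spans fewer than 3 columns; codon "
            "positions are undefined"
        )
    out = []
    for k in (1, 2, 3):
        shift = (reading_frame_offset - 1 + k - 1) % 3
        out.append(CharSet(f"{marker_name}_pos{k}", start + shift, end, step=3))
    return out


def assign_codon_charsets(
    alignment: ConcatenatedAlignment,
    frames: Mapping[str, int],
) -> ConcatenatedAlignment:
    """Return a copy of *alignment* with codon charsets for chosen markers.

    *frames* maps marker name to reading-frame offset (1/2/3).  Existing
    codon charsets for other markers are preserved.
    """
    by_name = {cs.name: cs for cs in alignment.charsets}
    for marker in frames:
        if marker not in by_name:
            from .errors import UnknownMarkerError

            raise UnknownMarkerError(f"no marker named {marker!r}")
    kept = [
        c
        for c in alignment.codon_charsets
        if not any(
            by_name[m].start <= c.start <= by_name[m].end for m in frames
        )
    ]
    added: list[CharSet] = []
    for cs in alignment.charsets:
        if cs.name in frames:
            added.extend(codon_subsets(cs.name, cs, frames[cs.name]))
    return ConcatenatedAlignment(
        alignment.records, alignment.charsets, kept + added
    )


def apply_display_names(
    alignment: ConcatenatedAlignment,
    name_map: Mapping[str, str],
) -> ConcatenatedAlignment:
    """Rename alignment records through an injective display-name map.

    Samples absent from the map keep their original names.
    """
    targets = [
        name_map.get(r.sample_name, r.sample_name) for r in alignment.records
    ]
    dupes = {t for t in targets if targets.count(t) > 1}
    if dupes:
        raise NameCollisionError(
            f"display-name map sends several samples to {sorted(dupes)!r}"
        )
    records = [
        SequenceRecord(t, r.residues)
        for t, r in zip(targets, alignment.records)
    ]
    return ConcatenatedAlignment(
        records, alignment.charsets, alignment.codon_charsets
    )
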