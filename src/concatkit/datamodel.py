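"""Core in-memory types for multi-marker DNA sequence datasets.

The model mirrors how supermatrix tools think about data:

* a :class:`SequenceRecord` is one sample's residues for one genetic marker;
* a :class:`MarkerBlock` is a named collection of records for one marker
  (one locus, e.g. one alignment file);
* a :class:`DataMatrix` is an ordered collection of marker blocks over a
  shared — possibly sparse — sample universe, optionally carrying a
  metadata table keyed by sample name;
* a :class:`CharSet` is a named 1-based inclusive column range over a
  concatenated alignment, with step 3 for codon-position subsets;
* a :class:`ConcatenatedAlignment` is the supermatrix: equal-length records
  plus the whole-marker charsets that tile its columns.

Sample matching is exact and case-sensitive throughout: two records belong
to the same sample iff their names are identical strings.  Fuzzy matching
is deliberately not offered — near-identical names are sometimes distinct
samples, and silent merging would be unauditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .errors import (
    AlphabetError,
    DuplicateMarkerError,
    DuplicateSampleError,
    EmptyInputError,
    InvalidOrderError,
    PartitionError,
    TokenError,
    UnknownMarkerError,
)

#: IUPAC nucleotide codes plus gap '-' and missing '?'.
NUCLEOTIDE_ALPHABET = frozenset("ACGTURYSWKMBDHVN-?")

#: Characters counted as "missing" by the marker overview census.
MISSING_CHARS = ("?", "N", "-")

_TOKEN_RE = re.compile(r"[A-Za-z0-9_.\-]+\Z")


def is_token(name: str) -> bool:
    """True if *name* survives a round trip through Phylip/Nexus unquoted."""
    return bool(_TOKEN_RE.match(name))


def require_token(name: str, what: str = "name") -> str:
    if not isinstance(name, str) or not is_token(name):
        raise TokenError(
            f"invalid {what} {name!r}: must be a non-empty token over "
            "[A-Za-z0-9_.-] with no whitespace"
        )
    return name


def sanitize_token(raw: str) -> str:
    """Replace every character outside the token alphabet with '_'."""
    return re.sub(r"[^A-Za-z0-9_.\-]", "_", raw.strip())


@dataclass(frozen=True)
class SequenceRecord:
    """One sample's residues for one marker.

    Residues are upper-cased on construction and checked against the IUPAC
    nucleotide alphabet (plus ``-`` gap and ``?`` missing).
    """

    sample_name: str
    residues: str

    def __post_init__(self) -> None:
        require_token(self.sample_name, "sample name")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - NUCLEOTIDE_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.sample_name!r} contains characters outside the "
                f"nucleotide alphabet: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class MarkerBlock:
    """A named, ordered set of records for one genetic marker.

    Sample names must be unique inside a block.  The block may be ragged
    (records of unequal length) before alignment; ``is_uniform_length`` and
    ``length`` expose the alignment-length bookkeeping.
    """

    def __init__(self, marker_name: str, records: Iterable[SequenceRecord]):
        require_token(marker_name, "marker name")
        self.marker_name = marker_name
        self.records: list[SequenceRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_name in seen:
                raise DuplicateSampleError(
                    f"marker {marker_name!r}: duplicate sample "
                    f"{rec.sample_name!r}"
                )
            seen.add(rec.sample_name)

    @property
    def sample_names(self) -> list[str]:
        return [rec.sample_name for rec in self.records]

    @property
    def is_uniform_length(self) -> bool:
        lengths = {len(rec) for rec in self.records}
        return len(lengths) <= 1

    @property
    def length(self) -> Optional[int]:
        """Common record length, or None for ragged/empty blocks."""
        lengths = {len(rec) for rec in self.records}
        return lengths.pop() if len(lengths) == 1 else None

    def get(self, sample_name: str) -> Optional[SequenceRecord]:
        for rec in self.records:
            if rec.sample_name == sample_name:
                return rec
        return None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerBlock):
            return NotImplemented
        return (
            self.marker_name == other.marker_name
            and self.records == other.records
        )

    def __repr__(self) -> str:
        return (
            f"MarkerBlock({self.marker_name!r}, n={len(self.records)}, "
            f"length={self.length})"
        )


class DataMatrix:
    """Ordered markers over a shared, sparse sample universe.

    Marker order is significant and preserved by every transform.  A sample
    need not occur in every marker; the universe is the union of sample
    names in first-appearance order (markers scanned in matrix order).

    ``metadata`` is an optional string-valued table indexed by sample name
    (``index.name`` holds the identifier-column label, e.g.
    ``specimen_voucher``).
    """

    def __init__(
        self,
        markers: Iterable[MarkerBlock],
        metadata: Optional[pd.DataFrame] = None,
    ):
        self.markers: list[MarkerBlock] = list(markers)
        seen: set[str] = set()
        for block in self.markers:
            if block.marker_name in seen:
                raise DuplicateMarkerError(
                    f"duplicate marker name {block.marker_name!r}"
                )
            seen.add(block.marker_name)
        self.metadata = metadata

    @property
    def marker_names(self) -> list[str]:
        return [b.marker_name for b in self.markers]

    @property
    def sample_names(self) -> list[str]:
        """Sample universe in first-appearance order across markers."""
        out: list[str] = []
        seen: set[str] = set()
        for block in self.markers:
            for rec in block.records:
                if rec.sample_name not in seen:
                    seen.add(rec.sample_name)
                    out.append(rec.sample_name)
        return out

    def get_marker(self, name: str) -> MarkerBlock:
        for block in self.markers:
            if block.marker_name == name:
                return block
        raise UnknownMarkerError(f"no marker named {name!r}")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[MarkerBlock]:
        return iter(self.markers)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataMatrix):
            return NotImplemented
        if self.markers != other.markers:
            return False
        if self.metadata is None or other.metadata is None:
            return self.metadata is None and other.metadata is None
        return self.metadata.equals(other.metadata)

    def __repr__(self) -> str:
        return f"DataMatrix(markers={self.marker_names!r})"


@dataclass(frozen=True)
class CharSet:
    """A named column range over a concatenated alignment.

    Coordinates are 1-based and inclusive (the Nexus SETS convention used
    by IQ-TREE and PAUP*).  ``step == 3`` marks a codon-position subset
    written as ``start-end\\3``.
    """

    name: str
    start: int
    end: int
    step: int = 1

    def __post_init__(self) -> None:
        require_token(self.name, "charset name")
        if not (1 <= self.start <= self.end):
            raise PartitionError(
                f"charset {self.name!r}: need 1 <= start <= end, got "
                f"{self.start}-{self.end}"
            )
        if self.step not in (1, 3):
            raise PartitionError(
                f"charset {self.name!r}: step must be 1 or 3, got {self.step}"
            )

    @property
    def columns(self) -> range:
        """The 1-based columns the set selects."""
        return range(self.start, self.end + 1, self.step)

    @property
    def size(self) -> int:
        return len(self.columns)

    def to_nexus(self) -> str:
        suffix = "\\3" if self.step == 3 else ""
        return f"charset {self.name} = {self.start}-{self.end}{suffix};"


class ConcatenatedAlignment:
    """A supermatrix: equal-length records plus the charsets that tile it.

    Whole-marker charsets must be contiguous, non-overlapping and exactly
    tile columns 1..L in marker order; ``codon_charsets`` optionally carries
    the step-3 codon-position subsets derived from protein-coding markers.
    """

    def __init__(
        self,
        records: Iterable[SequenceRecord],
        charsets: Sequence[CharSet],
        codon_charsets: Sequence[CharSet] = (),
    ):
        self.records: list[SequenceRecord] = list(records)
        if not self.records:
            raise EmptyInputError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise PartitionError(
                f"alignment records have unequal lengths {sorted(lengths)}"
            )
        self.length: int = lengths.pop()
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_name in seen:
                raise DuplicateSampleError(
                    f"duplicate sample {rec.sample_name!r} in alignment"
                )
            seen.add(rec.sample_name)
        self.charsets: list[CharSet] = list(charsets)
        _check_tiling(self.charsets, self.length)
        self.codon_charsets: list[CharSet] = list(codon_charsets)

    @property
    def sample_names(self) -> list[str]:
        return [r.sample_name for r in self.records]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcatenatedAlignment):
            return NotImplemented
        return (
            self.records == other.records
            and self.charsets == other.charsets
            and self.codon_charsets == other.codon_charsets
        )

    def __repr__(self) -> str:
        return (
            f"ConcatenatedAlignment(n={len(self.records)}, L={self.length}, "
            f"markers={[c.name for c in self.charsets]!r})"
        )


def _check_tiling(charsets: Sequence[CharSet], length: int) -> None:
    """Whole-marker charsets must exactly tile 1..length without overlap."""
    if not charsets:
        raise PartitionError("alignment needs at least one charset")
    expected = 1
    for cs in charsets:
        if cs.step != 1:
            raise PartitionError(
                f"whole-marker charset {cs.name!r} must have step 1"
            )
        if cs.start != expected:
            raise PartitionError(
                f"charsets do not tile the alignment: {cs.name!r} starts at "
                f"{cs.start}, expected {expected}"
            )
        expected = cs.end + 1
    if expected != length + 1:
        raise PartitionError(
            f"charsets cover 1-{expected - 1} but the alignment has "
            f"{length} columns"
        )


def merged_sample_order(matrix: DataMatrix) -> list[str]:
    """Sample universe ordered consistently with every marker's records.

    A stable topological merge of the per-block sample orders (ties
    broken by first appearance across markers), so restricting the
    result to any one marker's samples reproduces that block's record
    order.  Equal to plain first-appearance order whenever the first
    marker contains every sample; falls back to first-appearance order
    if the block orders contradict each other.
    """
    import heapq

    rank = {s: i for i, s in enumerate(matrix.sample_names)}
    succ: dict[str, set[str]] = {s: set() for s in rank}
    pred_count = {s: 0 for s in rank}
    for block in matrix:
        names = block.sample_names
        for a, b in zip(names, names[1:]):
            if b not in succ[a]:
                succ[a].add(b)
                pred_count[b] += 1
    ready = [(rank[s], s) for s in rank if pred_count[s] == 0]
    heapq.heapify(ready)
    out: list[str] = []
    while ready:
        _, s = heapq.heappop(ready)
        out.append(s)
        for b in sorted(succ[s], key=rank.__getitem__):
            pred_count[b] -= 1
            if pred_count[b] == 0:
                heapq.heappush(ready, (rank[b], b))
    if len(out) != len(rank):
        return matrix.sample_names
    return out


# ---------------------------------------------------------------------------
# Matrix operations (pure: inputs are never mutated)
# ---------------------------------------------------------------------------

def make_matrix(
    blocks: Sequence[MarkerBlock],
    metadata: Optional[pd.DataFrame] = None,
) -> DataMatrix:
    """Assemble marker blocks into a :class:`DataMatrix`.

    Raises
    ------
    EmptyInputError
        if *blocks* is empty.
    DuplicateMarkerError
        if two blocks share a marker name.
    """
    if not blocks:
        raise EmptyInputError("cannot build a matrix from zero markers")
    return DataMatrix(list(blocks), metadata)


def marker_overview(matrix: DataMatrix) -> pd.DataFrame:
    """Per-marker summary: taxa count, length, missing-character census.

    ``pct_missing`` counts '?', 'N' and '-' together (all three individual
    counts are also reported so either narrower convention is recoverable).
    ``length`` is the common record length, or a ``min-max`` range for
    ragged (not yet aligned) markers.
    """
    rows = []
    for block in matrix:
        total = sum(len(r) for r in block.records)
        counts = {c: 0 for c in MISSING_CHARS}
        for rec in block.records:
            for c in MISSING_CHARS:
                counts[c] += rec.residues.count(c)
        n_missing = sum(counts.values())
        if block.is_uniform_length:
            length = str(block.length if block.length is not None else 0)
        else:
            lens = [len(r) for r in block.records]
            length = f"{min(lens)}-{max(lens)}"
        rows.append(
            {
                "marker": block.marker_name,
                "n_samples": len(block.records),
                "length": length,
                "pct_missing": 100.0 * n_missing / total if total else 0.0,
                "n_question": counts["?"],
                "n_N": counts["N"],
                "n_gap": counts["-"],
            }
        )
    columns = [
        "marker", "n_samples", "length", "pct_missing",
        "n_question", "n_N", "n_gap",
    ]
    return pd.DataFrame(rows, columns=columns)


def delete_markers(matrix: DataMatrix, names: Iterable[str]) -> DataMatrix:
    """Return a matrix without the named markers (order preserved)."""
    names = set(names)
    unknown = names - set(matrix.marker_names)
    if unknown:
        raise UnknownMarkerError(f"cannot delete unknown markers {sorted(unknown)!r}")
    kept = [b for b in matrix.markers if b.marker_name not in names]
    return DataMatrix(kept, matrix.metadata)


def reorder_markers(matrix: DataMatrix, order: Sequence[str]) -> DataMatrix:
    """Return a matrix with markers rearranged to *order* (a permutation)."""
    if sorted(order) != sorted(matrix.marker_names) or len(order) != len(
        set(order)
    ):
        raise InvalidOrderError(
            f"order {list(order)!r} is not a permutation of "
            f"{matrix.marker_names!r}"
        )
    by_name = {b.marker_name: b for b in matrix.markers}
    return DataMatrix([by_name[n] for n in order], matrix.metadata)


def rename_marker(matrix: DataMatrix, old: str, new: str) -> DataMatrix:
    """Return a matrix with marker *old* renamed to *new*."""
    require_token(new, "marker name")
    if old not in matrix.marker_names:
        raise UnknownMarkerError(f"no marker named {old!r}")
    if new != old and new in matrix.marker_names:
        raise DuplicateMarkerError(f"marker {new!r} already exists")
    blocks = [
        MarkerBlock(new, b.records) if b.marker_name == old else b
        for b in matrix.markers
    ]
    return DataMatrix(blocks, matrix.metadata)
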