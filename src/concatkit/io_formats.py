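"""Readers and writers for every supported sequence-data format.

Each reader feeds the in-memory marker model (:mod:`concatkit.datamodel`),
and each writer consumes it, so any format converts to any other through
the same standardized stream of markers:

* FASTA — one marker per file; the header token up to the first whitespace
  is the sample name (Bio.SeqIO does the parsing).
* Phylip — relaxed dialect: names of any length terminated by whitespace,
  sequential and interleaved layouts auto-detected on read.
* NEXUS — DATA/CHARACTERS block (Bio.Nexus does the parsing) plus a SETS
  block whose ``charset`` lines carve the matrix into markers; codon
  subsets use the ``start-end\\3`` step notation.
* TSV — spreadsheet curation format: metadata columns plus one
  ``sequence_<marker>`` column per marker.
* Partition files — IQ-TREE nexus-sets style and RAxML-style, for
  downstream model selection.

All writers emit ``\\n`` line endings and a trailing newline so output is
byte-stable across platforms; every ``read_F(write_F(x))`` round trip
reproduces names, residues and marker boundaries exactly.

Sources may be a filesystem path (``str``/``Path``) or an open text handle.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Nexus import Nexus as BioNexus

from .datamodel import (
    CharSet,
    ConcatenatedAlignment,
    DataMatrix,
    MarkerBlock,
    SequenceRecord,
    is_token,
    merged_sample_order,
    sanitize_token,
)
from .errors import (
    DuplicateSampleError,
    EmptyInputError,
    FormatError,
    NameCollisionError,
    NotAlignedError,
    PartitionError,
    UnknownFormatError,
)

Source = Union[str, Path, TextIO]

_DIALECT_OPTIONS = {
    "fasta": {"line_width"},
    "phylip": {"interleaved"},
    "nexus": {"interleaved"},
    "tsv": {"marker_prefix", "id_column", "name_fields", "separator"},
    "partition": {"style"},
}

_EXTENSION_MAP = {
    ".fasta": "fasta", ".fa": "fasta", ".fas": "fasta", ".fna": "fasta",
    ".phy": "phylip", ".phylip": "phylip",
    ".nex": "nexus", ".nexus": "nexus", ".nxs": "nexus",
    ".tsv": "tsv", ".tab": "tsv",
    ".part": "partition", ".partition": "partition",
}


@dataclass(frozen=True)
class FormatDialect:
    """A format identifier plus per-format dialect options.

    Only option keys defined for the format are accepted, so typos fail
    loudly instead of being silently ignored.
    """

    format_id: str
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.format_id not in _DIALECT_OPTIONS:
            raise UnknownFormatError(f"unknown format id {self.format_id!r}")
        extra = set(self.options) - _DIALECT_OPTIONS[self.format_id]
        if extra:
            raise FormatError(
                f"options {sorted(extra)!r} are not defined for format "
                f"{self.format_id!r}"
            )


def _read_text(source: Source) -> str:
    if isinstance(source, (str, Path)):
        try:
            return Path(source).read_text(encoding="utf-8")
        except UnicodeDecodeError as exc:
            raise UnknownFormatError(f"{source}: not a text file") from exc
    return source.read()


def _source_stem(source: Source) -> Optional[str]:
    if isinstance(source, (str, Path)):
        return sanitize_token(Path(source).stem)
    name = getattr(source, "name", None)
    if isinstance(name, str) and name and not name.startswith("<"):
        return sanitize_token(Path(name).stem)
    return None


def _records_of(block_or_alignment) -> list[SequenceRecord]:
    records = list(block_or_alignment.records)
    if not records:
        raise EmptyInputError("refusing to write a file with no sequences")
    return records


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: Source, marker_name: Optional[str] = None) -> MarkerBlock:
    """Read a single-marker FASTA file.

    The header token up to the first whitespace becomes the sample name;
    sequence lines are concatenated and upper-cased.  The marker name
    defaults to the input filename stem.
    """
    if marker_name is None:
        marker_name = _source_stem(source)
        if marker_name is None:
            raise FormatError("marker_name required when reading from a bare stream")
    text = _read_text(source)
    records = [
        SequenceRecord(rec.id, str(rec.seq))
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise EmptyInputError("FASTA input contains no sequences")
    return MarkerBlock(marker_name, records)


def write_fasta(block_or_alignment, line_width: int = 60) -> str:
    """Serialize a marker block or concatenated alignment as FASTA.

    ``line_width`` 0 means unwrapped sequences.
    """
    if line_width < 0:
        raise FormatError("line_width must be >= 0")
    out: list[str] = []
    for rec in _records_of(block_or_alignment):
        out.append(f">{rec.sample_name}\n")
        if line_width == 0:
            out.append(rec.residues + "\n")
        else:
            for i in range(0, len(rec.residues), line_width):
                out.append(rec.residues[i : i + line_width] + "\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# Phylip (relaxed dialect)
# ---------------------------------------------------------------------------

def read_phylip(source: Source, marker_name: Optional[str] = None) -> MarkerBlock:
    """Read a relaxed-Phylip file, auto-detecting the layout.

    The header line gives ``ntax nchar``; names are whitespace-terminated
    tokens of any length.  An interleaved interpretation is tried first
    (names in the first block only, later blocks cycling over taxa); if it
    does not reproduce ``ntax`` sequences of ``nchar`` columns, a
    sequential interpretation (each taxon's sequence possibly spanning
    several lines) is tried.
    """
    if marker_name is None:
        marker_name = _source_stem(source) or "marker_1"
    text = _read_text(source)
    lines = text.splitlines()
    header_idx = next((i for i, ln in enumerate(lines) if ln.strip()), None)
    if header_idx is None:
        raise EmptyInputError("Phylip input is empty")
    header = lines[header_idx].split()
    if len(header) < 2 or not all(tok.isdigit() for tok in header[:2]):
        raise FormatError(
            f"Phylip header must be 'ntax nchar', got {lines[header_idx]!r}"
        )
    ntax, nchar = int(header[0]), int(header[1])
    if ntax < 1 or nchar < 1:
        raise FormatError("Phylip header must declare ntax >= 1 and nchar >= 1")
    body = [ln for ln in lines[header_idx + 1 :] if ln.strip()]

    parsed = _phylip_interleaved(body, ntax, nchar)
    if parsed is None:
        parsed = _phylip_sequential(body, ntax, nchar)
    if parsed is None:
        raise FormatError(
            f"Phylip body does not match header ({ntax} taxa x {nchar} chars) "
            "under a sequential or interleaved layout"
        )
    names, seqs = parsed
    return MarkerBlock(
        marker_name, [SequenceRecord(n, s) for n, s in zip(names, seqs)]
    )


def _phylip_interleaved(body, ntax, nchar):
    if len(body) < ntax:
        return None
    names, seqs = [], []
    for line in body[:ntax]:
        parts = line.split(None, 1)
        name = parts[0]
        if not is_token(name):
            return None
        names.append(name)
        seqs.append(re.sub(r"\s", "", parts[1]) if len(parts) > 1 else "")
    extra = body[ntax:]
    if extra and len(extra) % ntax != 0:
        return None
    for i, line in enumerate(extra):
        seqs[i % ntax] += re.sub(r"\s", "", line)
    if any(len(s) != nchar for s in seqs):
        return None
    return names, seqs


def _phylip_sequential(body, ntax, nchar):
    names, seqs = [], []
    i = 0
    while i < len(body) and len(names) < ntax:
        parts = body[i].split(None, 1)
        name = parts[0]
        if not is_token(name):
            return None
        seq = re.sub(r"\s", "", parts[1]) if len(parts) > 1 else ""
        i += 1
        while len(seq) < nchar and i < len(body):
            seq += re.sub(r"\s", "", body[i])
            i += 1
        if len(seq) != nchar:
            return None
        names.append(name)
        seqs.append(seq)
    if len(names) != ntax or i != len(body):
        return None
    return names, seqs


def write_phylip(
    block_or_alignment, interleaved: bool = False, chunk: int = 60
) -> str:
    """Serialize as relaxed Phylip (full name token + single space).

    Sequential layout puts each sequence on one line; interleaved layout
    names taxa in the first block only and emits ``chunk``-column blocks
    separated by blank lines.
    """
    records = _records_of(block_or_alignment)
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise NotAlignedError(
            "Phylip requires uniform sequence length; block is ragged "
            f"(lengths {sorted(lengths)})"
        )
    nchar = lengths.pop()
    ntax = len(records)
    out = [f" {ntax} {nchar}\n"]
    if not interleaved:
        for rec in records:
            out.append(f"{rec.sample_name} {rec.residues}\n")
        return "".join(out)
    width = max(len(r.sample_name) for r in records)
    for offset in range(0, nchar, chunk):
        if offset:
            out.append("\n")
        for rec in records:
            prefix = f"{rec.sample_name:<{width}} " if offset == 0 else ""
            out.append(prefix + rec.residues[offset : offset + chunk] + "\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

_CHARSET_RE = re.compile(
    r"charset\s+([A-Za-z0-9_.\-]+)\s*=\s*(\d+)\s*-\s*(\d+)\s*(\\3)?\s*;",
    re.IGNORECASE,
)


def _parse_sets_text(text: str) -> list[CharSet]:
    match = re.search(r"begin\s+sets\s*;(.*?)\bend\s*;", text, re.I | re.S)
    if match is None:
        return []
    out = []
    for name, start, end, step in _CHARSET_RE.findall(match.group(1)):
        out.append(CharSet(name, int(start), int(end), 3 if step else 1))
    return out


def _tile_with_gaps(
    whole: list[CharSet], nchar: int, allow_gaps: bool
) -> list[CharSet]:
    """Order whole-marker charsets by start and check/patch the tiling."""
    ordered = sorted(whole, key=lambda cs: cs.start)
    tiled: list[CharSet] = []
    cursor = 1
    n_unassigned = 0
    for cs in ordered:
        if cs.start < cursor:
            raise PartitionError(
                f"charsets overlap at column {cs.start} (charset {cs.name!r})"
            )
        if cs.start > cursor:
            if not allow_gaps:
                raise PartitionError(
                    f"columns {cursor}-{cs.start - 1} are not covered by any "
                    "charset (use allow_gaps_in_partition to keep them)"
                )
            n_unassigned += 1
            tiled.append(CharSet(f"unassigned_{n_unassigned}", cursor, cs.start - 1))
        if cs.end > nchar:
            raise PartitionError(
                f"charset {cs.name!r} ends at {cs.end} but the matrix has "
                f"{nchar} columns"
            )
        tiled.append(cs)
        cursor = cs.end + 1
    if cursor != nchar + 1:
        if not allow_gaps:
            raise PartitionError(
                f"columns {cursor}-{nchar} are not covered by any charset"
            )
        n_unassigned += 1
        tiled.append(CharSet(f"unassigned_{n_unassigned}", cursor, nchar))
    return tiled


def read_nexus(
    source: Source,
    allow_gaps_in_partition: bool = False,
) -> tuple[DataMatrix, list[CharSet]]:
    """Read a NEXUS file with a DATA/CHARACTERS block and optional SETS.

    The concatenated matrix is sliced into one :class:`MarkerBlock` per
    whole-marker charset (1-based inclusive coordinates), in position
    order.  Codon-style ``start-end\\3`` charsets are returned alongside
    but do not define markers.  Without a SETS block the whole matrix
    becomes a single marker named from the file stem.  MISSING/GAP symbols
    from the FORMAT line are normalized to ``?`` and ``-``.
    """
    stem = _source_stem(source) or "marker_1"
    text = _read_text(source)
    try:
        nx = BioNexus.Nexus(io.StringIO(text))
    except BioNexus.NexusError as exc:
        raise FormatError(f"malformed NEXUS input: {exc}") from exc
    if not nx.matrix:
        raise FormatError("NEXUS input has no DATA/CHARACTERS matrix")
    missing = nx.missing or "?"
    gap = nx.gap or "-"
    trans = str.maketrans({missing.upper(): "?", gap: "-"})
    taxa = list(nx.taxlabels) if nx.taxlabels else list(nx.matrix)
    seqs = {t: str(nx.matrix[t]).upper().translate(trans) for t in taxa}
    nchar = nx.nchar
    for t, s in seqs.items():
        if len(s) != nchar:
            raise FormatError(
                f"taxon {t!r} has {len(s)} characters, dimensions say {nchar}"
            )

    parsed = _parse_sets_text(text)
    whole = [cs for cs in parsed if cs.step == 1]
    codon = [cs for cs in parsed if cs.step == 3]
    if whole:
        whole = _tile_with_gaps(whole, nchar, allow_gaps_in_partition)
    else:
        whole = [CharSet(stem, 1, nchar)]
    blocks = []
    for cs in whole:
        records = [
            SequenceRecord(t, seqs[t][cs.start - 1 : cs.end]) for t in taxa
        ]
        blocks.append(MarkerBlock(cs.name, records))
    return DataMatrix(blocks), whole + codon


def write_nexus(
    alignment: ConcatenatedAlignment,
    interleaved: bool = False,
    chunk: int = 60,
) -> str:
    """Serialize a concatenated alignment as NEXUS (DATA + SETS blocks).

    The SETS block carries one charset per marker plus any codon-position
    charsets, so the file fully describes its own partition and
    round-trips through :func:`read_nexus`.
    """
    records = _records_of(alignment)
    width = max(len(r.sample_name) for r in records)
    out = [
        "#NEXUS\n",
        "begin data;\n",
        f"dimensions ntax={len(records)} nchar={alignment.length};\n",
        "format datatype=dna missing=? gap=-"
        + (" interleave=yes" if interleaved else "")
        + ";\n",
        "matrix\n",
    ]
    if not interleaved:
        for rec in records:
            out.append(f"{rec.sample_name:<{width}} {rec.residues}\n")
    else:
        for offset in range(0, alignment.length, chunk):
            if offset:
                out.append("\n")
            for rec in records:
                out.append(
                    f"{rec.sample_name:<{width}} "
                    + rec.residues[offset : offset + chunk]
                    + "\n"
                )
    out.append(";\nend;\n")
    out.append("begin sets;\n")
    for cs in list(alignment.charsets) + list(alignment.codon_charsets):
        out.append(cs.to_nexus() + "\n")
    out.append("end;\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# Tab-separated values
# ---------------------------------------------------------------------------

DEFAULT_MARKER_PREFIX = "sequence_"
DEFAULT_ID_COLUMN = "specimen_voucher"


def read_tsv(source: Source, dialect: Optional[FormatDialect] = None) -> DataMatrix:
    """Read a multi-marker spreadsheet (tab-delimited, header row).

    Columns named ``<prefix><marker>`` (prefix default ``sequence_``) hold
    sequences; everything else is metadata.  One designated identifier
    column (default ``specimen_voucher``) supplies sample names.  Empty
    sequence cells mean the sample lacks that marker: the record is
    omitted, never padded.
    """
    opts = dict(dialect.options) if dialect else {}
    prefix = opts.get("marker_prefix", DEFAULT_MARKER_PREFIX)
    id_column = opts.get("id_column", DEFAULT_ID_COLUMN)
    text = _read_text(source)
    if not text.strip():
        raise EmptyInputError("tsv input is empty")
    df = pd.read_csv(
        io.StringIO(text), sep="\t", dtype=str, keep_default_na=False
    )
    seq_cols = [c for c in df.columns if c.startswith(prefix)]
    if not seq_cols:
        raise FormatError(
            f"tsv input has no sequence columns (prefix {prefix!r})"
        )
    meta_cols = [c for c in df.columns if c not in seq_cols]
    if id_column not in meta_cols:
        raise FormatError(
            f"tsv input lacks the identifier column {id_column!r}"
        )
    ids = [v.strip() for v in df[id_column]]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise DuplicateSampleError(
            f"duplicate identifiers in tsv input: {sorted(dupes)!r}"
        )
    blocks = []
    for col in seq_cols:
        marker = col[len(prefix):]
        records = [
            SequenceRecord(sid, cell.strip())
            for sid, cell in zip(ids, df[col])
            if cell.strip()
        ]
        blocks.append(MarkerBlock(marker, records))
    metadata = df[[c for c in meta_cols if c != id_column]].copy()
    metadata.index = pd.Index(ids, name=id_column)
    return DataMatrix(blocks, metadata)


def write_tsv(matrix: DataMatrix, dialect: Optional[FormatDialect] = None) -> str:
    """Serialize a matrix as a multi-marker spreadsheet.

    Metadata columns come first, then one ``sequence_<marker>`` column per
    marker in matrix order; absent records are empty cells.  A matrix
    without metadata gets a single identifier column synthesized from the
    sample names.
    """
    opts = dict(dialect.options) if dialect else {}
    prefix = opts.get("marker_prefix", DEFAULT_MARKER_PREFIX)
    if matrix.metadata is not None:
        id_column = matrix.metadata.index.name or DEFAULT_ID_COLUMN
        meta_cols = list(matrix.metadata.columns)
        rows = list(matrix.metadata.index)
        rows += [s for s in matrix.sample_names if s not in set(rows)]
    else:
        id_column = opts.get("id_column", DEFAULT_ID_COLUMN)
        meta_cols = []
        rows = merged_sample_order(matrix)
    header = [id_column] + meta_cols + [
        prefix + b.marker_name for b in matrix.markers
    ]
    lines = ["\t".join(header) + "\n"]
    lookup = [
        {rec.sample_name: rec.residues for rec in b.records}
        for b in matrix.markers
    ]
    for sid in rows:
        cells = [sid]
        for col in meta_cols:
            value = (
                matrix.metadata.at[sid, col]
                if matrix.metadata is not None and sid in matrix.metadata.index
                else ""
            )
            cells.append(str(value))
        for table in lookup:
            cells.append(table.get(sid, ""))
        lines.append("\t".join(cells) + "\n")
    return "".join(lines)


def build_sequence_names(
    metadata: pd.DataFrame,
    fields: Sequence[str],
    separator: str = "_",
) -> dict[str, str]:
    """Combine metadata fields into display names for concatenated output.

    Field values are joined by *separator* (empty fields skipped) and
    sanitized to the token alphabet.  The identifier index itself may be
    named among *fields*.  Raises :class:`NameCollisionError` when two rows
    collapse to the same display name.
    """
    available = set(metadata.columns) | {metadata.index.name}
    missing = [f for f in fields if f not in available]
    if missing:
        raise FormatError(f"metadata has no columns {missing!r}")
    names: dict[str, str] = {}
    collisions: dict[str, list[str]] = {}
    for sid, row in metadata.iterrows():
        parts = []
        for f in fields:
            value = str(sid) if f == metadata.index.name else str(row[f])
            value = value.strip()
            if value:
                parts.append(value)
        display = sanitize_token(separator.join(parts))
        collisions.setdefault(display, []).append(str(sid))
        names[str(sid)] = display
    clashes = {n: ids for n, ids in collisions.items() if len(ids) > 1}
    if clashes:
        raise NameCollisionError(
            f"display names collide after joining: {clashes!r}"
        )
    return names


# ---------------------------------------------------------------------------
# Partition files
# ---------------------------------------------------------------------------

def partition_sets(alignment: ConcatenatedAlignment) -> list[CharSet]:
    """Charsets forming the model-selection partition.

    Per marker, the codon-position sets replace the whole-marker set when
    present, so the emitted sets always exactly tile the alignment.
    """
    out: list[CharSet] = []
    for cs in alignment.charsets:
        codons = [
            c for c in alignment.codon_charsets if cs.start <= c.start <= cs.end
        ]
        out.extend(codons if codons else [cs])
    return out


def write_partition_file(
    alignment: ConcatenatedAlignment, style: str = "nexus_sets"
) -> str:
    """Emit a partition command file for model selection.

    ``nexus_sets`` is IQ-TREE's nexus partition input; ``raxml`` emits
    ``DNA, name = start-end`` lines.  Coordinates are 1-based inclusive
    with ``\\3`` marking codon sets.
    """
    sets = partition_sets(alignment)
    if style == "nexus_sets":
        lines = ["#nexus\n", "begin sets;\n"]
        lines += [f"  {cs.to_nexus()}\n" for cs in sets]
        lines.append("end;\n")
        return "".join(lines)
    if style == "raxml":
        return "".join(
            f"DNA, {cs.name} = {cs.start}-{cs.end}"
            + ("\\3" if cs.step == 3 else "")
            + "\n"
            for cs in sets
        )
    raise FormatError(f"unknown partition style {style!r}")


_RAXML_LINE_RE = re.compile(
    r"^\s*DNA\s*,\s*([A-Za-z0-9_.\-]+)\s*=\s*(\d+)\s*-\s*(\d+)\s*(\\3)?\s*$",
    re.IGNORECASE,
)


def read_partition_file(source: Source) -> tuple[list[CharSet], list[CharSet]]:
    """Parse a partition file (either style) into charsets.

    Returns ``(whole_marker_sets, codon_sets)``.  When a marker appears
    only as codon-position sets (``<marker>_pos1..3``), its whole-marker
    range is reconstructed from their union so de-concatenation can slice
    the alignment.
    """
    text = _read_text(source)
    raw: list[CharSet] = []
    if re.search(r"begin\s+sets", text, re.I):
        raw = _parse_sets_text(text)
    else:
        for line in text.splitlines():
            if not line.strip():
                continue
            m = _RAXML_LINE_RE.match(line)
            if m is None:
                raise FormatError(f"unparseable partition line: {line!r}")
            name, start, end, step = m.groups()
            raw.append(CharSet(name, int(start), int(end), 3 if step else 1))
    if not raw:
        raise PartitionError("partition file defines no charsets")
    whole = [cs for cs in raw if cs.step == 1]
    codon = [cs for cs in raw if cs.step == 3]
    covered = {(cs.start, cs.end) for cs in whole}
    groups: dict[str, list[CharSet]] = {}
    for cs in codon:
        m = re.match(r"(.+)_pos[123]$", cs.name)
        key = m.group(1) if m else f"__range_{cs.end}"
        groups.setdefault(key, []).append(cs)
    for key, members in groups.items():
        start = min(c.start for c in members)
        end = max(c.end for c in members)
        if (start, end) not in covered:
            name = key if not key.startswith("__range_") else f"marker_{start}_{end}"
            whole.append(CharSet(name, start, end))
            covered.add((start, end))
    whole.sort(key=lambda cs: cs.start)
    return whole, codon


# ---------------------------------------------------------------------------
# Format detection
# ---------------------------------------------------------------------------

def detect_format(source: Source) -> str:
    """Classify an input by content sniffing.

    Leading ``>`` means FASTA; ``#NEXUS`` means NEXUS (or a nexus-sets
    partition file when only a SETS block is present); a numeric
    ``ntax nchar`` header means Phylip; ``DNA,`` lines mean a RAxML
    partition file; a tab-containing header row means tsv.  The filename
    extension is consulted only when content sniffing fails.
    """
    text = _read_text(source)
    head = text[:65536]
    if "\x00" not in head:
        first = next((ln for ln in head.splitlines() if ln.strip()), "")
        stripped = first.strip()
        if stripped.startswith(">"):
            return "fasta"
        if stripped.upper().startswith("#NEXUS"):
            has_data = re.search(r"begin\s+(data|characters)\b", head, re.I)
            has_sets = re.search(r"begin\s+sets\b", head, re.I)
            return "nexus" if has_data or not has_sets else "partition"
        if re.fullmatch(r"\d+\s+\d+", stripped):
            return "phylip"
        if _RAXML_LINE_RE.match(stripped):
            return "partition"
        if "\t" in first:
            return "tsv"
    if isinstance(source, (str, Path)):
        ext = Path(source).suffix.lower()
        if ext in _EXTENSION_MAP:
            return _EXTENSION_MAP[ext]
    raise UnknownFormatError("could not recognize the input format")
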