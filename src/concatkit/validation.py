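"""Output-data validation: outlier sequences and non-overlapping blocks.

Two failure modes plague hand-curated multi-marker datasets:

* a sequence that does not belong in its alignment (wrong locus, reverse
  complement, heavy misalignment).  These are flagged per marker with an
  entropy-weighted distance in the style of SequenceBouncer: each
  alignment column gets a Shannon entropy; the cost between two sequences
  is the summed entropy of the columns where they disagree; a sequence's
  cost is the median over its pairwise comparisons; and a sequence is an
  outlier when its cost exceeds Q3 + k*(Q3 - Q1) of the per-sequence cost
  distribution.  The interquartile-range coefficient k defaults to 20 —
  suitable for protein-coding barcoding data — and can be lowered to 1
  for highly variable alignments.

* misspelled sample names splitting one sample into several, which yields
  groups of samples that share no sequenced alignment column with each
  other.  These are found as connected components of the sample graph
  whose edges require at least one column where both samples carry a
  counted (non-missing) state in the same marker.

Counted states are A, C, G, T and the gap '-' (gaps are alignment
signal); '?', 'N' and the other ambiguity codes are treated as absence
of signal and excluded everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import DataMatrix, MarkerBlock, marker_overview
from .errors import EmptyInputError, InsufficientDataError, NotAlignedError

#: Residue states entering entropy and mismatch costs, in encoding order.
COUNTED_STATES = "ACGT-"

_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(COUNTED_STATES):
    _ENCODE[ord(_c)] = _i

#: Sequences needed for quartiles of the cost distribution to make sense.
MIN_SEQUENCES = 4

DEFAULT_IQR_COEFFICIENT = 20.0


@dataclass(frozen=True)
class OutlierCall:
    """Per-sequence outlier verdict for one marker."""

    sample_name: str
    marker_name: str
    cost: float
    threshold: float
    is_outlier: bool


@dataclass(frozen=True)
class OverlapReport:
    """Connected components of the sample-overlap graph.

    Components are ordered by decreasing size (ties broken by the
    lexicographically smallest member).  A single component means every
    sample is linked to every other through shared sequenced columns;
    more than one is the warning condition typical of misspelled names.
    """

    components: tuple[frozenset[str], ...]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def is_connected(self) -> bool:
        return len(self.components) <= 1


def _encode(seqs: list[str]) -> np.ndarray:
    """Encode sequences to int8: 0..4 counted states, -1 excluded."""
    arr = np.frombuffer(
        "".join(seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(seqs), -1)
    return _ENCODE[arr]


def column_entropy(column: str) -> float:
    """Shannon entropy (bits) of one alignment column.

    Frequencies are taken over the counted states A, C, G, T and '-';
    excluded characters do not contribute.  A column with no counted
    state has entropy 0 by convention.
    """
    if not column:
        raise EmptyInputError("column must be non-empty")
    codes = _encode([column])[0]
    counts = np.bincount(codes[codes >= 0], minlength=5)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _column_entropies(encoded: np.ndarray) -> np.ndarray:
    """Vectorized per-column entropies for an encoded block (n x L)."""
    n, L = encoded.shape
    counts = np.zeros((5, L), dtype=np.int64)
    for state in range(5):
        counts[state] = (encoded == state).sum(axis=0)
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=0)


def pairwise_cost(seq_i: str, seq_j: str, entropies) -> float:
    """Entropy-weighted mismatch cost between two aligned sequences.

    Sums the column entropies over columns where both sequences carry
    counted states that differ; columns where either side is excluded
    ('?', 'N', other ambiguity codes) are skipped.  Gap versus base is a
    mismatch.
    """
    if len(seq_i) != len(seq_j):
        raise NotAlignedError(
            f"sequences differ in length ({len(seq_i)} vs {len(seq_j)})"
        )
    ent = np.asarray(entropies, dtype=float)
    if ent.shape[0] != len(seq_i):
        raise NotAlignedError("entropies must give one value per column")
    enc = _encode([seq_i, seq_j])
    mask = (enc[0] >= 0) & (enc[1] >= 0) & (enc[0] != enc[1])
    return float(ent[mask].sum())


def _cost_matrix(encoded: np.ndarray, entropies: np.ndarray) -> np.ndarray:
    """Full symmetric matrix of pairwise mismatch-entropy costs."""
    n = encoded.shape[0]
    costs = np.zeros((n, n), dtype=float)
    for i in range(n):
        a = encoded[i]
        rest = encoded[i + 1 :]
        if rest.size == 0:
            continue
        mask = (a >= 0) & (rest >= 0) & (a != rest)
        row = mask @ entropies
        costs[i, i + 1 :] = row
        costs[i + 1 :, i] = row
    return costs


def detect_outliers(
    block: MarkerBlock,
    iqr_coefficient: float = DEFAULT_IQR_COEFFICIENT,
) -> list[OutlierCall]:
    """Flag outlier sequences in one aligned marker.

    Performs the full pairwise analysis (no sampling): each sequence's
    cost is the median of its entropy-weighted mismatch costs against all
    other sequences, and the outlier threshold is Q3 + k*(Q3 - Q1) over
    the per-sequence costs, with quartiles by linear interpolation.
    Smaller k flags more sequences; the default of 20 is conservative.

    Raises
    ------
    InsufficientDataError
        for blocks of fewer than four sequences (quartiles undefined).
    NotAlignedError
        for ragged blocks.
    """
    if iqr_coefficient <= 0:
        raise ValueError("iqr_coefficient must be positive")
    if len(block) < MIN_SEQUENCES:
        raise InsufficientDataError(
            f"marker {block.marker_name!r} has {len(block)} sequences; "
            f"outlier detection needs at least {MIN_SEQUENCES}"
        )
    if not block.is_uniform_length:
        raise NotAlignedError(
            f"marker {block.marker_name!r} is ragged; align it first"
        )
    encoded = _encode([rec.residues for rec in block.records])
    entropies = _column_entropies(encoded)
    costs = _cost_matrix(encoded, entropies)
    n = len(block)
    off_diag = costs[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    per_seq = np.median(off_diag, axis=1)
    q1, q3 = np.percentile(per_seq, [25, 75])
    threshold = float(q3 + iqr_coefficient * (q3 - q1))
    return [
        OutlierCall(
            sample_name=rec.sample_name,
            marker_name=block.marker_name,
            cost=float(per_seq[i]),
            threshold=threshold,
            is_outlier=bool(per_seq[i] > threshold),
        )
        for i, rec in enumerate(block.records)
    ]


def find_nonoverlapping_blocks(matrix: DataMatrix) -> OverlapReport:
    """Partition samples into groups connected by shared sequenced columns.

    Two samples are linked when some marker contains records for both
    with at least one column where both carry a counted state.  More than
    one connected component means subsets of samples share no sequence
    information at all — downstream concatenated analyses cannot relate
    them, and misspelled sample names are the usual cause.
    """
    graph = nx.Graph()
    graph.add_nodes_from(matrix.sample_names)
    for block in matrix:
        if not block.records:
            continue
        names = block.sample_names
        if block.is_uniform_length and len(names) > 1:
            coverage = _encode([r.residues for r in block.records]) >= 0
            overlap = coverage @ coverage.T
            ii, jj = np.nonzero(np.triu(overlap, k=1))
            graph.add_edges_from((names[i], names[j]) for i, j in zip(ii, jj))
        else:
            # ragged marker: compare column coverage pairwise up to the
            # shorter sequence
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a = block.records[i].residues
                    b = block.records[j].residues
                    m = min(len(a), len(b))
                    enc = _encode([a[:m], b[:m]]) if m else None
                    if m and bool(((enc[0] >= 0) & (enc[1] >= 0)).any()):
                        graph.add_edge(names[i], names[j])
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return OverlapReport(components=tuple(comps))


@dataclass
class ValidationReport:
    """Bundle of every validation finding for one matrix."""

    overview: pd.DataFrame
    outlier_calls: dict[str, list[OutlierCall]]
    skipped_markers: list[str]
    overlap: OverlapReport
    iqr_coefficient: float

    @property
    def outliers(self) -> list[OutlierCall]:
        return [
            c
            for calls in self.outlier_calls.values()
            for c in calls
            if c.is_outlier
        ]

    @property
    def has_findings(self) -> bool:
        return bool(self.outliers) or not self.overlap.is_connected

    def to_records(self) -> list[dict]:
        """Machine-readable findings, one record per finding."""
        out: list[dict] = []
        for call in self.outliers:
            out.append(
                {
                    "finding": "outlier_sequence",
                    "marker": call.marker_name,
                    "sample": call.sample_name,
                    "cost": call.cost,
                    "threshold": call.threshold,
                }
            )
        if not self.overlap.is_connected:
            for i, comp in enumerate(self.overlap.components, start=1):
                out.append(
                    {
                        "finding": "nonoverlapping_block",
                        "component": i,
                        "n_samples": len(comp),
                        "samples": sorted(comp),
                    }
                )
        for marker in self.skipped_markers:
            out.append(
                {
                    "finding": "outlier_check_skipped",
                    "marker": marker,
                    "reason": f"fewer than {MIN_SEQUENCES} sequences",
                }
            )
        return out

    def to_text(self) -> str:
        lines = ["Marker overview", "---------------"]
        lines.append(self.overview.to_string(index=False))
        lines.append("")
        lines.append(f"Outlier check (IQR coefficient {self.iqr_coefficient:g})")
        lines.append("-" * 40)
        if self.outliers:
            for c in self.outliers:
                lines.append(
                    f"  OUTLIER {c.sample_name} in {c.marker_name}: "
                    f"cost {c.cost:.4f} > threshold {c.threshold:.4f}"
                )
        else:
            lines.append("  no outlier sequences flagged")
        for marker in self.skipped_markers:
            lines.append(
                f"  note: marker {marker} skipped "
                f"(fewer than {MIN_SEQUENCES} sequences)"
            )
        lines.append("")
        lines.append("Sample overlap")
        lines.append("--------------")
        if self.overlap.is_connected:
            lines.append("  all samples connected through shared columns")
        else:
            lines.append(
                f"  WARNING: {self.overlap.n_components} non-overlapping "
                "sample blocks (check for misspelled names)"
            )
            for i, comp in enumerate(self.overlap.components, start=1):
                members = ", ".join(sorted(comp))
                lines.append(f"  block {i} ({len(comp)} samples): {members}")
        return "\n".join(lines) + "\n"


def validation_report(
    matrix: DataMatrix,
    iqr_coefficient: float = DEFAULT_IQR_COEFFICIENT,
) -> ValidationReport:
    """Run every validation on a matrix and bundle the results.

    Markers with fewer than four sequences are skipped by the outlier
    check (with a notice); ragged markers are likewise skipped since the
    entropy model needs aligned columns.
    """
    if not matrix.markers:
        raise EmptyInputError("cannot validate an empty matrix")
    calls: dict[str, list[OutlierCall]] = {}
    skipped: list[str] = []
    for block in matrix:
        if len(block) < MIN_SEQUENCES or not block.is_uniform_length:
            skipped.append(block.marker_name)
            continue
        calls[block.marker_name] = detect_outliers(block, iqr_coefficient)
    return ValidationReport(
        overview=marker_overview(matrix),
        outlier_calls=calls,
        skipped_markers=skipped,
        overlap=find_nonoverlapping_blocks(matrix),
        iqr_coefficient=iqr_coefficient,
    )
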