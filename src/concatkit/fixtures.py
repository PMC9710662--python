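"""Deterministic synthetic multi-marker datasets.

Every reader, transform and validator in the package is testable without
downloads: this module fabricates matrices with known ground truth.  The
model is a star phylogeny — per marker an ancestral sequence is drawn
uniformly over ACGT and each sample mutates it independently per site —
which is all the structure format handling and validation need (no
tree-shaped evolution is simulated).

Planted defects come with truth labels:

* outliers — a sample's sequence in the first marker is re-drawn
  uniformly at random instead of mutated, mimicking a wrong-locus or
  shuffled sequence;
* split blocks — a fraction of samples appear under perturbed names
  (``X`` -> ``X_2``) in the second half of the markers, and only those
  perturbed copies populate that half, which yields the disjoint
  sample blocks misspelled names produce in real datasets.

Randomness is one integer seed; per-(marker, sample) substreams are
derived by stable hashing, so adding a marker or sample never reshuffles
the sequences already generated.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import DataMatrix, MarkerBlock, SequenceRecord
from .errors import FixtureSpecError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``divergence`` is the per-site substitution probability away from the
    marker's ancestral sequence; ``missing_fraction`` removes whole
    sample-x-marker cells (the sample was never sequenced for that
    marker); ``split_fraction`` plants non-overlapping name blocks and
    needs at least two markers.
    """

    n_samples: int
    n_markers: int
    marker_lengths: Sequence[int]
    missing_fraction: float = 0.0
    divergence: float = 0.0
    n_outliers: int = 0
    split_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_markers < 1:
            raise FixtureSpecError("need at least one sample and one marker")
        if len(self.marker_lengths) != self.n_markers:
            raise FixtureSpecError(
                f"marker_lengths has {len(self.marker_lengths)} entries for "
                f"{self.n_markers} markers"
            )
        if any(length < 1 for length in self.marker_lengths):
            raise FixtureSpecError("marker lengths must be positive")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise FixtureSpecError("missing_fraction must be in [0, 1)")
        if not (0.0 <= self.divergence <= 1.0):
            raise FixtureSpecError("divergence must be in [0, 1]")
        if not (0.0 <= self.split_fraction < 1.0):
            raise FixtureSpecError("split_fraction must be in [0, 1)")
        if self.n_outliers >= self.n_samples:
            raise FixtureSpecError("n_outliers must be smaller than n_samples")
        if self.n_outliers < 0:
            raise FixtureSpecError("n_outliers must be non-negative")
        if self.split_fraction > 0 and self.n_markers < 2:
            raise FixtureSpecError("split blocks need at least two markers")


@dataclass
class FixtureTruth:
    """Ground-truth labels emitted alongside a generated matrix."""

    outliers: list[tuple[str, str]] = field(default_factory=list)  # (sample, marker)
    components: Optional[list[set[str]]] = None
    absent_cells: set[tuple[str, str]] = field(default_factory=set)  # (sample, marker)


def _stream(seed: int, *keys) -> np.random.Generator:
    """Independent substream keyed by stable string hashing."""
    digest = zlib.crc32(":".join(str(k) for k in keys).encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, digest])
    )


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(
    rng: np.random.Generator, ancestral: np.ndarray, divergence: float
) -> np.ndarray:
    seq = ancestral.copy()
    if divergence > 0:
        hit = rng.random(len(seq)) < divergence
        # substitute with one of the three other bases, uniformly
        idx = np.searchsorted(_BASES, seq[hit])
        seq[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.sum())) % 4]
    return seq


def sample_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def marker_names(m: int) -> list[str]:
    width = max(2, len(str(m)))
    return [f"M{j + 1:0{width}d}" for j in range(m)]


def generate_matrix(spec: FixtureSpec) -> tuple[DataMatrix, FixtureTruth]:
    """Generate a matrix and its truth labels from *spec*.

    Reproducible: identical spec (including seed) gives byte-identical
    output.  Outliers are planted in the first marker and are never
    removed by missingness.  Truth component labels assume
    ``missing_fraction == 0`` when ``split_fraction > 0`` (missing cells
    could otherwise isolate further samples).
    """
    samples = sample_names(spec.n_samples)
    markers = marker_names(spec.n_markers)
    truth = FixtureTruth()

    outlier_set: set[str] = set()
    if spec.n_outliers:
        picks = _stream(spec.seed, "outliers").choice(
            spec.n_samples, size=spec.n_outliers, replace=False
        )
        outlier_set = {samples[i] for i in sorted(picks)}
        truth.outliers = [(samples[i], markers[0]) for i in sorted(picks)]

    split_set: set[str] = set()
    first_half = spec.n_markers
    if spec.split_fraction > 0:
        k = max(1, math.ceil(spec.split_fraction * spec.n_samples))
        if k >= spec.n_samples:
            raise FixtureSpecError("split_fraction selects every sample")
        picks = _stream(spec.seed, "split").choice(
            spec.n_samples, size=k, replace=False
        )
        split_set = {samples[i] for i in sorted(picks)}
        first_half = math.ceil(spec.n_markers / 2)
        truth.components = [
            set(samples),
            {f"{s}_2" for s in split_set},
        ]

    blocks = []
    for j, marker in enumerate(markers):
        length = spec.marker_lengths[j]
        ancestral = _random_sequence(_stream(spec.seed, "anc", marker), length)
        records = []
        if j < first_half:
            present = samples
            rename = False
        else:
            present = [s for s in samples if s in split_set]
            rename = True
        for sample in present:
            rng = _stream(spec.seed, "cell", marker, sample)
            is_outlier_cell = j == 0 and sample in outlier_set
            if (
                spec.missing_fraction > 0
                and not is_outlier_cell
                and rng.random() < spec.missing_fraction
            ):
                truth.absent_cells.add((sample, marker))
                continue
            if is_outlier_cell:
                seq = _random_sequence(rng, length)
            else:
                seq = _mutate(rng, ancestral, spec.divergence)
            name = f"{sample}_2" if rename else sample
            records.append(
                SequenceRecord(name, seq.tobytes().decode("ascii"))
            )
        if not records:
            # never emit an empty marker: keep the first candidate sample
            sample = present[0]
            truth.absent_cells.discard((sample, marker))
            rng = _stream(spec.seed, "cell", marker, sample, "kept")
            seq = _mutate(rng, ancestral, spec.divergence)
            name = f"{sample}_2" if rename else sample
            records.append(SequenceRecord(name, seq.tobytes().decode("ascii")))
        blocks.append(MarkerBlock(marker, records))
    return DataMatrix(blocks), truth
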