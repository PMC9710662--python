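import numpy as np
import pytest

from concatkit.datamodel import DataMatrix, MarkerBlock, SequenceRecord
from concatkit.fixtures import FixtureSpec, generate_matrix


def block(name: str, **seqs: str) -> MarkerBlock:
    return MarkerBlock(name, [SequenceRecord(s, r) for s, r in seqs.items()])


@pytest.fixture
def two_marker_matrix() -> DataMatrix:
    """The canonical worked example: M1 (len 5: A,B) and M2 (len 3: B,C)."""
    return DataMatrix(
        [
            block("M1", A="ACGTA", B="AC-TA"),
            block("M2", B="GGT", C="GCT"),
        ]
    )


def random_fixture(seed: int, **overrides) -> DataMatrix:
    """A small seeded matrix with shape drawn from the seed."""
    rng = np.random.default_rng(seed)
    params = dict(
        n_samples=int(rng.integers(2, 9)),
        n_markers=int(rng.integers(1, 5)),
        missing_fraction=float(rng.uniform(0, 0.5)),
        divergence=float(rng.uniform(0, 0.2)),
        seed=seed,
    )
    params["marker_lengths"] = [
        int(rng.integers(5, 41)) for _ in range(params["n_markers"])
    ]
    params.update(overrides)
    matrix, _ = generate_matrix(FixtureSpec(**params))
    return matrix


def assert_same_markers(a: DataMatrix, b: DataMatrix) -> None:
    """Equality on names, residues and marker boundaries (not metadata)."""
    assert a.marker_names == b.marker_names
    for ba, bb in zip(a.markers, b.markers):
        assert ba == bb
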