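from __future__ import annotations

import numpy as np
import pytest

from kmergeo import ReadSet
from kmergeo.dissimilarity import DissimilarityMatrix


def make_reads(seed: int, n_reads: int = 20, read_length: int = 50) -> ReadSet:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads = [
        bases[rng.integers(0, 4, size=read_length)].tobytes().decode()
        for _ in range(n_reads)
    ]
    return ReadSet(sample_id=f"rand{seed}", reads=reads)


def separated_matrix(
    n_per_group: int = 4,
    groups: tuple[str, ...] = ("NA", "EU", "AS"),
    intra: float = 0.1,
    inter: float = 0.9,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[DissimilarityMatrix, dict[str, str]]:
    """Toy matrix where every between-group entry exceeds every within-group one."""
    ids = [f"{g}{i}" for g in groups for i in range(n_per_group)]
    labels = {f"{g}{i}": g for g in groups for i in range(n_per_group)}
    n = len(ids)
    rng = np.random.default_rng(seed)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = intra if labels[ids[i]] == labels[ids[j]] else inter
            v = base + (jitter * rng.uniform(-1, 1) if jitter else 0.0)
            values[i, j] = values[j, i] = v
    return DissimilarityMatrix(sample_ids=ids, values=values, measure="toy"), labels


@pytest.fixture
def toy_matrix():
    return separated_matrix()
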