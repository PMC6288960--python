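"""Six alignment-free distance / dissimilarity measures and pairwise matrices.

Three traditional measures compare raw k-mer frequency vectors (Manhattan,
Euclidean, and the cosine-type d2), and three background-adjusted measures
first remove each sample's expected word composition under a Markov null
model before correlating: d2* and d2s center counts with a fitted m-th order
model, CVTree with a (k−1)/(k−2)-mer plug-in expectation (structurally an
order k−2 null). The normalized measures live in [0, 1]: 0 for identical
profiles, 1 for perfectly anti-correlated centered profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kmer_profile import (
    KmerProfile,
    MarkovModel,
    centered_counts,
    count_kmers,
    fit_markov,
)
from .sequence_io import FormatError, ReadSet

__all__ = [
    "MEASURES",
    "UndefinedMeasureError",
    "DissimilarityMatrix",
    "SampleKmerData",
    "build_sample_data",
    "manhattan",
    "euclid",
    "d2",
    "d2star",
    "d2s",
    "cvtree",
    "dissimilarity",
    "pairwise_matrix",
    "cross_distances",
    "write_matrix",
    "read_matrix",
]

MEASURES = ("manhattan", "euclid", "d2", "cvtree", "d2star", "d2s")

#: Measures that require a fitted Markov background model.
MODEL_MEASURES = ("d2star", "d2s")


class UndefinedMeasureError(ValueError):
    """The measure is undefined for these inputs (empty profile, zero norms)."""


def _check_pair(x: KmerProfile, y: KmerProfile) -> None:
    if x.k != y.k:
        raise ValueError(f"word lengths differ: {x.k} vs {y.k}")
    if x.N == 0 or y.N == 0:
        raise UndefinedMeasureError("empty k-mer profile")


def manhattan(x: KmerProfile, y: KmerProfile) -> float:
    """L1 distance between relative frequency vectors; range [0, 2]."""
    _check_pair(x, y)
    return float(np.abs(x.frequencies - y.frequencies).sum())


def euclid(x: KmerProfile, y: KmerProfile) -> float:
    """L2 distance between relative frequency vectors; range [0, sqrt(2)]."""
    _check_pair(x, y)
    diff = x.frequencies - y.frequencies
    return float(math.sqrt(np.dot(diff, diff)))


def d2(x: KmerProfile, y: KmerProfile) -> float:
    """Cosine-type dissimilarity ``(1 − cos(X, Y)) / 2`` of raw count vectors."""
    _check_pair(x, y)
    xf = x.counts.astype(float)
    yf = y.counts.astype(float)
    nx = math.sqrt(np.dot(xf, xf))
    ny = math.sqrt(np.dot(yf, yf))
    if nx == 0 or ny == 0:
        raise UndefinedMeasureError("zero-norm profile in d2")
    return float(np.clip(0.5 * (1.0 - np.dot(xf, yf) / (nx * ny)), 0.0, 1.0))


def d2star(x: KmerProfile, mx: MarkovModel, y: KmerProfile, my: MarkovModel) -> float:
    """Background-standardised correlation dissimilarity.

    Counts are centered by their Markov-null expectation and standardised by
    ``sqrt(N p_w)``; the statistic is one minus the resulting correlation,
    halved. Words with zero null probability in either sample are excluded
    from the cross term and from both self-normalizers.
    """
    _check_pair(x, y)
    from .kmer_profile import word_probabilities

    px = word_probabilities(mx, x.k)
    py = word_probabilities(my, y.k)
    mask = (px > 0) & (py > 0)
    if not mask.any():
        raise UndefinedMeasureError("no word has positive null probability in both samples")
    xc = x.counts[mask] - x.N * px[mask]
    yc = y.counts[mask] - y.N * py[mask]
    wx = x.N * px[mask]
    wy = y.N * py[mask]
    cross = float(np.sum(xc * yc / np.sqrt(wx * wy)))
    norm_x = math.sqrt(float(np.sum(xc * xc / wx)))
    norm_y = math.sqrt(float(np.sum(yc * yc / wy)))
    if norm_x == 0 or norm_y == 0:
        raise UndefinedMeasureError("zero d2star normalizer")
    return float(np.clip(0.5 * (1.0 - cross / (norm_x * norm_y)), 0.0, 1.0))


def d2s(x: KmerProfile, mx: MarkovModel, y: KmerProfile, my: MarkovModel) -> float:
    """Self-standardised variant of d2star.

    Each word's term is scaled by ``sqrt(X̃_w² + Ỹ_w²)``; words whose
    centered counts are both zero are skipped.
    """
    _check_pair(x, y)
    xc = centered_counts(x, mx)
    yc = centered_counts(y, my)
    r = np.sqrt(xc * xc + yc * yc)
    mask = r > 0
    if not mask.any():
        raise UndefinedMeasureError("all centered counts are zero in d2s")
    xc, yc, r = xc[mask], yc[mask], r[mask]
    cross = float(np.sum(xc * yc / r))
    norm_x = math.sqrt(float(np.sum(xc * xc / r)))
    norm_y = math.sqrt(float(np.sum(yc * yc / r)))
    if norm_x == 0 or norm_y == 0:
        raise UndefinedMeasureError("zero d2s normalizer")
    return float(np.clip(0.5 * (1.0 - cross / (norm_x * norm_y)), 0.0, 1.0))


@lru_cache(maxsize=None)
def _cvtree_indices(k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(prefix, suffix, middle) sub-word indices for every k-mer index."""
    idx = np.arange(4**k, dtype=np.int64)
    prefix = idx >> 2
    suffix = idx & (4 ** (k - 1) - 1)
    middle = prefix & (4 ** (k - 2) - 1)
    return prefix, suffix, middle


def _composition_vector(x: KmerProfile, x1: KmerProfile, x2: KmerProfile) -> np.ndarray:
    """Relative deviation of counts from the (k−1)/(k−2)-mer plug-in expectation."""
    if not (x.k - 1 == x1.k and x.k - 2 == x2.k):
        raise ValueError("cvtree needs profiles of word lengths k, k-1, k-2")
    if x.k < 2:
        raise ValueError("cvtree requires k >= 2")
    prefix, suffix, middle = _cvtree_indices(x.k)
    denom = x2.counts[middle].astype(float)
    expected = np.divide(
        x1.counts[prefix].astype(float) * x1.counts[suffix],
        denom,
        out=np.zeros(4**x.k),
        where=denom > 0,
    )
    return np.divide(
        x.counts - expected, expected, out=np.zeros(4**x.k), where=expected > 0
    )


def cvtree(
    x: KmerProfile,
    x1: KmerProfile,
    x2: KmerProfile,
    y: KmerProfile,
    y1: KmerProfile,
    y2: KmerProfile,
) -> float:
    """Composition-vector dissimilarity ``(1 − cos(a, b)) / 2``.

    ``a_w = (X_w − E_w)/E_w`` with ``E_w = X(w_1..w_{k−1}) X(w_2..w_k) /
    X(w_2..w_{k−1})`` (0 whenever the denominator or expectation vanishes).
    """
    a = _composition_vector(x, x1, x2)
    b = _composition_vector(y, y1, y2)
    na = math.sqrt(float(np.dot(a, a)))
    nb = math.sqrt(float(np.dot(b, b)))
    if na == 0 or nb == 0:
        raise UndefinedMeasureError("zero composition vector in cvtree")
    return float(np.clip(0.5 * (1.0 - np.dot(a, b) / (na * nb)), 0.0, 1.0))


@dataclass
class SampleKmerData:
    """Everything one sample contributes to any of the six measures.

    ``profile`` is the k-mer profile; ``model`` the fitted background model
    (d2*, d2s); ``sub1``/``sub2`` the (k−1)- and (k−2)-mer profiles (CVTree).
    """

    sample_id: str
    profile: KmerProfile
    model: MarkovModel | None = None
    sub1: KmerProfile | None = None
    sub2: KmerProfile | None = None


def build_sample_data(
    rs: ReadSet,
    k: int,
    m: int | None = None,
    measure: str = "d2star",
    strand: str = "both",
) -> SampleKmerData:
    """Count profiles and fit models as required by ``measure``."""
    profile = count_kmers(rs, k, strand)
    model = sub1 = sub2 = None
    if measure in MODEL_MEASURES:
        if m is None:
            raise ValueError(f"{measure} requires a Markov order m")
        model = fit_markov(rs, m, strand)
    elif measure == "cvtree":
        sub1 = count_kmers(rs, k - 1, strand)
        sub2 = count_kmers(rs, k - 2, strand)
    return SampleKmerData(
        sample_id=rs.sample_id, profile=profile, model=model, sub1=sub1, sub2=sub2
    )


def dissimilarity(a: SampleKmerData, b: SampleKmerData, measure: str) -> float:
    """Dispatch one pairwise measure on prepared sample data."""
    if measure == "manhattan":
        return manhattan(a.profile, b.profile)
    if measure == "euclid":
        return euclid(a.profile, b.profile)
    if measure == "d2":
        return d2(a.profile, b.profile)
    if measure == "d2star":
        return d2star(a.profile, a.model, b.profile, b.model)
    if measure == "d2s":
        return d2s(a.profile, a.model, b.profile, b.model)
    if measure == "cvtree":
        return cvtree(a.profile, a.sub1, a.sub2, b.profile, b.sub1, b.sub2)
    raise ValueError(f"unknown measure {measure!r}")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    sample_ids: list[str]
    values: np.ndarray
    measure: str = ""
    k: int | None = None
    m: int | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match the number of sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("matrix diagonal is not zero")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.values[self._index[i], self._index[j]])

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self._index[sample_id]]

    def index(self, sample_id: str) -> int:
        return self._index[sample_id]

    def submatrix(self, ids: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self._index[s] for s in ids]
        return DissimilarityMatrix(
            sample_ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            measure=self.measure,
            k=self.k,
            m=self.m,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def pairwise_matrix(
    samples: Sequence[SampleKmerData], measure: str
) -> DissimilarityMatrix:
    """Assemble the symmetric pairwise matrix for one measure.

    Entries are pure functions of the per-sample data, so the result is
    independent of evaluation order.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    n = len(samples)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dissimilarity(samples[i], samples[j], measure)
    k = samples[0].profile.k
    m = samples[0].model.m if samples[0].model is not None else None
    return DissimilarityMatrix(sample_ids=ids, values=values, measure=measure, k=k, m=m)


def cross_distances(
    query: SampleKmerData, references: Sequence[SampleKmerData], measure: str
) -> np.ndarray:
    """Dissimilarity of one query to each reference sample."""
    return np.array([dissimilarity(query, ref, measure) for ref in references])


def write_matrix(dm: DissimilarityMatrix, path: str | Path, format: str = "phylip") -> Path:
    """Write a matrix as PHYLIP square (n, then label + n values/row) or labeled TSV."""
    path = Path(path)
    if format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(dm)}\n")
            for sid, row in zip(dm.sample_ids, dm.values):
                fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif format == "tsv":
        dm.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")
    else:
        raise FormatError(f"unknown matrix format {format!r}")
    return path


def read_matrix(path: str | Path, format: str = "auto", **meta) -> DissimilarityMatrix:
    """Read a PHYLIP square or labeled TSV matrix written by :func:`write_matrix`."""
    path = Path(path)
    if format == "auto":
        format = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "phylip"
    if format == "phylip":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 1 or not header[0].isdigit():
                raise FormatError(f"{path}: malformed PHYLIP header")
            n = int(header[0])
            ids: list[str] = []
            rows: list[list[float]] = []
            for line in fh:
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != n + 1:
                    raise FormatError(
                        f"{path}: row {parts[0] if parts else '?'} has "
                        f"{len(parts) - 1} values, expected {n}"
                    )
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        if len(ids) != n:
            raise FormatError(f"{path}: expected {n} rows, found {len(ids)}")
        values = np.array(rows)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise FormatError(f"{path}: row and column labels differ")
        ids = [str(s) for s in df.index]
        values = df.to_numpy(dtype=float)
    else:
        raise FormatError(f"unknown matrix format {format!r}")
    try:
        return DissimilarityMatrix(sample_ids=ids, values=values, **meta)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
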