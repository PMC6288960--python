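"""k-mer counting and Markov background models for read sets.

Word counts ``X_w`` over the full ``4^k`` alphabet are the raw material of
every dissimilarity measure; the background-adjusted measures additionally
need an m-th order Markov model of each sample's composition, from which the
null word probabilities ``p_w`` and the centered counts
``X̃_w = X_w − N p_w`` are derived.

Profiles and models are stored as dense numpy vectors indexed by the
2-bit encoding A=0, C=1, G=2, T=3 (most significant digit first); at the
k ≤ 12 word lengths used for shotgun provenance this is compact and fast.
k-mers never span read boundaries, and windows containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import numpy as np

from .sequence_io import ReadSet

__all__ = [
    "KmerProfile",
    "MarkovModel",
    "count_kmers",
    "fit_markov",
    "word_probability",
    "word_probabilities",
    "centered_counts",
    "encode_kmer",
    "decode_kmer",
    "default_k_m",
]

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def default_k_m(k: int | None = None, m: int | None = None) -> tuple[int, int]:
    """Resolve the word length / Markov order pair.

    Background-adjusted measures perform well when ``k = m + 2``; when only
    one of the two is given the other is filled in by that rule. The full
    default is k=12, m=10 (genome-scale shotgun data).
    """
    if k is None and m is None:
        return 12, 10
    if k is None:
        return m + 2, m
    if m is None:
        return k, max(k - 2, 0)
    return k, m


def encode_kmer(word: str) -> int:
    """Integer index of a DNA word (A=0,C=1,G=2,T=3, first base most significant)."""
    idx = 0
    for ch in word:
        code = _CODE[ord(ch)]
        if code < 0:
            raise ValueError(f"invalid base {ch!r} in {word!r}")
        idx = (idx << 2) | int(code)
    return idx


def decode_kmer(idx: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_BASES[(idx >> shift) & 3])
    return "".join(out)


@lru_cache(maxsize=None)
def _revcomp_index(k: int) -> np.ndarray:
    """Permutation sending each k-mer index to its reverse complement's index."""
    idx = np.arange(4**k, dtype=np.int64)
    out = np.zeros_like(idx)
    tmp = idx.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return out


def _encode_reads(reads: Iterable[str]) -> np.ndarray:
    """Concatenate reads into one code array with a -1 sentinel between reads.

    The sentinel makes every window that would span a read boundary invalid,
    exactly like a window containing N.
    """
    chunks: list[np.ndarray] = []
    sep = np.array([-1], dtype=np.int64)
    for read in reads:
        chunks.append(_CODE[np.frombuffer(read.encode(), dtype=np.uint8)])
        chunks.append(sep)
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chunks[:-1])


def _window_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Dense counts of valid k-windows (no N, no read-boundary crossing)."""
    counts = np.zeros(4**k, dtype=np.int64)
    if codes.size < k:
        return counts
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return counts
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = windows[valid] @ powers
    np.add.at(counts, idx, 1)
    return counts


@dataclass
class KmerProfile:
    """Occurrence counts of every k-word in one sample's reads.

    ``counts[w]`` is the number of occurrences ``X_w`` of word index ``w``;
    ``N`` is the total occurrence count ``Σ_w X_w``; relative frequencies are
    ``f_w = X_w / N``.
    """

    k: int
    counts: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.counts.shape != (4**self.k,):
            raise ValueError(f"counts must have length 4^{self.k}")
        if (self.counts < 0).any():
            raise ValueError("negative k-mer count")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        n = self.N
        if n == 0:
            raise ValueError(f"profile {self.sample_id!r} is empty")
        return self.counts / n

    def to_dict(self) -> dict[str, int]:
        """Sparse word -> count map of the observed words."""
        nz = np.nonzero(self.counts)[0]
        return {decode_kmer(int(w), self.k): int(self.counts[w]) for w in nz}

    def write_tsv(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            fh.write("word\tcount\n")
            for word, count in self.to_dict().items():
                fh.write(f"{word}\t{count}\n")
        return Path(path)


@dataclass
class MarkovModel:
    """m-th order Markov background model fitted to one sample's reads.

    ``transition[u, a]`` is ``P(a | u)`` for context index ``u`` (rows of
    unobserved contexts are all-zero) and ``initial[u]`` is the stationary
    m-word probability ``q(u)`` estimated from m-mer counts. For ``m = 0``
    there is a single empty context with ``q ≡ 1``.
    """

    m: int
    transition: np.ndarray
    initial: np.ndarray
    context_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        n_ctx = 4**self.m
        if self.transition.shape != (n_ctx, 4):
            raise ValueError(f"transition must be (4^{self.m}, 4)")
        if self.initial.shape != (n_ctx,):
            raise ValueError(f"initial must have length 4^{self.m}")
        if self.context_counts is None:
            self.context_counts = np.zeros(n_ctx, dtype=np.int64)
        rowsums = self.transition.sum(axis=1)
        observed = rowsums > 0
        if observed.any() and not np.allclose(rowsums[observed], 1.0, atol=1e-12):
            raise ValueError("observed transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > 1e-12:
            raise ValueError("initial probabilities must sum to 1")

    def write_tsv(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            fh.write("context\tbase\tprobability\tinitial\n")
            for u in range(4**self.m):
                ctx = decode_kmer(u, self.m) if self.m else "-"
                for a in range(4):
                    fh.write(
                        f"{ctx}\t{_BASES[a]}\t{self.transition[u, a]!r}\t{self.initial[u]!r}\n"
                    )
        return Path(path)


def count_kmers(rs: ReadSet, k: int, strand: str = "both") -> KmerProfile:
    """Count all k-words within reads.

    Windows are taken inside reads only; any window containing N is skipped.
    With ``strand="both"`` the counts of every read's reverse complement are
    added, making the profile invariant to the sequencing strand.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if strand not in ("forward", "both"):
        raise ValueError(f"unknown strand policy {strand!r}")
    codes = _encode_reads(rs.reads)
    counts = _window_counts(codes, k)
    if strand == "both":
        counts = counts + counts[_revcomp_index(k)]
    return KmerProfile(k=k, counts=counts, sample_id=rs.sample_id)


def fit_markov(rs: ReadSet, m: int, strand: str = "both") -> MarkovModel:
    """Fit the m-th order background model from within-read window counts.

    Transitions come from (m+1)-mer counts, ``P(a|u) = C(ua) / Σ_b C(ub)``;
    initial probabilities from m-mer counts, ``q(u) = C_m(u) / Σ_v C_m(v)``.
    ``m = 0`` yields single-nucleotide frequencies with ``q ≡ 1`` for the
    empty context. Strand handling matches :func:`count_kmers`.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    codes = _encode_reads(rs.reads)
    c_next = _window_counts(codes, m + 1)
    if strand == "both":
        c_next = c_next + c_next[_revcomp_index(m + 1)]
    elif strand != "forward":
        raise ValueError(f"unknown strand policy {strand!r}")
    if c_next.sum() == 0:
        raise ValueError(
            f"sample {rs.sample_id}: no read provides an (m+1)={m + 1} base window"
        )
    table = c_next.reshape(4**m, 4).astype(float)
    rowsums = table.sum(axis=1, keepdims=True)
    transition = np.divide(table, rowsums, out=np.zeros_like(table), where=rowsums > 0)

    if m == 0:
        initial = np.ones(1)
        ctx_counts = np.array([int(c_next.sum())], dtype=np.int64)
    else:
        c_m = _window_counts(codes, m)
        if strand == "both":
            c_m = c_m + c_m[_revcomp_index(m)]
        ctx_counts = c_m
        initial = c_m / c_m.sum()
    return MarkovModel(
        m=m,
        transition=transition,
        initial=initial,
        context_counts=ctx_counts,
        sample_id=rs.sample_id,
    )


def word_probability(mm: MarkovModel, word: str) -> float:
    """Null probability of one word under the background model (chain rule).

    ``p_w = q(w_1..w_m) · Π_{i>m} P(w_i | w_{i-m}..w_{i-1})``; a context or
    transition never observed in the data contributes probability 0.
    """
    if len(word) < mm.m:
        raise ValueError(f"word {word!r} shorter than model order {mm.m}")
    codes = [int(_CODE[ord(c)]) for c in word]
    if any(c < 0 for c in codes):
        raise ValueError(f"invalid base in {word!r}")
    ctx = 0
    for c in codes[: mm.m]:
        ctx = (ctx << 2) | c
    p = float(mm.initial[ctx])
    mask = 4**mm.m - 1
    for c in codes[mm.m :]:
        p *= float(mm.transition[ctx, c])
        if p == 0.0:
            return 0.0
        ctx = ((ctx << 2) | c) & mask
    return p


def word_probabilities(mm: MarkovModel, k: int) -> np.ndarray:
    """Null probabilities of all ``4^k`` words, vectorised.

    Dynamic programming over word length: the length-t probability vector is
    extended one base at a time using the transition row of each word's
    trailing m bases.
    """
    if k < mm.m:
        raise ValueError(f"k={k} shorter than model order m={mm.m}")
    p = mm.initial.copy()
    mask = 4**mm.m - 1
    for _ in range(k - mm.m):
        n = p.size
        ctx = np.arange(n, dtype=np.int64) & mask
        p = (p[:, None] * mm.transition[ctx]).reshape(4 * n)
    return p


def centered_counts(kp: KmerProfile, mm: MarkovModel) -> np.ndarray:
    """Background-centered counts ``X̃_w = X_w − N p_w`` over all 4^k words."""
    if mm.m > kp.k:
        raise ValueError(f"model order {mm.m} exceeds word length {kp.k}")
    return kp.counts - kp.N * word_probabilities(mm, kp.k)
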