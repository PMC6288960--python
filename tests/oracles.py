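"""Independent brute-force reference implementations used as test oracles.

Everything here works on plain Python dicts and strings, loops explicitly
over all 4^k words of the alphabet, and computes word probabilities by
chain-rule products — deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def all_words(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def count_kmers_dict(reads: list[str], k: int, strand: str = "both") -> dict[str, int]:
    """Word counts by explicit string slicing; windows with N skipped."""
    pool = list(reads)
    if strand == "both":
        pool += [revcomp(r) for r in reads]
    counts: dict[str, int] = {}
    for read in pool:
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            if "N" not in w:
                counts[w] = counts.get(w, 0) + 1
    return counts


def markov_dicts(
    reads: list[str], m: int, strand: str = "both"
) -> tuple[dict[str, float], dict[str, float]]:
    """(initial q, transition P) of the m-th order background model.

    q maps m-words to probabilities; P maps (m+1)-words u+a to P(a|u).
    """
    c_next = count_kmers_dict(reads, m + 1, strand)
    transition: dict[str, float] = {}
    for u in all_words(m):
        row_total = sum(c_next.get(u + a, 0) for a in BASES)
        if row_total:
            for a in BASES:
                transition[u + a] = c_next.get(u + a, 0) / row_total
    if m == 0:
        initial = {"": 1.0}
    else:
        c_m = count_kmers_dict(reads, m, strand)
        total = sum(c_m.values())
        initial = {u: c_m.get(u, 0) / total for u in all_words(m)}
    return initial, transition


def word_prob(initial: dict[str, float], transition: dict[str, float], m: int, w: str) -> float:
    p = initial.get(w[:m], 0.0)
    for i in range(m, len(w)):
        p *= transition.get(w[i - m : i + 1], 0.0)
    return p


def _freq(counts: dict[str, int]) -> tuple[dict[str, float], int]:
    n = sum(counts.values())
    return {w: c / n for w, c in counts.items()}, n


def manhattan_bf(cx: dict[str, int], cy: dict[str, int], k: int) -> float:
    fx, _ = _freq(cx)
    fy, _ = _freq(cy)
    return sum(abs(fx.get(w, 0.0) - fy.get(w, 0.0)) for w in all_words(k))


def euclid_bf(cx: dict[str, int], cy: dict[str, int], k: int) -> float:
    fx, _ = _freq(cx)
    fy, _ = _freq(cy)
    return math.sqrt(sum((fx.get(w, 0.0) - fy.get(w, 0.0)) ** 2 for w in all_words(k)))


def d2_bf(cx: dict[str, int], cy: dict[str, int], k: int) -> float:
    dot = sum(cx.get(w, 0) * cy.get(w, 0) for w in all_words(k))
    nx = math.sqrt(sum(v * v for v in cx.values()))
    ny = math.sqrt(sum(v * v for v in cy.values()))
    return 0.5 * (1.0 - dot / (nx * ny))


def d2star_bf(
    reads_x: list[str], reads_y: list[str], k: int, m: int, strand: str = "both"
) -> float:
    cx = count_kmers_dict(reads_x, k, strand)
    cy = count_kmers_dict(reads_y, k, strand)
    nx, ny = sum(cx.values()), sum(cy.values())
    qx, px_t = markov_dicts(reads_x, m, strand)
    qy, py_t = markov_dicts(reads_y, m, strand)
    cross = sum_x = sum_y = 0.0
    for w in all_words(k):
        px = word_prob(qx, px_t, m, w)
        py = word_prob(qy, py_t, m, w)
        if px <= 0.0 or py <= 0.0:
            continue
        xt = cx.get(w, 0) - nx * px
        yt = cy.get(w, 0) - ny * py
        cross += xt * yt / math.sqrt(nx * px * ny * py)
        sum_x += xt * xt / (nx * px)
        sum_y += yt * yt / (ny * py)
    return 0.5 * (1.0 - cross / (math.sqrt(sum_x) * math.sqrt(sum_y)))


def d2s_bf(
    reads_x: list[str], reads_y: list[str], k: int, m: int, strand: str = "both"
) -> float:
    cx = count_kmers_dict(reads_x, k, strand)
    cy = count_kmers_dict(reads_y, k, strand)
    nx, ny = sum(cx.values()), sum(cy.values())
    qx, px_t = markov_dicts(reads_x, m, strand)
    qy, py_t = markov_dicts(reads_y, m, strand)
    cross = sum_x = sum_y = 0.0
    for w in all_words(k):
        xt = cx.get(w, 0) - nx * word_prob(qx, px_t, m, w)
        yt = cy.get(w, 0) - ny * word_prob(qy, py_t, m, w)
        r = math.sqrt(xt * xt + yt * yt)
        if r == 0.0:
            continue
        cross += xt * yt / r
        sum_x += xt * xt / r
        sum_y += yt * yt / r
    return 0.5 * (1.0 - cross / (math.sqrt(sum_x) * math.sqrt(sum_y)))


def cvtree_bf(reads_x: list[str], reads_y: list[str], k: int, strand: str = "both") -> float:
    def comp_vector(reads: list[str]) -> dict[str, float]:
        ck = count_kmers_dict(reads, k, strand)
        c1 = count_kmers_dict(reads, k - 1, strand)
        c2 = count_kmers_dict(reads, k - 2, strand)
        vec: dict[str, float] = {}
        for w in all_words(k):
            mid = c2.get(w[1:-1], 0)
            expected = c1.get(w[:-1], 0) * c1.get(w[1:], 0) / mid if mid else 0.0
            vec[w] = (ck.get(w, 0) - expected) / expected if expected > 0 else 0.0
        return vec

    a, b = comp_vector(reads_x), comp_vector(reads_y)
    dot = sum(a[w] * b[w] for w in a)
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    return 0.5 * (1.0 - dot / (na * nb))


def wmw_u_bf(intra: list[float], inter: list[float]) -> float:
    """Naive double-loop Mann–Whitney U (inter exceeding intra; ties half)."""
    u = 0.0
    for b in inter:
        for a in intra:
            if b > a:
                u += 1.0
            elif b == a:
                u += 0.5
    return u


def random_reads(rng, n_reads: int, read_length: int) -> list[str]:
    return [
        "".join(rng.choice(list(BASES)) for _ in range(read_length)) for _ in range(n_reads)
    ]
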