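"""Statistics linking k-mer dissimilarity to geography.

Covers the permutation Wilcoxon–Mann–Whitney test of intra- versus
inter-continental dissimilarities, classical principal coordinate analysis
(PCoA) of a dissimilarity matrix, great-circle distances, and the
correlation between pairwise dissimilarity and geographic distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import pearsonr, rankdata, spearmanr

from .dissimilarity import DissimilarityMatrix
from .sequence_io import SampleMeta

__all__ = [
    "EARTH_RADIUS_KM",
    "PermutationTestResult",
    "PCoAResult",
    "GeoCorrelation",
    "wmw_statistic",
    "permutation_test",
    "pcoa",
    "great_circle",
    "geo_correlation",
]

#: IUGG mean Earth radius, kilometres.
EARTH_RADIUS_KM = 6371.0088


def wmw_statistic(intra: Sequence[float], inter: Sequence[float]) -> float:
    """Mann–Whitney U counting pairs where an inter value exceeds an intra value.

    ``U = Σ 1[inter > intra] + ½ Σ 1[inter = intra]`` over all cross pairs,
    computed via rank sums so that permutation loops stay cheap.
    """
    intra = np.asarray(intra, dtype=float)
    inter = np.asarray(inter, dtype=float)
    if intra.size == 0 or inter.size == 0:
        raise ValueError("both intra and inter lists must be non-empty")
    ranks = rankdata(np.concatenate([inter, intra]))
    r_inter = ranks[: inter.size].sum()
    return float(r_inter - inter.size * (inter.size + 1) / 2.0)


def _pair_partition(
    labels: np.ndarray, group: str, iu: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (intra, inter) over the upper-triangle pairs for one group.

    For a single continent ``c``: intra pairs are within ``c`` and inter
    pairs oppose ``c`` to any other continent. For ``ALL`` the three
    per-continent partitions are pooled, so each between-continent pair
    contributes to the inter side of both continents it touches (weight 2).
    """
    li, lj = labels[iu[0]], labels[iu[1]]
    if group != "ALL":
        intra = (li == group) & (lj == group)
        inter = ((li == group) | (lj == group)) & (li != lj)
        return intra, inter
    intra = li == lj
    inter = li != lj
    return intra, inter


def _group_statistic(
    values: np.ndarray, labels: np.ndarray, group: str, iu
) -> float:
    if group == "ALL":
        # pooled per-continent partitions: between pairs enter twice
        total = 0.0
        for c in np.unique(labels):
            intra, inter = _pair_partition(labels, str(c), iu)
            if intra.any() and inter.any():
                total += wmw_statistic(values[intra], values[inter])
        return total
    intra, inter = _pair_partition(labels, group, iu)
    if not intra.any() or not inter.any():
        raise ValueError(f"degenerate grouping for {group!r}: empty intra or inter set")
    return wmw_statistic(values[intra], values[inter])


@dataclass
class PermutationTestResult:
    group: str
    W_observed: float
    p_value: float
    B: int
    seed: int
    n_intra: int = 0
    n_inter: int = 0


def permutation_test(
    dm: DissimilarityMatrix,
    labels: Mapping[str, str],
    group: str = "ALL",
    B: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Label-permutation WMW test that inter-continental dissimilarities
    exceed intra-continental ones.

    Continent labels are permuted jointly across samples (matrix untouched),
    preserving the dependence structure of pairwise entries; the p-value is
    the add-one estimator ``(1 + #{U_perm ≥ U_obs}) / (B + 1)``, never
    smaller than ``1/(B+1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ids = [s for s in dm.sample_ids if s in labels]
    if group != "ALL":
        counts = sum(labels[s] == group for s in ids)
        if counts < 2 or len(ids) - counts < 1:
            raise ValueError(f"degenerate grouping: group {group!r} has too few samples")
    idx = [dm.index(s) for s in ids]
    sub = dm.values[np.ix_(idx, idx)]
    lab = np.array([labels[s] for s in ids])
    iu = np.triu_indices(len(ids), k=1)
    values = sub[iu]
    u_obs = _group_statistic(values, lab, group, iu)
    intra, inter = _pair_partition(lab, group, iu)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(lab)
        if u_obs <= _group_statistic(values, perm, group, iu):
            count += 1
    return PermutationTestResult(
        group=group,
        W_observed=u_obs,
        p_value=(1 + count) / (B + 1),
        B=B,
        seed=seed,
        n_intra=int(intra.sum()),
        n_inter=int(inter.sum()),
    )


@dataclass
class PCoAResult:
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    n_negative: int = 0
    negative_mass: float = 0.0

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"coord{i + 1}": self.coordinates[:, i] for i in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


def pcoa(dm: DissimilarityMatrix, r: int | None = None) -> PCoAResult:
    """Classical multidimensional scaling of a dissimilarity matrix.

    Gower double-centering ``B = −½ J (D∘D) J`` with ``J = I − 11ᵀ/n``,
    followed by eigendecomposition; coordinates are eigenvectors scaled by
    ``sqrt(λ)`` for positive eigenvalues, sorted descending. Negative
    eigenvalues (non-Euclidean input) are dropped, not corrected, and
    reported; variance fractions are over positive eigenvalues only.
    """
    d = dm.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # clamp numerically-zero eigenvalues so they neither count as positive axes
    # nor inflate the reported negative mass
    tiny = np.abs(eigvals).max() * 1e-12 if n else 0.0
    positive = eigvals > tiny
    negative = eigvals < -tiny
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    if r is not None:
        coords = coords[:, :r]
    return PCoAResult(
        coordinates=coords,
        eigenvalues=pos_vals,
        variance_explained=pos_vals / pos_vals.sum() if pos_vals.size else pos_vals,
        sample_ids=list(dm.sample_ids),
        n_negative=int(negative.sum()),
        negative_mass=float(-eigvals[negative].sum()),
    )


def great_circle(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in kilometres (IUGG mean radius)."""
    for name, val, lim in (
        ("lat1", lat1, 90.0),
        ("lat2", lat2, 90.0),
        ("lon1", lon1, 180.0),
        ("lon2", lon2, 180.0),
    ):
        if val is None or not -lim <= val <= lim:
            raise ValueError(f"{name}={val} outside valid range")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


@dataclass
class GeoCorrelation:
    pearson_r: float
    r_squared: float
    spearman_rho: float
    n_pairs: int


def geo_correlation(dm: DissimilarityMatrix, metas: Sequence[SampleMeta]) -> GeoCorrelation:
    """Correlation between pairwise dissimilarity and great-circle distance.

    Pearson and Spearman coefficients over all n(n−1)/2 sample pairs. A
    degenerate input (constant dissimilarity or distance) yields NaN
    coefficients with a warning rather than an error.
    """
    coords = {m.sample_id: (m.latitude, m.longitude) for m in metas}
    missing = [
        s
        for s in dm.sample_ids
        if s not in coords or coords[s][0] is None or coords[s][1] is None
    ]
    if missing:
        raise ValueError(f"missing coordinates for samples: {missing}")
    diss: list[float] = []
    geo: list[float] = []
    ids = dm.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            diss.append(dm.values[i, j])
            geo.append(great_circle(*coords[ids[i]], *coords[ids[j]]))
    diss_arr, geo_arr = np.array(diss), np.array(geo)
    if np.ptp(diss_arr) == 0 or np.ptp(geo_arr) == 0:
        warnings.warn("constant dissimilarity or distance: correlation undefined", stacklevel=2)
        return GeoCorrelation(math.nan, math.nan, math.nan, len(diss))
    r = float(pearsonr(geo_arr, diss_arr).statistic)
    rho = float(spearmanr(geo_arr, diss_arr).statistic)
    return GeoCorrelation(pearson_r=r, r_squared=r * r, spearman_rho=rho, n_pairs=len(diss))
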