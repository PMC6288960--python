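import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from scipy.spatial.distance import pdist, squareform

from kmergeo import (
    SampleMeta,
    geo_correlation,
    great_circle,
    pcoa,
    permutation_test,
    wmw_statistic,
)
from kmergeo.dissimilarity import DissimilarityMatrix
from kmergeo.geostats import EARTH_RADIUS_KM, _group_statistic

from .conftest import separated_matrix
from .oracles import wmw_u_bf


class TestWmwStatistic:
    def test_all_concordant_pairs(self):
        assert wmw_statistic([1, 2], [3, 4]) == 4.0

    def test_single_tie_counts_half(self):
        assert wmw_statistic([1], [1]) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        intra = list(rng.integers(0, 10, size=12).astype(float))  # forces ties
        inter = list(rng.integers(0, 10, size=9).astype(float))
        assert wmw_statistic(intra, inter) == pytest.approx(wmw_u_bf(intra, inter))

    def test_matches_scipy_u(self):
        rng = np.random.default_rng(3)
        intra = rng.normal(size=20)
        inter = rng.normal(size=15)
        expected = mannwhitneyu(inter, intra, alternative="two-sided").statistic
        assert wmw_statistic(intra, inter) == pytest.approx(float(expected))

    @pytest.mark.parametrize("seed", range(5))
    def test_complementarity(self, seed):
        rng = np.random.default_rng(seed + 10)
        x = list(rng.integers(0, 6, size=8).astype(float))
        y = list(rng.integers(0, 6, size=11).astype(float))
        assert wmw_statistic(x, y) + wmw_statistic(y, x) == pytest.approx(len(x) * len(y))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wmw_statistic([], [1.0])


class TestPermutationTest:
    def test_minimal_p_on_separated_matrix(self):
        # groups of 8: a permutation reproducing a complete continent (the
        # only way to tie the maximal U) has probability ~4e-6
        dm, labels = separated_matrix(n_per_group=8)
        for group in ("NA", "EU", "AS"):
            res = permutation_test(dm, labels, group=group, B=999, seed=0)
            assert res.p_value == pytest.approx(1 / 1000)

    def test_all_group_pools_per_continent_partitions(self, toy_matrix):
        dm, labels = toy_matrix
        ids = dm.sample_ids
        lab = np.array([labels[s] for s in ids])
        iu = np.triu_indices(len(ids), 1)
        values = dm.values[iu]
        total = sum(
            _group_statistic(values, lab, g, iu) for g in ("NA", "EU", "AS")
        )
        assert _group_statistic(values, lab, "ALL", iu) == pytest.approx(total)

    def test_p_floor_cannot_decrease_with_smaller_b(self, toy_matrix):
        dm, labels = toy_matrix
        r1 = permutation_test(dm, labels, group="NA", B=99, seed=1)
        r2 = permutation_test(dm, labels, group="NA", B=999, seed=1)
        assert r1.p_value >= 1 / 100
        assert r2.p_value >= 1 / 1000
        assert r2.p_value <= r1.p_value

    def test_invariant_to_sample_relabeling(self, toy_matrix):
        dm, labels = toy_matrix
        renamed_ids = [f"s{i}" for i in range(len(dm))]
        renamed = DissimilarityMatrix(sample_ids=renamed_ids, values=dm.values)
        relabels = {f"s{i}": labels[s] for i, s in enumerate(dm.sample_ids)}
        a = permutation_test(dm, labels, group="EU", B=200, seed=9)
        b = permutation_test(renamed, relabels, group="EU", B=200, seed=9)
        assert a.W_observed == b.W_observed
        assert a.p_value == b.p_value

    def test_degenerate_grouping_rejected(self, toy_matrix):
        dm, labels = toy_matrix
        with pytest.raises(ValueError):
            permutation_test(dm, labels, group="AF", B=10, seed=0)


class TestPcoa:
    def test_two_points(self):
        dm = DissimilarityMatrix(sample_ids=["a", "b"], values=[[0, 2], [2, 0]])
        res = pcoa(dm)
        assert res.coordinates.shape == (2, 1)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_equilateral_triangle(self):
        d = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
        res = pcoa(DissimilarityMatrix(sample_ids=list("abc"), values=d))
        assert res.eigenvalues.size == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], abs=1e-12)
        coords = res.coordinates
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0)

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(10, 2))
        d = squareform(pdist(points))
        dm = DissimilarityMatrix(sample_ids=[f"p{i}" for i in range(10)], values=d)
        res = pcoa(dm)
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, d, atol=1e-9)
        assert res.n_negative == 0

    def test_matches_independent_pcoa(self):
        """Cross-check coordinates against scikit-bio's implementation."""
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix as SkbioDM

        dm, _ = separated_matrix(jitter=0.05, seed=1)
        ours = pcoa(dm)
        theirs = skbio_pcoa(SkbioDM(dm.values, ids=dm.sample_ids), method="eigh")
        n_pos = ours.eigenvalues.size
        ref = theirs.samples.to_numpy()[:, :n_pos]
        # embeddings agree up to per-axis sign
        for axis in range(min(3, n_pos)):
            ratio = ours.coordinates[:, axis] / ref[:, axis]
            assert np.allclose(np.abs(ratio), 1.0, atol=1e-6)

    def test_variance_fractions_sum_to_at_most_one(self):
        dm, _ = separated_matrix(jitter=0.1, seed=2)
        res = pcoa(dm)
        assert res.variance_explained.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)


class TestGreatCircle:
    def test_identical_points(self):
        assert great_circle(45.0, 30.0, 45.0, 30.0) == 0.0

    def test_quarter_meridian(self):
        assert great_circle(0, 0, 0, 90) == pytest.approx(math.pi * EARTH_RADIUS_KM / 2, abs=0.01)

    def test_symmetric(self):
        assert great_circle(10, 20, -30, 150) == great_circle(-30, 150, 10, 20)

    def test_invalid_coordinates(self):
        with pytest.raises(ValueError):
            great_circle(95, 0, 0, 0)
        with pytest.raises(ValueError):
            great_circle(0, None, 0, 0)


class TestGeoCorrelation:
    def _metas_square(self):
        return [
            SampleMeta("a", latitude=0.0, longitude=0.0),
            SampleMeta("b", latitude=0.0, longitude=10.0),
            SampleMeta("c", latitude=10.0, longitude=0.0),
            SampleMeta("d", latitude=10.0, longitude=10.0),
        ]

    def test_affine_relation_gives_r_one(self):
        metas = self._metas_square()
        ids = [m.sample_id for m in metas]
        geo = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                geo[i, j] = great_circle(
                    metas[i].latitude, metas[i].longitude, metas[j].latitude, metas[j].longitude
                )
        diss = 0.1 + 1e-5 * geo
        np.fill_diagonal(diss, 0.0)
        dm = DissimilarityMatrix(sample_ids=ids, values=diss)
        corr = geo_correlation(dm, metas)
        assert corr.pearson_r == pytest.approx(1.0)
        assert corr.r_squared == pytest.approx(corr.pearson_r**2, abs=1e-12)
        assert corr.n_pairs == 6

    def test_hand_computed_r(self):
        metas = self._metas_square()
        rng = np.random.default_rng(1)
        vals = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        vals[iu] = rng.uniform(0.2, 0.8, size=6)
        vals += vals.T
        dm = DissimilarityMatrix(sample_ids=[m.sample_id for m in metas], values=vals)
        corr = geo_correlation(dm, metas)
        geo = [
            great_circle(a.latitude, a.longitude, b.latitude, b.longitude)
            for i, a in enumerate(metas)
            for b in metas[i + 1 :]
        ]
        diss = [dm.values[i, j] for i, j in zip(*iu)]
        expected = np.corrcoef(geo, diss)[0, 1]
        assert corr.pearson_r == pytest.approx(float(expected), abs=1e-12)

    def test_constant_dissimilarity_flagged(self):
        metas = self._metas_square()
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0.0)
        dm = DissimilarityMatrix(sample_ids=[m.sample_id for m in metas], values=vals)
        with pytest.warns(UserWarning):
            corr = geo_correlation(dm, metas)
        assert math.isnan(corr.pearson_r)

    def test_missing_coordinates_listed(self):
        metas = self._metas_square()
        metas[2].latitude = None
        dm, _ = separated_matrix(n_per_group=2, groups=("a", "b"))
        dm = DissimilarityMatrix(
            sample_ids=[m.sample_id for m in metas], values=dm.values
        )
        with pytest.raises(ValueError, match="c"):
            geo_correlation(dm, metas)
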