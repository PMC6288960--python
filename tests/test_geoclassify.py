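import numpy as np
import pytest

from kmergeo import (
    build_sample_data,
    evaluate_splits,
    knn_predict,
    leave_one_out_accuracy,
    ngs_confidence,
    nn_link_table,
    reference_confidence,
)
from kmergeo.dissimilarity import DissimilarityMatrix
from kmergeo.synthetic_data import SimulationConfig, simulate_readsets

from .conftest import separated_matrix


def matrix_from(ids, entries):
    n = len(ids)
    values = np.zeros((n, n))
    index = {s: i for i, s in enumerate(ids)}
    for (a, b), v in entries.items():
        values[index[a], index[b]] = values[index[b], index[a]] = v
    return DissimilarityMatrix(sample_ids=list(ids), values=values)


class TestKnnPredict:
    @pytest.fixture
    def small(self):
        ids = ["q", "A1", "A2", "B1"]
        dm = matrix_from(
            ids,
            {
                ("q", "A1"): 0.1,
                ("q", "A2"): 0.2,
                ("q", "B1"): 0.3,
                ("A1", "A2"): 0.05,
                ("A1", "B1"): 0.5,
                ("A2", "B1"): 0.5,
            },
        )
        return dm, {"A1": "NA", "A2": "NA", "B1": "EU"}

    def test_majority_vote(self, small):
        dm, labels = small
        pred = knn_predict(dm, labels, "q", K=2)
        assert pred.predicted == "NA"
        assert pred.votes == {"NA": 2}
        assert pred.neighbor_ids == ["A1", "A2"]
        assert pred.neighbor_distances == [0.1, 0.2]

    def test_majority_with_minority_neighbor(self, small):
        dm, labels = small
        pred = knn_predict(dm, labels, "q", K=3)
        assert pred.predicted == "NA"
        assert pred.votes == {"NA": 2, "EU": 1}

    def test_vote_tie_goes_to_nearest(self):
        ids = ["q", "A1", "B1"]
        dm = matrix_from(ids, {("q", "A1"): 0.3, ("q", "B1"): 0.1, ("A1", "B1"): 0.5})
        pred = knn_predict(dm, {"A1": "NA", "B1": "EU"}, "q", K=2)
        assert pred.predicted == "EU"

    def test_k_exceeding_training_size(self, small):
        dm, labels = small
        with pytest.raises(ValueError):
            knn_predict(dm, labels, "q", K=4)

    def test_invariant_to_matrix_row_order(self, small):
        dm, labels = small
        shuffled = dm.submatrix(["B1", "q", "A2", "A1"])
        a = knn_predict(dm, labels, "q", K=2)
        b = knn_predict(shuffled, labels, "q", K=2)
        assert a.predicted == b.predicted and a.neighbor_ids == b.neighbor_ids

    def test_distance_tie_broken_by_ascending_id(self):
        ids = ["q", "B1", "A1"]
        dm = matrix_from(ids, {("q", "A1"): 0.2, ("q", "B1"): 0.2, ("A1", "B1"): 0.5})
        pred = knn_predict(dm, {"A1": "NA", "B1": "EU"}, "q", K=1)
        assert pred.neighbor_ids == ["A1"]


class TestEvaluateSplits:
    def test_perfectly_separated_is_exact(self, toy_matrix):
        dm, labels = toy_matrix
        # train_size 9 of 12 guarantees every 4-member continent is represented
        df = evaluate_splits(dm, labels, train_size=9, K_values=[1], n_splits=20, seed=0)
        assert df.loc[0, "accuracy"] == 1.0

    def test_shuffled_labels_near_chance(self):
        dm, labels = separated_matrix(n_per_group=6, jitter=0.0)
        rng = np.random.default_rng(42)
        shuffled_values = list(labels.values())
        rng.shuffle(shuffled_values)
        shuffled = dict(zip(labels.keys(), shuffled_values))
        # distances carry no information about the shuffled labels, so 1-NN
        # accuracy is near the 1/3 chance level for 3 balanced classes
        accs = []
        for seed in range(10):
            rnd = np.random.default_rng(seed + 1)
            n = len(dm)
            vals = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            draws = rnd.uniform(0.1, 0.9, size=iu[0].size)
            vals[iu] = draws
            vals += vals.T
            rdm = DissimilarityMatrix(sample_ids=dm.sample_ids, values=vals)
            df = evaluate_splits(rdm, shuffled, train_size=12, K_values=[1], n_splits=20, seed=seed)
            accs.append(df.loc[0, "accuracy"])
        assert abs(np.mean(accs) - 1 / 3) < 0.1

    def test_leave_one_out_limit(self, toy_matrix):
        dm, labels = toy_matrix
        n = len(dm)
        df = evaluate_splits(dm, labels, train_size=n - 1, K_values=[1], n_splits=30, seed=1)
        assert df.loc[0, "accuracy"] == leave_one_out_accuracy(dm, labels, K=1)

    def test_split_missing_a_class_is_not_an_error(self):
        dm, labels = separated_matrix(n_per_group=2)
        df = evaluate_splits(dm, labels, train_size=2, K_values=[1], n_splits=50, seed=0)
        assert 0.0 <= df.loc[0, "accuracy"] <= 1.0


class TestNnLinkTable:
    def test_separated_matrix_links_perfectly(self, toy_matrix):
        dm, labels = toy_matrix
        table = nn_link_table(dm, labels)
        assert table["top1_same_continent"].all()
        assert table["top1_same_continent"].mean() == 1.0

    def test_one_mislabeled_sample(self):
        # NA0 is relabeled EU but sits slightly apart within the NA cluster,
        # so it is nobody's nearest neighbor while its own nearest neighbor
        # is a genuine NA sample
        dm, labels = separated_matrix(jitter=0.01, seed=7)
        pushed = dm.values.copy()
        i = dm.index("NA0")
        for j in range(len(dm)):
            if j != i and labels[dm.sample_ids[j]] == "NA":
                pushed[i, j] = pushed[j, i] = pushed[i, j] + 0.05
        dm2 = DissimilarityMatrix(sample_ids=dm.sample_ids, values=pushed)
        wrong = dict(labels)
        wrong["NA0"] = "EU"
        table = nn_link_table(dm2, wrong)
        n = len(dm2)
        assert table["top1_same_continent"].mean() == (n - 1) / n

    def test_top1_not_farther_than_top2(self, toy_matrix):
        dm, labels = separated_matrix(jitter=0.05, seed=3)
        table = nn_link_table(dm, labels)
        assert (table["top1_distance"] <= table["top2_distance"]).all()


class TestReferenceConfidence:
    def test_separated_data_fully_confident(self):
        # group sizes large enough that a bootstrap resample dropping an
        # entire continent is essentially impossible
        dm, labels = separated_matrix(n_per_group=12)
        rc = reference_confidence(dm, labels, "NA0", K_values=(1, 3), B=100, seed=0)
        assert rc == {1: 1.0, 3: 1.0}

    def test_single_bootstrap_identity_resample(self, toy_matrix):
        dm, labels = toy_matrix
        # any resample of a perfectly separated panel predicts identically
        rc = reference_confidence(dm, labels, "EU1", K_values=(1,), B=1, seed=5)
        assert rc[1] == 1.0

    def test_borderline_query_is_uncertain(self):
        # query almost equidistant between two groups: dropping its single
        # nearest reference in a resample flips the prediction
        ids = ["q"] + [f"NA{i}" for i in range(8)] + [f"EU{i}" for i in range(8)]
        entries = {}
        for i in range(8):
            entries[("q", f"NA{i}")] = 0.499 if i == 0 else 0.6
            entries[("q", f"EU{i}")] = 0.5005 if i == 0 else 0.6
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                key = (ids[a], ids[b])
                if key not in entries and "q" not in key:
                    entries[key] = 0.3
        dm = matrix_from(ids, entries)
        labels = {s: ("NA" if s.startswith("NA") else "EU") for s in ids if s != "q"}
        rc = reference_confidence(dm, labels, "q", K_values=(1,), B=200, seed=0)
        assert rc[1] < 1.0

    def test_invalid_b(self, toy_matrix):
        dm, labels = toy_matrix
        with pytest.raises(ValueError):
            reference_confidence(dm, labels, "NA0", B=0)


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(
        genome_length=30_000,
        n_individuals=3,
        bases_per_sample=30_000,
        seed=11,
    )
    readsets, metas = simulate_readsets(cfg)
    labels = {m.sample_id: m.continent for m in metas}
    refs = [
        build_sample_data(readsets[sid], k=6, m=2, measure="d2star")
        for sid in sorted(readsets)
    ]
    return readsets, refs, labels


class TestNgsConfidence:
    def test_unanimous_subsets_give_full_confidence(self, cohort):
        readsets, refs, labels = cohort
        query = readsets["EU_00"]
        refs_wo_query = [r for r in refs if r.sample_id != "EU_00"]
        nc, modal, preds = ngs_confidence(
            query, refs_wo_query, labels, k=6, m=2, n_subsets=4, seed=3
        )
        assert modal == "EU"
        assert nc == len([p for p in preds if p == modal]) / len(preds)
        assert nc == 1.0

    def test_nc_counts_modal_fraction(self):
        # direct check of the modal-agreement arithmetic on forced predictions
        from collections import Counter

        preds = ["EU"] * 9 + ["AS"]
        counts = Counter(preds)
        assert counts["EU"] / len(preds) == 0.9

    def test_insufficient_query_data(self, cohort):
        readsets, refs, labels = cohort
        tiny = readsets["NA_00"]
        with pytest.raises(Exception):
            ngs_confidence(
                tiny, refs, labels, k=6, m=2, n_subsets=2, subset_bases=10**9, seed=0
            )
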