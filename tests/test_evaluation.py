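import numpy as np
import pytest

from lbmff import (
    TrainConfig,
    ValidationError,
    ablate,
    compute_metrics,
    cross_validate,
    make_folds,
    rank_predictions,
)
from lbmff.evaluation import best_f1_threshold
from lbmff.synthetic import SyntheticSpec, generate
from oracles import auc_oracle, aupr_oracle, confusion_oracle

FAST = TrainConfig(epochs=120)


class TestFolds:
    def test_even_split(self, rng):
        A = np.zeros((5, 4), int)
        A.flat[rng.choice(20, 10, replace=False)] = 1
        split = make_folds(A, 5, seed=0)
        assert [len(f) for f in split.folds] == [2, 2, 2, 2, 2]

    def test_remainder_spread_by_at_most_one(self, rng):
        A = np.zeros((4, 4), int)
        A.flat[rng.choice(16, 11, replace=False)] = 1
        sizes = [len(f) for f in make_folds(A, 5, seed=1).folds]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 11

    def test_folds_are_disjoint_and_cover_all_positives(self, rng):
        A = (rng.random((8, 9)) < 0.3).astype(int)
        split = make_folds(A, 5, seed=2)
        seen = {tuple(p) for f in split.folds for p in f}
        assert len(seen) == A.sum()
        assert all(A[i, j] == 1 for i, j in seen)

    def test_deterministic_given_seed(self, rng):
        A = (rng.random((6, 6)) < 0.4).astype(int)
        f1 = make_folds(A, 5, seed=3).folds
        f2 = make_folds(A, 5, seed=3).folds
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_too_few_positives_raises(self):
        A = np.zeros((3, 3), int)
        A[0, 0] = 1
        with pytest.raises(ValidationError):
            make_folds(A, 5)


class TestMetrics:
    def test_four_point_example(self):
        row = compute_metrics([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0], threshold=0.5)
        assert row["auc"] == pytest.approx(0.75, abs=1e-12)

    def test_perfect_separation(self):
        row = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], threshold=0.5)
        assert row["auc"] == 1.0 and row["aupr"] == 1.0

    def test_constant_scores_give_half_auc(self):
        row = compute_metrics([0.4, 0.4, 0.4, 0.4], [1, 0, 1, 0], threshold=0.5)
        assert row["auc"] == pytest.approx(0.5)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValidationError, match="single class"):
            compute_metrics([0.1, 0.2], [1, 1], threshold=0.5)

    def test_matches_brute_force_oracles_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            thr = float(rng.random())
            row = compute_metrics(scores, labels, threshold=thr)
            assert row["auc"] == pytest.approx(auc_oracle(scores, labels), abs=1e-9)
            assert row["aupr"] == pytest.approx(aupr_oracle(scores, labels), abs=1e-9)
            expect = confusion_oracle(scores, labels, thr)
            for key, val in expect.items():
                assert row[key] == pytest.approx(val, abs=1e-9)

    def test_specificity_and_recall_are_the_rate_complements(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        labels[0], labels[1] = 0, 1
        for thr in (0.2, 0.5, 0.8):
            row = compute_metrics(scores, labels, threshold=thr)
            pred = scores >= thr
            fpr = np.sum(pred & (labels == 0)) / np.sum(labels == 0)
            tpr = np.sum(pred & (labels == 1)) / np.sum(labels == 1)
            assert row["spe"] + fpr == pytest.approx(1.0)
            assert row["rec"] == pytest.approx(tpr)

    def test_best_f1_threshold_is_optimal(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        thr = best_f1_threshold(scores, labels)
        best = confusion_oracle(scores, labels, thr)["f1"]
        for t in np.unique(scores):
            assert confusion_oracle(scores, labels, t)["f1"] <= best + 1e-12


class TestCrossValidation:
    def test_identical_seeds_give_identical_reports(self, default_dataset, default_measures):
        ds, _ = default_dataset
        r1 = cross_validate(ds, weights="uniform", config=FAST, seed=7,
                            measures=default_measures, threshold_policy=0.5)
        r2 = cross_validate(ds, weights="uniform", config=FAST, seed=7,
                            measures=default_measures, threshold_policy=0.5)
        assert r1.rows == r2.rows

    def test_report_metrics_within_unit_interval(self, default_dataset, default_measures):
        ds, _ = default_dataset
        rep = cross_validate(ds, weights="uniform", config=FAST, seed=1,
                             measures=default_measures, threshold_policy=0.5)
        for row in rep.rows:
            for key in ("aupr", "auc", "f1", "acc", "rec", "spe", "pre"):
                assert 0.0 <= row[key] <= 1.0
        assert all(v >= 0 for v in rep.std.values())

    def test_sampled_negative_mode_runs_and_differs(self, default_dataset, default_measures):
        ds, _ = default_dataset
        rep = cross_validate(ds, weights="uniform", config=FAST, seed=1,
                             measures=default_measures, threshold_policy=0.5,
                             negative_mode="sampled", negative_ratio=1.0)
        # balanced negatives make AUPR far higher than full-matrix evaluation
        assert rep.mean["aupr"] > 0.5

    def test_inner_threshold_policy_produces_usable_confusion_metrics(
        self, default_dataset, default_measures
    ):
        ds, _ = default_dataset
        rep = cross_validate(ds, weights="uniform", config=TrainConfig(epochs=400),
                             seed=2, measures=default_measures,
                             threshold_policy="inner_f1")
        assert rep.mean["f1"] > 0.2
        assert rep.mean["rec"] > 0.2


class TestAblation:
    def test_rows_share_identical_folds_and_expected_keys(self, default_dataset, default_measures):
        ds, _ = default_dataset
        reports = ablate(ds, config=FAST, seed=3, measures=default_measures)
        assert {"chemical", "side_effect", "target", "literature", "MFF", "LBMFF"} <= set(reports)
        ref = reports["chemical"].fold_pairs
        for rep in reports.values():
            assert rep.fold_pairs == ref  # paired design


class TestRanking:
    @pytest.fixture()
    def tiny(self):
        ds, _ = generate(SyntheticSpec(m=2, n=2, b=1, p_in=0.5, p_out=0.0, seed=5))
        return ds

    def test_exclusion_plus_argmax_on_two_by_two(self, tiny):
        A = tiny.associations.values
        assert A.sum() >= 1
        scores = np.array([[0.9, 0.8], [0.7, 0.6]])
        top = rank_predictions(scores, tiny, mode="pairs", k=1)
        known = {(d, z) for d, z in zip(*np.where(A == 1))}
        cat = tiny.catalog
        best_unknown = max(
            ((i, j) for i in range(2) for j in range(2) if (i, j) not in known),
            key=lambda ij: scores[ij],
        )
        assert top.loc[0, "drug_id"] == cat.drug_ids[best_unknown[0]]
        assert top.loc[0, "disease_id"] == cat.disease_ids[best_unknown[1]]

    def test_all_known_matrix_yields_empty_list_with_warning(self, tiny):
        ones = np.ones_like(tiny.associations.values)
        with pytest.warns(UserWarning, match="truncating"):
            top = rank_predictions(np.full((2, 2), 0.5), tiny, k=1, known=ones)
        assert len(top) == 0

    def test_per_drug_mode_matches_row_sort_oracle(self, default_dataset, rng):
        ds, _ = default_dataset
        scores = rng.random((ds.catalog.m, ds.catalog.n))
        drug = ds.catalog.drug_ids[4]
        top = rank_predictions(scores, ds, mode="per_drug", k=5, entity_id=drug)
        row = scores[4].copy()
        row[ds.associations.values[4] == 1] = -np.inf
        expect = [ds.catalog.disease_ids[j] for j in np.argsort(-row)[:5]]
        assert top["disease_id"].tolist() == expect
        assert (top["drug_id"] == drug).all()

    def test_known_positives_never_ranked(self, default_dataset, rng):
        ds, _ = default_dataset
        scores = rng.random((ds.catalog.m, ds.catalog.n))
        top = rank_predictions(scores, ds, mode="pairs", k=50)
        known = {
            (ds.catalog.drug_ids[i], ds.catalog.disease_ids[j])
            for i, j in zip(*np.where(ds.associations.values == 1))
        }
        assert all((d, z) not in known for d, z in zip(top.drug_id, top.disease_id))

    def test_ties_break_lexicographically(self, tiny):
        scores = np.full((2, 2), 0.5)
        top = rank_predictions(scores, tiny, k=4, known=np.zeros((2, 2), int))
        pairs = list(zip(top.drug_id, top.disease_id))
        assert pairs == sorted(pairs)
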