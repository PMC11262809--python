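"""Classifier training, metrics, cross-validation, importance, ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import repomine as rm
from repomine.classify import METRIC_NAMES, make_classifier


def brute_force_auroc(labels, scores) -> float:
    """Concordant-pair counting oracle: ties count one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = rm.compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert all(m[name] == 1.0 for name in METRIC_NAMES)

    def test_three_of_four_concordant_pairs(self):
        m = rm.compute_metrics([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert m["auroc"] == 0.75

    def test_all_correct_hard_predictions(self):
        m = rm.compute_metrics([1, 0, 1, 0], [1.0, 0.0, 1.0, 0.0])
        for name in ("accuracy", "precision", "recall", "f1"):
            assert m[name] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rm.compute_metrics([1, 1], [0.9, 0.8])

    def test_auroc_matches_concordance_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(10, 120)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            m = rm.compute_metrics(labels, scores)
            assert m["auroc"] == pytest.approx(brute_force_auroc(labels, scores), abs=1e-12)


class TestTrainClassifier:
    def test_separable_toy_reaches_training_accuracy_one(self):
        X = np.vstack([np.zeros((20, 3)), np.ones((20, 3))])
        y = np.array([0] * 20 + [1] * 20)
        model = rm.train_classifier(X, y, rm.ClassifierSpec(seed=0))
        assert (model.predict(X) == y).all()

    def test_same_seed_gives_identical_predictions(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 4))
        y = rng.integers(0, 2, 60)
        p1 = rm.train_classifier(X, y, rm.ClassifierSpec(seed=9)).predict_proba(X)
        p2 = rm.train_classifier(X, y, rm.ClassifierSpec(seed=9)).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            rm.train_classifier(np.zeros((5, 2)), np.ones(5))

    def test_constant_features_predict_majority_class_for_all_rows(self):
        X = np.ones((30, 3))
        y = np.array([1] * 10 + [0] * 20)
        model = rm.train_classifier(X, y, rm.ClassifierSpec(seed=0))
        proba = model.predict_proba(X)[:, 1]
        # every row gets the same score, near the class prior (bootstrap
        # resampling jitters it slightly), and the majority class wins
        assert len(np.unique(proba)) == 1
        assert proba[0] == pytest.approx(1 / 3, abs=0.1)
        assert (model.predict(X) == 0).all()

    @pytest.mark.filterwarnings("ignore::UserWarning")  # short MLP run need not converge
    @pytest.mark.parametrize("name", ["random_forest", "logistic_regression", "decision_tree", "knn", "mlp"])
    def test_every_registered_classifier_fits_and_scores(self, name):
        rng = np.random.default_rng(1)
        X = rng.random((50, 4))
        y = (X[:, 0] > 0.5).astype(int)
        spec = rm.ClassifierSpec(name, {"max_iter": 50} if name == "mlp" else {}, seed=0)
        model = rm.train_classifier(X, y, spec)
        proba = model.predict_proba(X)[:, 1]
        assert proba.shape == (50,) and (proba >= 0).all() and (proba <= 1).all()

    def test_unknown_classifier_name_rejected(self):
        with pytest.raises(ValueError):
            make_classifier(rm.ClassifierSpec("svm"))


@pytest.fixture(scope="module")
def cv_inputs(default_dataset, default_sims, pipeline_result):
    return pipeline_result.dataset_pairs, np.array(pipeline_result.dataset_labels), default_sims


class TestCrossValidate:
    def test_aggregate_is_exact_mean_of_folds(self, pipeline_result):
        report = pipeline_result.evaluation
        assert report.n_folds == 5
        for name in METRIC_NAMES:
            assert report.aggregate[name] == np.mean([f[name] for f in report.per_fold])

    def test_same_seed_gives_identical_report(self, cv_inputs):
        pairs, labels, sims = cv_inputs
        sub = list(range(0, len(pairs), 4))  # thin for speed
        pairs = [pairs[i] for i in sub]
        labels = labels[sub]
        r1 = rm.cross_validate(pairs, labels, sims, rm.ClassifierSpec(seed=3), seed=3)
        r2 = rm.cross_validate(pairs, labels, sims, rm.ClassifierSpec(seed=3), seed=3)
        assert r1.per_fold == r2.per_fold

    def test_spy_positive_in_test_fold_scores_like_an_unknown(self, default_sims, default_dataset):
        """Fold-restricted featurization: a held-out positive must be scored
        against an index that does not contain it."""
        index = default_dataset.index
        positives = sorted(index.positives)
        spy = positives[0]
        fold_index = rm.AssociationIndex.from_pairs(positives[1:])
        X_spy = rm.build_design_matrix([spy], default_sims, fold_index, mask_self=True)
        X_unknown = rm.build_design_matrix([spy], default_sims, fold_index, mask_self=False)
        np.testing.assert_array_equal(X_spy.values, X_unknown.values)
        d, s = spy
        assert s not in fold_index.diseases_of(d) and d not in fold_index.drugs_of(s)

    def test_mismatched_lengths_rejected(self, cv_inputs):
        pairs, labels, sims = cv_inputs
        with pytest.raises(ValueError):
            rm.cross_validate(pairs[:10], labels[:9], sims)

    def test_unknown_slot_name_rejected(self, cv_inputs):
        pairs, labels, sims = cv_inputs
        mixed = list(range(50)) + list(range(len(pairs) - 50, len(pairs)))  # both classes
        with pytest.raises(KeyError):
            rm.cross_validate(
                [pairs[i] for i in mixed], labels[mixed], sims,
                slots=["x__drug__nonexistent"], n_folds=2,
            )


class TestFeatureImportance:
    def _planted_model(self, permute=False, classifier="random_forest"):
        rng = np.random.default_rng(4)
        X = rng.random((300, 6))
        y = (X[:, 2] > 0.5).astype(int)  # only column 2 is informative
        names = [f"slot{i}" for i in range(6)]
        if permute:
            order = [3, 2, 0, 5, 1, 4]
            X = X[:, order]
            names = [names[i] for i in order]
        model = rm.train_classifier(X, y, rm.ClassifierSpec(classifier, seed=0))
        return model, names

    def test_planted_informative_slot_ranks_first(self):
        model, names = self._planted_model()
        ranking = rm.feature_importance(model, names)
        assert ranking[0][0] == "slot2"

    def test_importances_sum_to_one_and_descend(self):
        model, names = self._planted_model()
        ranking = rm.feature_importance(model, names)
        scores = [v for _, v in ranking]
        assert sum(scores) == pytest.approx(1.0, abs=1e-9)
        assert scores == sorted(scores, reverse=True)

    def test_column_permutation_permutes_but_preserves_scores(self):
        # a deterministic single tree considers every feature at each split,
        # so reordering columns relabels importances without changing them
        # (forests subsample features per split, so this holds only per-tree)
        r1 = dict(rm.feature_importance(*self._planted_model(classifier="decision_tree")))
        r2 = dict(rm.feature_importance(*self._planted_model(permute=True, classifier="decision_tree")))
        for name in r1:
            assert r1[name] == pytest.approx(r2[name], abs=1e-9)

    def test_non_tree_model_rejected(self):
        rng = np.random.default_rng(0)
        X, y = rng.random((40, 3)), rng.integers(0, 2, 40)
        model = rm.train_classifier(X, y, rm.ClassifierSpec("logistic_regression", seed=0))
        with pytest.raises(TypeError):
            rm.feature_importance(model, ["a", "b", "c"])


@pytest.fixture(scope="module")
def small_run():
    """A small 8-slot benchmark so the 2j+2 CV sweep stays cheap."""
    cfg = rm.GeneratorConfig(
        n_drugs=30, m_diseases=20, k_set_features_drug=1, k_text_features_drug=1,
        k_set_features_disease=1, k_text_features_disease=0, density=0.08, seed=5,
    )
    ds = rm.generate(cfg)
    sims = rm.build_all_similarities(ds.drug_table, ds.disease_table)
    result = rm.run_pipeline(ds.drug_table, ds.disease_table, ds.index, rm.PipelineConfig(seed=5), sims=sims)
    return ds, sims, result


class TestIncrementalEvaluation:
    def test_table_has_one_row_per_slot_and_final_row_matches_full_cv(self, small_run):
        ds, sims, result = small_run
        ranking = rm.feature_importance(result.model, sims.catalog.slot_names())
        table = rm.incremental_feature_evaluation(
            result.dataset_pairs, result.dataset_labels, sims, ranking,
            rm.ClassifierSpec(seed=5), seed=5,
        )
        assert len(table) == sims.catalog.n_slots == 8
        full = rm.cross_validate(
            result.dataset_pairs, result.dataset_labels, sims, rm.ClassifierSpec(seed=5), seed=5
        )
        last = table.iloc[-1]
        for name in METRIC_NAMES:
            assert last[name] == pytest.approx(full.aggregate[name], abs=1e-12)

    def test_incomplete_ranking_rejected(self, small_run):
        ds, sims, result = small_run
        with pytest.raises(ValueError):
            rm.incremental_feature_evaluation(
                result.dataset_pairs, result.dataset_labels, sims,
                [("size_A", 1.0)], rm.ClassifierSpec(seed=5),
            )


class TestRankCandidates:
    def test_descending_order_and_positive_exclusion(self, pipeline_result, default_dataset):
        index = default_dataset.index
        s = sorted(index.B)[0]  # a disease with known drugs
        frame = rm.rank_candidates(pipeline_result.model, pipeline_result.sims, index, disease_id=s)
        assert (frame.score.values[:-1] >= frame.score.values[1:]).all()
        assert not set(zip(frame.drug_id, frame.disease_id)) & index.positives
        assert len(frame) == len(pipeline_result.sims.drug_ids) - len(index.drugs_of(s))

    def test_top_k_and_drug_query(self, pipeline_result, default_dataset):
        index = default_dataset.index
        d = sorted(index.A)[0]
        frame = rm.rank_candidates(pipeline_result.model, pipeline_result.sims, index, drug_id=d, top_k=7)
        assert len(frame) == 7
        assert (frame.drug_id == d).all()

    def test_unknown_query_and_ambiguous_query_rejected(self, pipeline_result, default_dataset):
        with pytest.raises(KeyError):
            rm.rank_candidates(pipeline_result.model, pipeline_result.sims, default_dataset.index,
                               disease_id="S999")
        with pytest.raises(ValueError):
            rm.rank_candidates(pipeline_result.model, pipeline_result.sims, default_dataset.index)

    def test_withheld_true_pairs_rank_high_among_candidates(self, pipeline_result, default_dataset):
        """Ranking recovers planted-but-withheld associations: the best one
        reaches the podium and the typical one sits in the top half."""
        ds = default_dataset
        ranks = []
        for d, s in ds.heldout_pairs:
            frame = rm.rank_candidates(pipeline_result.model, pipeline_result.sims, ds.index, disease_id=s)
            position = frame.index[frame.drug_id == d][0] + 1
            ranks.append(position)
        assert min(ranks) <= 3
        assert np.median(ranks) <= 0.5 * len(pipeline_result.sims.drug_ids)
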