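"""Cross-validation schemes, class equalization and wrapper selection."""

import numpy as np
import pandas as pd
import pytest

from geomood.evaluation import (
    CVConfig,
    group_equalize,
    make_folds,
    qda_factory,
    run_cv,
    wrapper_select,
)
from geomood.models import fit_qda


class TestGroupEqualize:
    def test_already_balanced_keeps_everything(self):
        y = np.repeat([0, 1], 10)
        idx = group_equalize(y, np.random.default_rng(0))
        assert len(idx) == 20

    def test_majority_subsampled_to_minority_count(self):
        y = np.concatenate([np.zeros(30), np.ones(10)])
        idx = group_equalize(y, np.random.default_rng(0))
        assert len(idx) == 20
        assert (y[idx] == 0).sum() == 10 and (y[idx] == 1).sum() == 10
        # the under-represented class is fully included
        assert set(np.flatnonzero(y == 1)) <= set(idx)

    def test_deterministic_given_seed(self):
        y = np.concatenate([np.zeros(30), np.ones(10)])
        a = group_equalize(y, np.random.default_rng(5))
        b = group_equalize(y, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            group_equalize(np.zeros(10), np.random.default_rng(0))


def _toy_data(n_participants=8, weeks=10, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    rows, y, groups = [], [], []
    for p in range(n_participants):
        for w in range(weeks):
            depressed = rng.random() < 0.4
            rows.append(rng.normal(sep if depressed else 0.0, 1.0, 3))
            y.append(int(depressed))
            groups.append(f"p{p}")
    return np.asarray(rows), np.asarray(y), np.asarray(groups)


class TestFolds:
    def test_lopo_fold_count_and_no_leakage(self):
        X, y, groups = _toy_data()
        partitions = make_folds(groups, y, CVConfig(scheme="lopo"), np.random.default_rng(0))
        assert len(partitions) == 1
        splits = partitions[0]
        assert len(splits) == len(np.unique(groups))
        for tr, te in splits:
            assert set(groups[tr]).isdisjoint(set(groups[te]))

    def test_kfold_participant_partitions_and_repeats(self):
        X, y, groups = _toy_data(n_participants=12)
        config = CVConfig(scheme="kfold_participant", k=5)
        partitions = make_folds(groups, y, config, np.random.default_rng(0))
        assert len(partitions) == int(np.ceil(12 / 5))
        for splits in partitions:
            tested = np.concatenate([te for _, te in splits])
            assert sorted(tested) == list(range(len(y)))
            for tr, te in splits:
                assert set(groups[tr]).isdisjoint(set(groups[te]))

    def test_threefold_within_interleaves_participant_weeks(self):
        X, y, groups = _toy_data(n_participants=3, weeks=9)
        partitions = make_folds(groups, y, CVConfig(scheme="threefold_within"),
                                np.random.default_rng(0))
        splits = partitions[0]
        assert len(splits) == 3
        for _, te in splits:
            # every participant contributes weeks to every fold
            assert set(groups[te]) == set(np.unique(groups))

    def test_two_participants_lopo_two_folds(self):
        X, y, groups = _toy_data(n_participants=2)
        splits = make_folds(groups, y, CVConfig(), np.random.default_rng(0))[0]
        assert len(splits) == 2


class TestRunCV:
    def test_separable_data_high_f1(self):
        X, y, groups = _toy_data(sep=4.0)
        cv = run_cv(X, y, groups, qda_factory(), CVConfig(m_equalize=10, seed=0))
        assert cv.median("f1") > 0.85
        assert len(cv.metrics["f1"]) == 10

    def test_deterministic_given_seed(self):
        X, y, groups = _toy_data()
        cv1 = run_cv(X, y, groups, qda_factory(), CVConfig(m_equalize=5, seed=3))
        cv2 = run_cv(X, y, groups, qda_factory(), CVConfig(m_equalize=5, seed=3))
        np.testing.assert_array_equal(cv1.metrics["f1"], cv2.metrics["f1"])

    def test_single_class_training_fold_skipped(self):
        X, y, groups = _toy_data(n_participants=3)
        # make all weeks of p0 and p1 class 0: leaving p2 out yields a
        # single-class training set
        y = y.copy()
        y[groups != "p2"] = 0
        y[groups == "p2"] = 1
        with pytest.warns(UserWarning, match="single-class"):
            cv = run_cv(X, y, groups, qda_factory(), CVConfig(m_equalize=2, seed=0))
        # leaving p2 out removes every positive week from training
        assert cv.n_skipped_folds == 1
        # the remaining folds pool only class-0 test weeks: metrics undefined
        assert np.all(np.isnan(cv.metrics["f1"]))

    def test_regression_task_reports_mae(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (60, 2))
        y = X @ [2.0, -1.0] + 10 + rng.normal(0, 0.1, 60)
        groups = np.repeat([f"p{i}" for i in range(6)], 10)
        from geomood.evaluation import linear_factory

        cv = run_cv(X, y, groups, linear_factory(), CVConfig(seed=0), task="regression")
        assert cv.median("mae") < 0.5


class TestWrapperSelect:
    def _informative_table(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 120
        y = (np.arange(n) % 2).astype(int)
        groups = np.repeat([f"p{i}" for i in range(8)], n // 8)
        data = {"signal": np.where(y == 1, 2.5, 0.0) + rng.normal(0, 0.5, n)}
        for j in range(9):
            data[f"noise{j}"] = rng.normal(0, 1, n)
        return pd.DataFrame(data), y, groups

    def test_informative_feature_selected_first(self):
        table, y, groups = self._informative_table()
        selected, trace = wrapper_select(
            table, y, groups, qda_factory(), CVConfig(m_equalize=2, seed=0),
            criterion="f1", max_features=1,
        )
        assert selected[0] == "signal"
        assert len(trace) == 1

    def test_max_features_one_is_argmax_of_single_feature_score(self):
        table, y, groups = self._informative_table(seed=1)
        config = CVConfig(m_equalize=2, seed=0)
        selected, _ = wrapper_select(table, y, groups, qda_factory(), config, max_features=1)
        scores = {}
        for col in table.columns:
            cv = run_cv(table[[col]].to_numpy(), y, groups, qda_factory(), config)
            scores[col] = cv.median("f1")
        assert selected[0] == max(scores, key=scores.get)

    def test_greedy_path_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(2)
        n = 90
        y = (np.arange(n) % 2).astype(int)
        groups = np.repeat([f"p{i}" for i in range(6)], n // 6)
        table = pd.DataFrame(
            {
                "a": np.where(y == 1, 1.5, 0.0) + rng.normal(0, 0.8, n),
                "b": np.where(y == 1, 0.8, 0.0) + rng.normal(0, 0.8, n),
                "c": rng.normal(0, 1, n),
            }
        )
        config = CVConfig(m_equalize=2, seed=0)
        selected, _ = wrapper_select(table, y, groups, qda_factory(), config, max_features=3)

        # brute-force greedy oracle
        remaining, chosen = list(table.columns), []
        while remaining:
            best, best_score = None, -np.inf
            for col in remaining:
                cv = run_cv(table[chosen + [col]].to_numpy(), y, groups, qda_factory(), config)
                if cv.median("f1") > best_score + 1e-12:
                    best, best_score = col, cv.median("f1")
            chosen.append(best)
            remaining.remove(best)
        assert selected == chosen


def test_wrapper_with_mae_criterion_prefers_predictive_feature():
    rng = np.random.default_rng(3)
    n = 80
    groups = np.repeat([f"p{i}" for i in range(8)], n // 8)
    signal = rng.uniform(0, 1, n)
    q = 5 + 15 * signal + rng.normal(0, 0.5, n)
    table = pd.DataFrame({"signal": signal, "noise": rng.normal(0, 1, n)})
    from geomood.evaluation import linear_factory

    selected, trace = wrapper_select(
        table, q, groups, linear_factory(), CVConfig(seed=0),
        criterion="mae", max_features=1,
    )
    assert selected == ["signal"]
    assert trace[0].median("mae") < 2.0
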