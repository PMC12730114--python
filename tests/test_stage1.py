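"""Standardization, OAO/OAA training and prediction, metrics, GA fitness."""

import itertools

import numpy as np
import pytest

from hpastack.stage1 import (
    CVPlan,
    apply_standardizer,
    fit_standardizer,
    macro_f1,
    make_ga_fitness,
    oao_input,
    oao_scores,
    predict_oaa,
    predict_oao,
    train_oaa,
    train_oao,
    weighted_f1,
)


class TestStandardizer:
    def test_hand_computed_zscores(self):
        stats = fit_standardizer(np.array([[1.0], [2.0], [3.0]]))
        out = apply_standardizer(stats, np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_train_columns_become_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(50, 4))
        stats = fit_standardizer(X)
        Z = apply_standardizer(stats, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-12)

    def test_constant_column_standardizes_to_zeros(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        stats = fit_standardizer(X)
        Z = apply_standardizer(stats, X)
        np.testing.assert_array_equal(Z[:, 1], np.zeros(5))

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_standardizer(np.ones((1, 3)))


def _blobs(n_classes=3, per_class=20, sep=8.0, seed=0, d=5):
    """Linearly separable Gaussian blobs."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k in range(n_classes):
        center = np.zeros(d)
        center[k % d] = sep * (1 + k // d)
        X.append(rng.normal(center, 0.5, size=(per_class, d)))
        y.append(np.full(per_class, k))
    return np.vstack(X), np.concatenate(y)


class TestOAO:
    def test_pair_count_is_n_choose_2(self):
        X, y = _blobs(n_classes=4, per_class=8)
        model = train_oao(X, y, C=1.0)
        assert len(model.pair_models) == 6
        X2, y2 = _blobs(n_classes=2, per_class=8)
        assert len(train_oao(X2, y2, C=1.0).pair_models) == 1

    def test_separable_blobs_reach_perfect_macro_f1_via_cv(self):
        X, y = _blobs(n_classes=3, per_class=15, seed=1)
        model = train_oao(X, y, plan=CVPlan(seed=0))
        assert model.C in (0.01, 0.1, 1.0, 10.0)
        y_hat = predict_oao(model, oao_input(model, X))
        assert macro_f1(y, y_hat, [0, 1, 2]) == 1.0

    def test_scores_are_calibrated_probabilities_in_unit_interval(self):
        X, y = _blobs(n_classes=3, per_class=10, seed=2)
        model = train_oao(X, y, C=1.0)
        S = oao_scores(model, oao_input(model, X))
        assert S.shape == (30, 3)
        assert S.min() >= 0.0 and S.max() <= 1.0
        # pair (0, 1): class-0 rows should score the lower index high
        assert S[y == 0, 0].mean() > 0.9
        assert S[y == 1, 0].mean() < 0.1

    def test_voting_matches_brute_force_counter_on_random_instances(self):
        """Decide every pairwise contest at random and compare predict_oao's
        winner to an exhaustive vote count, for all N <= 6."""
        rng = np.random.default_rng(7)
        for n in range(2, 7):
            classes = list(range(n))
            for _ in range(40):
                wins = {}
                for i, j in itertools.combinations(classes, 2):
                    wins[(i, j)] = int(rng.integers(0, 2))  # 1 -> i beats j
                votes = {c: 0 for c in classes}
                for (i, j), w in wins.items():
                    votes[i if w else j] += 1
                best = max(votes.values())
                expected = min(c for c in classes if votes[c] == best)
                got = _vote_winner(classes, wins)
                assert got == expected
                assert sum(votes.values()) == n * (n - 1) // 2

    def test_excluded_tiny_classes_warn(self):
        X, y = _blobs(n_classes=3, per_class=10)
        y = np.concatenate([y, [9]])
        X = np.vstack([X, X[:1]])
        with pytest.warns(UserWarning, match="excluded"):
            model = train_oao(X, y, C=1.0)
        assert 9 not in model.classes


def _vote_winner(classes, wins):
    """Drive predict_oao with stub pairwise models implementing `wins`."""
    from hpastack.stage1 import OAOModelSet, StandardizationStats, _PairModel

    class _StubSVM:
        def __init__(self, w):
            self.w = w

        def decision_function(self, X):
            return np.full(X.shape[0], 1.0 if self.w else -1.0)

    pair_models = {
        pair: _PairModel(svm=_StubSVM(w), calibrator=None)
        for pair, w in wins.items()
    }
    stats = StandardizationStats(mean=np.zeros(1), sd=np.ones(1))
    ms = OAOModelSet(classes=tuple(classes), pair_models=pair_models,
                     C=1.0, stats=stats)
    return int(predict_oao(ms, np.zeros((1, 1)))[0])


class TestOAA:
    def test_model_count_equals_class_count(self):
        X, y = _blobs(n_classes=4, per_class=8)
        model = train_oaa(X, y, C=1.0)
        assert len(model.per_class_models) == 4

    def test_oaa_and_oao_agree_on_separable_fixture(self):
        X, y = _blobs(n_classes=3, per_class=15, seed=3)
        oao = train_oao(X, y, C=1.0)
        oaa = train_oaa(X, y, C=1.0)
        from hpastack.stage1 import apply_standardizer

        p_oao = predict_oao(oao, oao_input(oao, X))
        p_oaa = predict_oaa(oaa, apply_standardizer(oaa.stats, X))
        np.testing.assert_array_equal(p_oao, p_oaa)
        np.testing.assert_array_equal(p_oao, y)


class TestMetrics:
    def test_perfect_prediction_scores_one(self):
        y = np.array([0, 1, 2, 1])
        assert macro_f1(y, y, [0, 1, 2]) == 1.0

    def test_hand_computed_macro_f1(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 1, 1, 1])
        # class 0: P=1, R=1/2 -> F1=2/3 ; class 1: P=2/3, R=1 -> F1=4/5
        assert macro_f1(y_true, y_pred, [0, 1]) == pytest.approx(11 / 15)

    def test_all_wrong_scores_zero(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([1, 1, 0, 0])
        assert macro_f1(y_true, y_pred, [0, 1]) == 0.0

    def test_macro_f1_is_invariant_under_class_relabeling(self):
        rng = np.random.default_rng(11)
        y_true = rng.integers(0, 4, 60)
        y_pred = rng.integers(0, 4, 60)
        base = macro_f1(y_true, y_pred, [0, 1, 2, 3])
        perm = np.array([2, 0, 3, 1])
        assert macro_f1(perm[y_true], perm[y_pred], [0, 1, 2, 3]) == pytest.approx(base)

    def test_weighted_f1_weights_by_support(self):
        y_true = np.array([0, 0, 0, 1])
        y_pred = np.array([0, 0, 0, 0])
        # class 0: F1 = 6/7 (P=3/4, R=1); class 1: F1=0; weights 3:1
        assert weighted_f1(y_true, y_pred, [0, 1]) == pytest.approx((6 / 7) * 3 / 4)


class TestLeakFreedom:
    def test_cv_fold_statistics_differ_and_exclude_heldout_rows(self):
        """Per-fold standardization means must differ across folds and match
        statistics recomputed from the fold's training rows only."""
        from sklearn.model_selection import StratifiedKFold

        from hpastack.stage1 import fit_standardizer

        X, y = _blobs(n_classes=3, per_class=10, seed=5)
        model = train_oao(X, y, plan=CVPlan(seed=0))
        fold_stats = model.cv_fold_stats
        assert len(fold_stats) == 5
        sums = {round(s.checksum(), 9) for s in fold_stats}
        assert len(sums) == 5  # all folds differ
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for (tr, va), stats in zip(skf.split(X, y), fold_stats):
            expected = fit_standardizer(X[tr])
            np.testing.assert_allclose(stats.mean, expected.mean)
            np.testing.assert_allclose(stats.sd, expected.sd)

    def test_permuting_test_rows_leaves_training_artifacts_unchanged(self):
        X, y = _blobs(n_classes=3, per_class=10, seed=6)
        model_a = train_oao(X, y, C=1.0)
        model_b = train_oao(X, y, C=1.0)
        np.testing.assert_array_equal(model_a.stats.mean, model_b.stats.mean)
        for pair in model_a.pair_models:
            np.testing.assert_allclose(
                model_a.pair_models[pair].svm.coef_,
                model_b.pair_models[pair].svm.coef_,
            )


class TestGAFitness:
    def test_signal_chromosome_beats_noise_chromosome(self, small_synth):
        from hpastack.blocks import BlockId
        from hpastack.io import phase1_split
        from hpastack.pipeline import planted_cell_matrix

        index, _ = small_synth
        singles = index.subset([r.sample_id for r in index.single_label_records])
        informative = [BlockId("densenet201", "nucleus"),
                       BlockId("densenet201", "ring")]
        matrix = planted_cell_matrix(singles, singles.sample_ids, informative,
                                     seed=0, signal_stats=None)
        sub = singles.subset(matrix.sample_ids)
        split = phase1_split(sub, seed=0)
        y_tr = np.array([next(iter(sub[i].labels)) for i in split.train_ids])
        y_te = np.array([next(iter(sub[i].labels)) for i in split.test_ids])
        fitness = make_ga_fitness(
            matrix.rows_for(split.train_ids), matrix.rows_for(split.test_ids),
            y_tr, y_te,
        )
        from hpastack.blocks import cell_level_block_ids

        names = cell_level_block_ids()
        signal = np.array([1 if b in informative else 0 for b in names],
                          dtype=np.uint8)
        noise = np.zeros(24, dtype=np.uint8)
        noise[0] = 1  # alexnet:nucleus carries no signal
        assert fitness(signal) > 0.85
        assert fitness(noise) < 0.6
        # determinism of the fitness itself
        assert fitness(signal) == fitness(signal)
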