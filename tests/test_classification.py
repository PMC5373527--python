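"""OVO RBF-SVM: kernel, scaler, voting, grid search, CV driver."""
import numpy as np
import pytest

from mibci import (FeatureMatrix, FeatureScaler, SVMHyper,
                   cross_validate_10x10, grid_search, predict, rbf_kernel,
                   train_ovo)


def gaussian_blobs(seed=0, n=30, sigma=0.1, spread=5.0):
    """Three well-separated Gaussian blobs in 2-D."""
    rng = np.random.default_rng(seed)
    centers = {"REST": (0, 0), "MI-GRASP": (spread, 0),
               "MI-ELBOW": (0, spread)}
    X, y = [], []
    for cls, (cx, cy) in centers.items():
        X.append(rng.normal((cx, cy), sigma, size=(n, 2)))
        y += [cls] * n
    return FeatureMatrix(np.vstack(X), ["f1", "f2"], np.array(y, object))


class TestRBFKernel:
    def test_zero_distance_is_one(self):
        u = np.array([1.0, 2.0, 3.0])
        assert rbf_kernel(u, u, gamma=0.7) == pytest.approx(1.0)

    def test_unit_distance_closed_form(self):
        assert rbf_kernel([0.0], [1.0], gamma=1.0) == pytest.approx(
            np.exp(-1.0))

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u, v = rng.standard_normal((2, 5))
            k = rbf_kernel(u, v, 0.3)
            assert k == pytest.approx(rbf_kernel(v, u, 0.3))
            assert 0 < k <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([1.0], [1.0, 2.0], 1.0)


class TestScaler:
    def test_fit_transform_standardizes(self):
        X = np.random.default_rng(0).normal(5, 3, size=(200, 4))
        Z = FeatureScaler().fit(X).transform(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_heldout_rows_use_training_statistics(self):
        rng = np.random.default_rng(1)
        train, test = rng.normal(0, 1, (100, 3)), rng.normal(2, 1, (100, 3))
        Z = FeatureScaler().fit(train).transform(test)
        assert np.abs(Z.mean(axis=0)).min() > 0.5  # shifted, not re-centred

    def test_constant_column_passes_through(self, caplog):
        X = np.random.default_rng(2).standard_normal((50, 2))
        X[:, 1] = 4.2
        with caplog.at_level("WARNING"):
            Z = FeatureScaler().fit(X).transform(X)
        assert np.allclose(Z[:, 1], 4.2)
        assert "constant" in caplog.text

    def test_unfitted_scaler_rejected(self):
        with pytest.raises(RuntimeError):
            FeatureScaler().transform(np.zeros((2, 2)))


class TestTrainPredict:
    def test_three_classes_give_three_binary_models(self):
        fm = gaussian_blobs()
        model = train_ovo(fm, SVMHyper(10, 0.5))
        assert len(model.binary_models) == 3
        assert len(model.pairs) == 3

    def test_separable_blobs_train_accuracy_100(self):
        fm = gaussian_blobs()
        model = train_ovo(fm, SVMHyper(10, 0.5))
        assert np.all(predict(model, fm) == fm.labels)

    def test_duplication_invariance(self):
        fm = gaussian_blobs(seed=3)
        doubled = FeatureMatrix(np.vstack([fm.values, fm.values]),
                                fm.feature_names,
                                np.concatenate([fm.labels, fm.labels]))
        probe = gaussian_blobs(seed=4)
        m1 = train_ovo(fm, SVMHyper(10, 0.5))
        m2 = train_ovo(doubled, SVMHyper(10, 0.5))
        assert np.all(predict(m1, probe) == predict(m2, probe))

    def test_majority_vote_wins(self):
        fm = gaussian_blobs()
        model = train_ovo(fm, SVMHyper(10, 0.5))
        # points at blob centers get unanimous pairwise outcomes
        centers = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        assert list(predict(model, centers)) == ["REST", "MI-GRASP",
                                                 "MI-ELBOW"]

    def test_predictions_within_class_list(self, small_features):
        model = train_ovo(small_features, SVMHyper(10, 0.05))
        preds = predict(model, small_features)
        assert set(preds) <= set(model.class_list)

    def test_cyclic_tie_broken_by_decision_values(self):
        """A probe equidistant from all blobs exercises the tie rule."""
        fm = gaussian_blobs()
        model = train_ovo(fm, SVMHyper(10, 0.5))
        probe = np.array([[2.5, 2.5], [1.7, 1.7]])
        preds = predict(model, probe)
        assert all(p in model.class_list for p in preds)

    def test_feature_count_mismatch_rejected(self):
        model = train_ovo(gaussian_blobs(), SVMHyper(10, 0.5))
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 5)))

    def test_invalid_hyper_rejected(self):
        with pytest.raises(ValueError):
            SVMHyper(0, 1.0)
        with pytest.raises(ValueError):
            SVMHyper(10, -1.0)


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self):
        fm = gaussian_blobs()
        hyper, surface = grid_search(fm, c_grid=[7], gamma_grid=[0.3],
                                     inner_folds=3)
        assert hyper == SVMHyper(7, 0.3)
        assert surface.shape == (1, 1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(gaussian_blobs(), c_grid=[], gamma_grid=[0.1])

    def test_shuffled_labels_score_at_chance(self, small_features):
        """Under the label-permutation null the best grid score is chance."""
        rng = np.random.default_rng(0)
        fm = FeatureMatrix(small_features.values,
                           small_features.feature_names,
                           rng.permutation(small_features.labels))
        _, surface = grid_search(fm, c_grid=[10, 100],
                                 gamma_grid=[0.01, 0.1], inner_folds=5,
                                 seed=0)
        n_trials = small_features.n_instances // 2
        half_width = 196.0 * np.sqrt((1 / 3) * (2 / 3) / n_trials)
        assert surface.max() < 100 / 3 + half_width + 5  # max-selection slack

    def test_selected_cell_is_argmax_of_surface(self, small_features):
        hyper, surface = grid_search(small_features, c_grid=[10, 100],
                                     gamma_grid=[0.01, 0.2], inner_folds=3,
                                     seed=1)
        a, b = np.unravel_index(np.argmax(surface), surface.shape)
        assert hyper.c == [10, 100][a]
        assert hyper.gamma == [0.01, 0.2][b]
        assert surface.max() >= surface[a, b] - 1e-12


class TestCrossValidation:
    def test_report_dimensions_and_conservation(self, small_features):
        rep = cross_validate_10x10(small_features, c_grid=[10],
                                   gamma_grid=[0.05], reps=2, folds=5,
                                   inner_folds=3, seed=0)
        assert rep.fold_accuracies.shape == (2, 5)
        assert rep.confusion_counts.sum() == 2 * small_features.n_instances

    def test_identical_seed_identical_report(self, small_features):
        kw = dict(c_grid=[10, 100], gamma_grid=[0.05], reps=2, folds=5,
                  inner_folds=3, seed=7)
        r1 = cross_validate_10x10(small_features, **kw)
        r2 = cross_validate_10x10(small_features, **kw)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)
        assert np.array_equal(r1.confusion_counts, r2.confusion_counts)
        assert r1.selected_hyper == r2.selected_hyper

    def test_trial_grouping_keeps_sibling_windows_together(self,
                                                          small_features):
        from mibci.classify import _make_folds
        folds = _make_folds(small_features.labels, small_features.groups,
                            5, seed=0)
        for tr, te in folds:
            tr_groups = set(small_features.groups[tr])
            te_groups = set(small_features.groups[te])
            assert not (tr_groups & te_groups)

    def test_training_ignores_test_labels(self, small_features):
        """Leakage guard: permuting test-fold labels cannot change models."""
        from mibci.classify import _make_folds
        tr, te = _make_folds(small_features.labels, small_features.groups,
                             5, seed=0)[0]
        fm = small_features
        train_fm = FeatureMatrix(fm.values[tr], fm.feature_names,
                                 fm.labels[tr])
        m1 = train_ovo(train_fm, SVMHyper(10, 0.05))
        # corrupt test labels; retrain from the identical training partition
        corrupted = fm.labels.copy()
        corrupted[te] = np.random.default_rng(0).permutation(corrupted[te])
        train_fm2 = FeatureMatrix(fm.values[tr], fm.feature_names,
                                  corrupted[tr])
        m2 = train_ovo(train_fm2, SVMHyper(10, 0.05))
        assert m1.parameter_digest() == m2.parameter_digest()

    def test_too_few_instances_rejected(self):
        fm = gaussian_blobs(n=5)
        with pytest.raises(ValueError):
            cross_validate_10x10(fm, folds=10)

    def test_report_json_round_trip(self, small_features, tmp_path):
        from mibci import CVReport
        rep = cross_validate_10x10(small_features, c_grid=[10],
                                   gamma_grid=[0.05], reps=1, folds=5,
                                   inner_folds=3, seed=0)
        p = tmp_path / "rep.json"
        rep.to_json(p)
        back = CVReport.from_json(p)
        assert np.array_equal(back.fold_accuracies, rep.fold_accuracies)
        assert back.per_class_accuracy == rep.per_class_accuracy
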