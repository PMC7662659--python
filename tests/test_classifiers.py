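import numpy as np
import pytest

from walnutmir.classifiers import (ClassifierModel, ClassifierSpec,
                                   _rf_votes, fit_bpnn, fit_classifier,
                                   fit_elm, fit_plsda, fit_rbf, fit_rf,
                                   predict, threshold_accept)


def _blobs(seed=0, n_per=10, d=3, sep=4.0, classes=("A", "B")):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, c in enumerate(classes):
        X.append(rng.normal(size=(n_per, d)) + i * sep)
        y += [c] * n_per
    return np.vstack(X), np.array(y, dtype=object)


class TestELM:
    def test_identity_activation_reproduces_least_squares(self):
        rng = np.random.default_rng(0)
        X, y = _blobs(seed=1)
        # p+1 affine hidden units generically span [X, 1], so the
        # pseudoinverse fit equals the least-squares fit on [X, 1]
        m = fit_elm(X, y, n_hidden=X.shape[1] + 1, seed=0,
                    activation="identity")
        Z = np.hstack([X, np.ones((X.shape[0], 1))])
        classes = m.class_labels
        T = np.zeros((len(y), 2))
        for i, l in enumerate(y):
            T[i, classes.index(l)] = 1.0
        ls = Z @ np.linalg.lstsq(Z, T, rcond=None)[0]
        np.testing.assert_allclose(m.decision_values(X), ls, atol=1e-8)

    def test_auto_sweep_separable(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array(["A", "B"], dtype=object)
        m = fit_elm(X, y, n_hidden="auto", seed=0)
        assert list(m.predict(X)) == ["A", "B"]
        assert 1 <= m.spec.parameter <= X.shape[0]

    def test_auto_upper_bound_is_train_size(self):
        X, y = _blobs(seed=2, n_per=6)
        m = fit_elm(X, y, n_hidden="auto", seed=0)
        assert m.spec.parameter <= X.shape[0]
        with pytest.raises(ValueError, match="n_hidden"):
            fit_elm(X, y, n_hidden=X.shape[0] + 1)


class TestRF:
    def test_pure_training_data_fit(self):
        X, y = _blobs(seed=3)
        m = fit_rf(X, y, n_trees=10, seed=0)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_single_tree_reproduces_its_bootstrap_tree(self):
        X, y = _blobs(seed=4, n_per=8)
        m = fit_rf(X, y, n_trees=1, seed=0)
        tree = m.state["trees"][0]
        via_tree = [m.class_labels[int(i)] for i in tree.predict(X)]
        assert list(m.predict(X)) == via_tree

    def test_vote_tally_matches_manual_loop(self):
        X, y = _blobs(seed=5, n_per=4, classes=("A", "B", "C"))
        m = fit_rf(X, y, n_trees=7, seed=2)
        votes = _rf_votes(m, X)
        manual = np.zeros_like(votes)
        for t in m.state["trees"]:
            for i, p in enumerate(t.predict(X).astype(int)):
                manual[i, p] += 1
        np.testing.assert_array_equal(votes, manual)
        assert votes.sum() == 7 * X.shape[0]


class TestRBF:
    def test_all_points_as_centers_interpolates(self):
        X, y = _blobs(seed=6, n_per=5)
        m = fit_rbf(X, y, n_centers=X.shape[0], spread=0.2, seed=0)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_weights_match_least_squares_oracle(self):
        X, y = _blobs(seed=7, n_per=3)
        m = fit_rbf(X, y, n_centers=3, seed=0)
        from walnutmir.classifiers import _rbf_design
        G = _rbf_design(X, m.state["centers"], m.state["spread"])
        Z = np.hstack([G, np.ones((X.shape[0], 1))])
        T = np.zeros((len(y), 2))
        for i, l in enumerate(y):
            T[i, m.class_labels.index(l)] = 1.0
        ref = np.linalg.lstsq(Z, T, rcond=None)[0]
        np.testing.assert_allclose(m.state["Wout"], ref, atol=1e-6)

    def test_parameter_reports_center_count(self):
        X, y = _blobs(seed=8)
        m = fit_rbf(X, y, n_centers=4, seed=0)
        assert m.spec.parameter == 4


class TestPLSDA:
    def test_one_hot_inputs_perfectly_classified(self):
        labels = np.array(["a", "b", "c", "a", "b", "c"], dtype=object)
        X = np.zeros((6, 3))
        for i, l in enumerate(labels):
            X[i, ["a", "b", "c"].index(l)] = 1.0
        m = fit_plsda(X, labels, n_LV=2)
        assert np.mean(m.predict(X) == labels) == 1.0

    def test_threshold_rule_two_class(self):
        assert threshold_accept(np.array([[0.49]]), np.array([[0.0]]))[0, 0]
        assert not threshold_accept(np.array([[0.51]]), np.array([[0.0]]))[0, 0]

    def test_argmax_agrees_when_one_column_passes(self):
        # sweep a grid of 3-class prediction vectors for one-hot target e_k:
        # whenever exactly one column passes the 0.5 rule, argmax agrees
        grid = np.linspace(-0.2, 1.2, 8)
        for k in range(3):
            t = np.zeros(3)
            t[k] = 1.0
            for a in grid:
                for b in grid:
                    for c in grid:
                        yhat = np.array([a, b, c])
                        acc = threshold_accept(yhat[None], t[None])[0]
                        if acc.sum() == 3:  # all columns consistent
                            passing = np.nonzero(
                                np.abs(yhat - 1.0) < 0.5)[0]
                            if passing.size == 1:
                                assert np.argmax(yhat) == passing[0]

    def test_relabeling_invariance(self):
        X, y = _blobs(seed=9, n_per=6, classes=("A", "B", "C"))
        m = fit_plsda(X, y, n_LV=2)
        swapped = np.array(
            [{"A": "C", "B": "B", "C": "A"}[l] for l in y], dtype=object)
        m2 = fit_plsda(X, swapped, n_LV=2)
        pred1 = m.predict(X)
        pred2 = m2.predict(X)
        assert all({"A": "C", "B": "B", "C": "A"}[p1] == p2
                   for p1, p2 in zip(pred1, pred2))


class TestBPNN:
    def test_epochs_zero_reproducible(self):
        X, y = _blobs(seed=10)
        m1 = fit_bpnn(X, y, n_hidden=5, epochs=0, seed=3)
        m2 = fit_bpnn(X, y, n_hidden=5, epochs=0, seed=3)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
        np.testing.assert_array_equal(m1.state["W1"], m2.state["W1"])

    def test_separable_blobs_learned(self):
        X, y = _blobs(seed=11, n_per=10, d=2, sep=5.0)
        m = fit_bpnn(X, y, n_hidden=8, seed=0)
        assert np.mean(m.predict(X) == y) == 1.0


class TestContract:
    def test_permutation_equivariance(self, easy_task):
        tr, sel = easy_task["train"], easy_task["selected"]
        X = tr.absorbance[:, sel]
        m = fit_classifier(X, tr.origin, ClassifierSpec("PLSDA", 3))
        perm = np.random.default_rng(0).permutation(X.shape[0])
        np.testing.assert_array_equal(m.predict(X)[perm], m.predict(X[perm]))

    def test_dimension_mismatch_raises(self):
        X, y = _blobs(seed=12)
        m = fit_classifier(X, y, ClassifierSpec("ELM", 5, seed=0))
        with pytest.raises(ValueError, match="variables"):
            m.predict(np.zeros((2, X.shape[1] + 1)))

    @pytest.mark.parametrize("kind,par", [("ELM", 10), ("RF", 15),
                                          ("RBF", 6), ("BPNN", 6)])
    def test_seeded_refit_reproducible(self, kind, par):
        X, y = _blobs(seed=13, n_per=8, classes=("A", "B", "C"))
        m1 = fit_classifier(X, y, ClassifierSpec(kind, par, seed=7))
        m2 = fit_classifier(X, y, ClassifierSpec(kind, par, seed=7))
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_predictions_stay_in_label_set(self, easy_task):
        tr, te, sel = (easy_task["train"], easy_task["test"],
                       easy_task["selected"])
        m = fit_classifier(tr.absorbance[:, sel], tr.origin,
                           ClassifierSpec("RF", 20, seed=0))
        assert set(m.predict(te.absorbance[:, sel])) <= set(m.class_labels)

    def test_json_round_trip_and_rf_refusal(self, tmp_path):
        X, y = _blobs(seed=14)
        m = fit_classifier(X, y, ClassifierSpec("BPNN", 4, seed=0))
        f = tmp_path / "m.json"
        m.to_json(f)
        back = ClassifierModel.from_json(f)
        np.testing.assert_array_equal(back.predict(X), m.predict(X))
        rf = fit_classifier(X, y, ClassifierSpec("RF", 5, seed=0))
        with pytest.raises(NotImplementedError, match="joblib"):
            rf.to_json(tmp_path / "rf.json")

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ClassifierSpec("SVM", 10)
        with pytest.raises(ValueError, match="parameter"):
            ClassifierSpec("ELM", 0)
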