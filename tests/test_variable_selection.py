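import itertools

import numpy as np
import pytest

from walnutmir.pls_core import _cv_press, make_folds
from walnutmir.variable_selection import (GAPLSConfig, _chain, _windows,
                                          ga_pls_select, selection_frame,
                                          spa_select, uve_select, uve_spa)


class TestUVE:
    def test_planted_column_retained(self):
        rng = np.random.default_rng(0)
        n = 30
        y = rng.normal(size=n)
        X = np.column_stack([y] + [rng.normal(size=n) for _ in range(49)])
        res = uve_select(X, y, pls_factor=5, n_artificial=50, seed=1)
        assert 0 in res.retained_index
        assert res.cutoff_lo == -res.cutoff_hi <= 0

    def test_all_informative_columns_retained(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=25)
        X = np.column_stack([y * s for s in (1.0, -2.0, 0.5, 3.0)])
        X = X + rng.normal(size=X.shape) * 1e-6
        res = uve_select(X, y, pls_factor=2, n_artificial=10, seed=0)
        assert set(res.retained_index) == {0, 1, 2, 3}

    def test_cutoff_monotone_in_artificial_prefix(self):
        """max|stability| over a superset of noise columns never shrinks."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=20)
        X = np.column_stack([y, rng.normal(size=(20, 9)).T[0]] +
                            [rng.normal(size=20) for _ in range(8)])
        res = uve_select(X, y, pls_factor=3, n_artificial=40, seed=0)
        art = np.abs(res.stability[X.shape[1]:])
        cuts = np.maximum.accumulate(np.maximum.accumulate(art))
        assert np.all(np.diff(cuts) >= 0)
        assert res.cutoff_hi == pytest.approx(art.max())

    def test_retained_are_real_indices(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 8))
        y = X[:, 0] + rng.normal(size=15) * 0.1
        res = uve_select(X, y, pls_factor=3, seed=0)
        assert np.all(res.retained_index < 8)


class TestSPA:
    def test_hand_computed_projection_chain(self):
        # starting from v1, the residual of v2 has norm 0.1 and of v3 norm
        # 1.0, so the chain picks v3
        X = np.array([[1.0, 0.9, 0.0],
                      [0.0, 0.1, 0.0],
                      [0.0, 0.0, 1.0]])
        assert _chain(X, 0, 2) == [0, 2]

    def test_orthonormal_columns_selected_in_norm_order(self):
        # scaled orthogonal columns: projections never interact, so the
        # chain adds them by decreasing norm
        X = np.diag([1.0, 3.0, 2.0])
        assert _chain(X, 1, 3) == [1, 2, 0]

    def test_selected_columns_linearly_independent(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(30, 4))
        # heavily collinear pool: noisy copies of 4 base directions
        X = np.hstack([base + rng.normal(size=base.shape) * 0.01
                       for _ in range(5)])
        y = base @ rng.normal(size=4)
        res = spa_select(X, y, k_min=2, k_max=4)
        sub = X[:, res.selected_index]
        assert np.linalg.matrix_rank(sub) == sub.shape[1]
        # better conditioned than a random subset of the same size
        rnd = rng.choice(X.shape[1], size=sub.shape[1], replace=False)
        assert (np.linalg.cond(sub.T @ sub)
                < np.linalg.cond(X[:, rnd].T @ X[:, rnd]))

    def test_subset_size_within_range(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 30))
        y = X[:, :3] @ np.array([1.0, -1.0, 0.5]) + rng.normal(size=40) * 0.1
        res = spa_select(X, y, k_min=5, k_max=12)
        assert 5 <= res.selected_index.size <= 12
        assert res.rmse_by_k.size == 8

    def test_infeasible_k_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="k_min"):
            spa_select(X, X[:, 0], k_min=5, k_max=30)


class TestUveSpa:
    def test_uve_retaining_all_equals_plain_spa(self):
        rng = np.random.default_rng(7)
        t = rng.normal(size=25)
        # every column carries the signal direction -> UVE keeps all
        X = np.column_stack([t * s + rng.normal(size=25) * 1e-3
                             for s in (1.0, -1.5, 2.0, 0.7, -0.9, 1.2)])
        y = t
        res = uve_spa(X, y, uve_cfg={"pls_factor": 2, "seed": 0},
                      spa_cfg={"k_min": 2, "k_max": 4})
        assert set(res.uve.retained_index) == set(range(6))
        plain = spa_select(X, y, k_min=2, k_max=4)
        np.testing.assert_array_equal(res.selected_index,
                                      plain.selected_index)

    def test_too_few_retained_raises(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="retained only"):
            uve_spa(X, y, uve_cfg={"pls_factor": 3, "seed": 0,
                                   "n_artificial": 200},
                    spa_cfg={"k_min": 8, "k_max": 9})


def _small_cfg(**kw):
    base = dict(n_runs=5, n_evaluations=300, a_max=5, seed=0, trace_len=20,
                population=30)
    base.update(kw)
    return GAPLSConfig(**base)


class TestGAPLS:
    def test_single_variable_always_selected(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(20, 1))
        y = x[:, 0] * 2 + rng.normal(size=20) * 0.1
        res = ga_pls_select(x, y, _small_cfg(trace_len=1))
        # the lone gene sits in every chromosome of every final population
        assert res.gene_frequency[0] == pytest.approx(30.0)
        np.testing.assert_array_equal(res.selected_index, [0])

    def test_planted_pair_ranks_top_two(self):
        rng = np.random.default_rng(10)
        n, p = 40, 20
        X = rng.normal(size=(n, p))
        y = 2.0 * X[:, 3] + 1.5 * X[:, 7] + rng.normal(size=n) * 0.1
        res = ga_pls_select(X, y, _small_cfg(n_runs=10, n_evaluations=500))
        top2 = set(np.argsort(-res.frequency)[:2])
        assert top2 == {3, 7}
        # brute force: {3, 7} is the best 2-variable subset by RMSECV
        folds = make_folds(n, ("k_fold", 5))
        def rmsecv(cols):
            press = _cv_press(X[:, list(cols)], y[:, None],
                              min(5, len(cols)), folds)
            return float(np.sqrt(press.min() / n))
        best_pair = min(itertools.combinations(range(p), 2), key=rmsecv)
        assert set(best_pair) == {3, 7}

    def test_informative_frequency_dominates_across_seeds(self):
        """Sign test: informative variables out-rank noise in every seed."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(30, 15))
            y = 1.8 * X[:, 2] + 1.2 * X[:, 11] + rng.normal(size=30) * 0.15
            res = ga_pls_select(X, y, _small_cfg(
                seed=seed, n_runs=3, n_evaluations=200, trace_len=15))
            info = res.frequency[[2, 11]].mean()
            noise = np.delete(res.frequency, [2, 11]).mean()
            wins += int(info > noise)
        assert wins == 10

    def test_near_exhaustive_on_small_instance(self):
        rng = np.random.default_rng(12)
        n, p = 30, 10
        X = rng.normal(size=(n, p))
        y = X[:, 1] - 2.0 * X[:, 6] + rng.normal(size=n) * 0.2
        folds = make_folds(n, ("k_fold", 5))
        def rmsecv(cols):
            press = _cv_press(X[:, list(cols)], y[:, None],
                              min(5, len(cols)), folds)
            return float(np.sqrt(press.min() / n))
        exhaustive = min(
            rmsecv(c) for k in range(1, p + 1)
            for c in itertools.combinations(range(p), k))
        res = ga_pls_select(X, y, _small_cfg(trace_len=10))
        assert res.best_rmsecv <= 1.05 * exhaustive

    def test_window_averaging_maps_back(self):
        members = _windows(1000, 500)
        assert len(members) <= 500
        covered = np.concatenate(members)
        np.testing.assert_array_equal(np.sort(covered), np.arange(1000))
        rng = np.random.default_rng(13)
        X = rng.normal(size=(25, 1000))
        y = X[:, 100] + rng.normal(size=25) * 0.2
        res = ga_pls_select(X, y, _small_cfg(
            n_runs=2, n_evaluations=120, trace_len=5))
        # frequency is constant within a window
        for m in res.gene_members:
            assert np.unique(res.frequency[m]).size == 1

    def test_trace_and_marks_consistent(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 12))
        y = X[:, 0] + rng.normal(size=30) * 0.3
        res = ga_pls_select(X, y, _small_cfg(trace_len=12))
        g, b, s = (res.model_marks[k] for k in ("global", "better",
                                                "suggested"))
        assert res.rmsecv_trace.argmin() + 1 == g
        assert b <= g and s <= g
        assert res.rmsecv_trace[b - 1] <= 1.02 * res.rmsecv_trace[g - 1]

    def test_selection_frame_export(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(20, 6))
        y = X[:, 0] + rng.normal(size=20) * 0.1
        res = ga_pls_select(X, y, _small_cfg(n_runs=2, n_evaluations=120,
                                             trace_len=6))
        df = selection_frame(res, np.arange(6.0) + 700)
        assert list(df.columns) == ["wavenumber", "frequency", "selected"]
        assert df["selected"].sum() == res.selected_index.size
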