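"""Parameter grids, CV loss and kernel-smoothed selection."""

import numpy as np
import pytest

from metabobench.simple import fit_predict_nb
from metabobench.tuning import (
    GridAxis,
    ParameterGrid,
    cv_loss,
    smooth_and_select,
    table4_grid,
    tune,
)


class TestGrids:
    def test_pls_component_grids(self):
        for name in ("PLS-DA", "sPLS-DA"):
            g = table4_grid(name)
            comps = next(a for a in g.axes if a.name == "n_components")
            assert comps.values == tuple(range(1, 16))

    def test_spls_lambda_grid(self):
        g = table4_grid("sPLS-DA")
        lam = next(a for a in g.axes if a.name == "sparsity")
        assert np.allclose(lam.values, np.arange(0.1, 0.95, 0.1))
        assert len(g.points) == 15 * 9

    @pytest.mark.parametrize(
        "post,lo,hi", [(False, 1e-5, 1e-1), (True, 1e-2, 1.0)]
    )
    def test_svm_gamma_grid_log_spaced(self, post, lo, hi):
        g = table4_grid("SVM", post_filter=post)
        gammas = np.array([pt["gamma"] for pt in g.points])
        assert len(gammas) == 1000
        assert gammas[0] == pytest.approx(lo, rel=1e-9)
        assert gammas[-1] == pytest.approx(hi, rel=1e-9)
        ratios = np.diff(np.log10(gammas))
        assert np.allclose(ratios, ratios[0])

    def test_rf_mtry_grid_spans_5_to_p(self):
        g = table4_grid("RF", n_metabolites=1000)
        vals = [pt["mtry"] for pt in g.points]
        assert len(vals) == 25 and vals[0] == 5 and vals[-1] == 1000

    def test_knn_grid(self):
        g = table4_grid("k-NN")
        assert [pt["k"] for pt in g.points] == list(range(1, 21))

    def test_nnet_grid(self):
        g = table4_grid("NNet")
        layers = {pt["n_hidden_layers"] for pt in g.points}
        nodes = sorted({pt["nodes_per_layer"] for pt in g.points})
        assert layers == {1, 2}
        assert nodes == list(range(15, 101, 5))

    def test_subsampling_caps_grid(self):
        g = table4_grid("SVM", max_points=25)
        assert len(g.points) <= 25
        full = {pt["gamma"] for pt in table4_grid("SVM").points}
        assert {pt["gamma"] for pt in g.points} <= full


class TestCVLoss:
    def test_oracle_classifier_has_zero_loss(self, rng):
        def perfect(X_tr, y_tr, X_te, seed=0):
            # cheats by construction: class is encoded in the first column
            P = np.zeros((len(X_te), 3))
            P[np.arange(len(X_te)), X_te[:, 0].astype(int)] = 1.0
            return P

        y = np.tile([0, 1, 2], 10)
        X = np.column_stack([y.astype(float), rng.standard_normal(30)])
        assert cv_loss(perfect, X, y, {}, n_folds=5, fold_seed=1) == 0.0

    def test_uniform_classifier_loses_ln3(self, rng):
        def uniform(X_tr, y_tr, X_te, seed=0):
            return np.full((len(X_te), 3), 1.0 / 3.0)

        y = np.tile([0, 1, 2], 10)
        X = rng.standard_normal((30, 4))
        assert cv_loss(uniform, X, y, {}, n_folds=5, fold_seed=1) == pytest.approx(
            np.log(3.0), abs=1e-12
        )

    def test_cv_estimate_near_holdout_oracle(self, rng):
        """5-fold CV cross-entropy of NB is close to an independent
        large-hold-out estimate on the same generating process."""
        def gen(n):
            y = rng.integers(0, 3, n)
            X = rng.standard_normal((n, 4)) + 1.2 * np.eye(4)[:3][y][:, :4]
            return X, y

        X, y = gen(120)
        cv = cv_loss(
            lambda Xa, ya, Xb, seed=0: fit_predict_nb(Xa, ya, Xb),
            X, y, {}, n_folds=5, fold_seed=3,
        )
        Xh, yh = gen(4000)
        from metabobench.evaluation import cross_entropy

        holdout = cross_entropy(yh, fit_predict_nb(X, y, Xh))
        assert cv == pytest.approx(holdout, abs=0.35)


class TestSmoothing:
    def _grid_1d(self, values, scale="linear"):
        return ParameterGrid(
            "toy",
            axes=(GridAxis("x", tuple(values), scale),),
            points=tuple({"x": v} for v in values),
        )

    def test_hand_computed_nadaraya_watson(self):
        """3 points, losses (1,0,1), unit spacing, bandwidth 1.5: the
        middle point stays the smoothed minimum."""
        g = self._grid_1d([0.0, 1.0, 2.0])
        res = smooth_and_select(g, np.array([1.0, 0.0, 1.0]))
        w1 = np.exp(-0.5 * (1.0 / 1.5) ** 2)
        w2 = np.exp(-0.5 * (2.0 / 1.5) ** 2)
        expected_mid = (w1 * 1.0 + 1.0 * 0.0 + w1 * 1.0) / (1.0 + 2 * w1)
        expected_edge = (1.0 + w1 * 0.0 + w2 * 1.0) / (1.0 + w1 + w2)
        assert res.smoothed_losses[1] == pytest.approx(expected_mid, abs=1e-12)
        assert res.smoothed_losses[0] == pytest.approx(expected_edge, abs=1e-12)
        assert res.selected == {"x": 1.0}

    def test_constant_surface_selects_smallest_point(self):
        g = table4_grid("sPLS-DA", max_points=20)
        res = smooth_and_select(g, np.ones(len(g.points)))
        assert res.selected == dict(g.points[0])
        assert res.selected["n_components"] == min(
            pt["n_components"] for pt in g.points
        )

    def test_singleton_grid(self):
        g = self._grid_1d([3.0])
        res = smooth_and_select(g, np.array([0.42]))
        assert res.selected == {"x": 3.0}

    def test_smoothing_preserves_loss_range(self, rng):
        g = self._grid_1d(np.logspace(-3, 0, 12), scale="log")
        raw = rng.uniform(0.2, 2.0, 12)
        res = smooth_and_select(g, raw)
        assert res.smoothed_losses.min() >= raw.min() - 1e-12
        assert res.smoothed_losses.max() <= raw.max() + 1e-12

    def test_selected_point_always_on_grid(self, rng):
        g = table4_grid("NNet", max_points=25)
        raw = rng.uniform(0, 3, len(g.points))
        res = smooth_and_select(g, raw)
        assert res.selected in [dict(pt) for pt in g.points]


def test_tuning_deterministic_for_deterministic_classifier(toy_multiclass):
    from metabobench.tuning import TECHNIQUES

    X, y = toy_multiclass
    g = table4_grid("k-NN")
    a = tune(TECHNIQUES["k-NN"], g, X, y, rng=np.random.default_rng(9))
    b = tune(TECHNIQUES["k-NN"], g, X, y, rng=np.random.default_rng(9))
    assert a.selected == b.selected
    assert np.allclose(a.raw_losses, b.raw_losses)
    assert a.selected in [dict(pt) for pt in g.points]
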