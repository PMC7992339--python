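"""Late integration, network forward/loss/training, CV and Bayesian tuning."""

import numpy as np
import pandas as pd
import pytest

from lateomics.nets import (
    NetArchitecture,
    TrainedNet,
    _loss_and_grad,
    bayesopt_minimize,
    bayesopt_tune,
    cross_validate,
    forward,
    init_params,
    late_integrate,
    penalized_loss,
    train_network,
)
from lateomics.omics_io import MultiOmicsDataset, OmicsMatrix


def _dataset(rng, n=6, p=4, layers=("mrna", "cnv", "protein"), clinical=True):
    ids = [f"S{i}" for i in range(n)]
    built = {}
    for name in layers:
        vals = rng.standard_normal((n, p))
        if name == "cnv":
            vals = np.tanh(vals)
        built[name] = OmicsMatrix(
            pd.DataFrame(vals, index=ids, columns=[f"{name}{j}" for j in range(p)]), name
        )
    clin = None
    if clinical:
        clin = pd.DataFrame(
            {"age": rng.normal(60, 5, n), "stage": rng.choice(["I", "II"], n)}, index=ids
        )
    return MultiOmicsDataset(layers=built, clinical=clin)


class TestLateIntegrate:
    def test_three_equal_blocks_give_m_by_3n(self, rng):
        ds = _dataset(rng, n=5, p=4, clinical=False)
        out = late_integrate(ds, {name: [0, 1, 2, 3] for name in ds.layers})
        assert out.shape == (5, 12)

    def test_clinical_only(self, rng):
        ds = _dataset(rng)
        out = late_integrate(ds, {}, {"numeric": ["age"]})
        assert list(out.columns) == ["clinical:age"]
        assert np.allclose(out["clinical:age"], ds.clinical["age"])

    def test_columns_copied_verbatim(self, rng):
        ds = _dataset(rng)
        sel = {"mrna": [2, 0], "cnv": [1]}
        out = late_integrate(ds, sel, {"categorical": ["stage"]})
        assert np.array_equal(out["mrna:mrna2"], ds.layers["mrna"].values.iloc[:, 2])
        assert np.array_equal(out["mrna:mrna0"], ds.layers["mrna"].values.iloc[:, 0])
        assert np.array_equal(out["cnv:cnv1"], ds.layers["cnv"].values.iloc[:, 1])
        onehot = [c for c in out.columns if c.startswith("clinical:stage")]
        assert (out[onehot].sum(axis=1) == 1).all()

    def test_unknown_clinical_column_rejected(self, rng):
        ds = _dataset(rng)
        with pytest.raises(ValueError, match="'bmi'"):
            late_integrate(ds, {}, {"numeric": ["bmi"]})


class TestForward:
    def test_zero_weights_classifier_is_uniform(self, rng):
        arch = NetArchitecture(n_inputs=3, hidden_layers=[4], output="classifier")
        net = TrainedNet(architecture=arch, params=np.zeros(arch.n_params))
        out = forward(net, rng.standard_normal((5, 3)))
        assert np.allclose(out, 0.5)

    def test_zero_weights_regressor_returns_bias(self, rng):
        arch = NetArchitecture(n_inputs=3, hidden_layers=[4], output="regressor", n_outputs=2)
        theta = np.zeros(arch.n_params)
        theta[-2:] = [1.5, -0.5]  # output-layer bias
        net = TrainedNet(architecture=arch, params=theta)
        out = forward(net, rng.standard_normal((4, 3)))
        assert np.allclose(out, [1.5, -0.5])

    def test_matches_independent_matrix_evaluation(self, rng):
        arch = NetArchitecture(n_inputs=3, hidden_layers=[4, 5], output="regressor", n_outputs=2)
        theta = rng.standard_normal(arch.n_params)
        net = TrainedNet(architecture=arch, params=theta)
        X = rng.standard_normal((6, 3))
        # independent evaluation via direct slicing
        pos = 0
        Ws, bs = [], []
        for din, dout in arch.layer_dims():
            Ws.append(theta[pos : pos + din * dout].reshape(din, dout)); pos += din * dout
            bs.append(theta[pos : pos + dout]); pos += dout
        a = np.tanh(X @ Ws[0] + bs[0])
        a = np.tanh(a @ Ws[1] + bs[1])
        expected = a @ Ws[2] + bs[2]
        assert np.allclose(forward(net, X), expected)

    def test_shape_mismatch_rejected(self, rng):
        arch = NetArchitecture(n_inputs=3, hidden_layers=[2])
        net = TrainedNet(architecture=arch, params=np.zeros(arch.n_params))
        with pytest.raises(ValueError, match="expects 3"):
            forward(net, rng.standard_normal((2, 5)))


class TestPenalizedLoss:
    def test_uniform_classifier_gives_ln2(self, rng):
        arch = NetArchitecture(n_inputs=2, hidden_layers=[3], output="classifier", gamma=0.0)
        theta = np.zeros(arch.n_params)
        X = rng.standard_normal((7, 2))
        y = rng.integers(0, 2, 7)
        assert penalized_loss(theta, X, y, arch) == pytest.approx(np.log(2))

    def test_gamma_one_is_pure_penalty(self, rng):
        arch = NetArchitecture(n_inputs=2, hidden_layers=[3], output="regressor", n_outputs=1, gamma=1.0)
        theta = rng.standard_normal(arch.n_params)
        loss = penalized_loss(theta, rng.standard_normal((5, 2)), rng.standard_normal((5, 1)), arch)
        assert loss == pytest.approx(np.mean(theta**2))

    def test_missing_targets_excluded(self, rng):
        arch = NetArchitecture(n_inputs=2, hidden_layers=[2], output="regressor", n_outputs=2, gamma=0.0)
        theta = np.zeros(arch.n_params)
        T = np.array([[1.0, np.nan], [np.nan, 2.0], [3.0, 1.0]])
        loss = penalized_loss(theta, rng.standard_normal((3, 2)), T, arch)
        assert loss == pytest.approx(np.nanmean(T**2))  # prediction is 0 everywhere

    @pytest.mark.parametrize("output,n_out", [("classifier", 2), ("regressor", 3)])
    def test_gradient_matches_finite_differences(self, rng, output, n_out):
        arch = NetArchitecture(n_inputs=3, hidden_layers=[4], output=output, n_outputs=n_out, gamma=0.3)
        theta = 0.5 * rng.standard_normal(arch.n_params)
        X = rng.standard_normal((6, 3))
        T = rng.integers(0, 2, 6) if output == "classifier" else rng.standard_normal((6, n_out))
        T = np.asarray(T, dtype=float)
        _, g = _loss_and_grad(theta, X, T, arch)
        h = 1e-6
        for i in rng.choice(arch.n_params, 10, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h; tm[i] -= h
            fd = (penalized_loss(tp, X, T, arch) - penalized_loss(tm, X, T, arch)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestTrainNetwork:
    def test_separable_classes_learned(self, rng):
        X = rng.standard_normal((200, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        arch = NetArchitecture(n_inputs=2, hidden_layers=[7, 7], output="classifier", gamma=0.01)
        net = train_network(X, y, arch, seed=0)
        assert np.mean(net.predict(X) == y) >= 0.99

    def test_noiseless_linear_regression_learned_by_lm(self, rng):
        X = rng.standard_normal((80, 3))
        Y = X @ np.array([[1.0], [-2.0], [0.5]])
        arch = NetArchitecture(n_inputs=3, hidden_layers=[11, 11], output="regressor", n_outputs=1, gamma=0.001)
        net = train_network(X, Y, arch, seed=0)
        assert net.report["optimizer"] == "lm"
        pred = forward(net, X)
        ss_res = np.sum((pred - Y) ** 2)
        ss_tot = np.sum((Y - Y.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.99

    def test_pure_penalty_shrinks_weights(self, rng):
        X = rng.standard_normal((40, 2))
        y = rng.integers(0, 2, 40)
        arch = NetArchitecture(n_inputs=2, hidden_layers=[3], output="classifier", gamma=1.0)
        net = train_network(X, y, arch, seed=0)
        assert np.abs(net.params).max() < 0.05

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((50, 3))
        y = (X[:, 0] > 0).astype(int)
        arch = NetArchitecture(n_inputs=3, hidden_layers=[5], output="classifier")
        a = train_network(X, y, arch, seed=4)
        b = train_network(X, y, arch, seed=4)
        assert np.array_equal(a.params, b.params)

    def test_large_net_falls_back_to_cg(self, rng):
        X = rng.standard_normal((30, 40))
        Y = rng.standard_normal((30, 20))
        arch = NetArchitecture(n_inputs=40, hidden_layers=[11, 11], output="regressor", n_outputs=20)
        net = train_network(X, Y, arch, optimizer="lm", seed=0, max_rounds=2)
        assert net.report["optimizer"] == "scg"
        assert net.report["requested_optimizer"] == "lm"


class TestCrossValidate:
    def test_loo_partition_each_sample_once(self, rng):
        X = rng.standard_normal((10, 2))
        Y = rng.standard_normal((10, 1))
        arch = NetArchitecture(n_inputs=2, hidden_layers=[2], output="regressor", n_outputs=1)
        rep = cross_validate(X, Y, arch, n_folds=10, seed=0, max_rounds=1)
        assert sorted(rep.fold_assignments) == list(range(10))

    def test_fold_assignments_reproducible(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.integers(0, 2, 30).astype(float)
        arch = NetArchitecture(n_inputs=2, hidden_layers=[2], output="classifier")
        a = cross_validate(X, y, arch, n_folds=3, seed=9, max_rounds=1)
        b = cross_validate(X, y, arch, n_folds=3, seed=9, max_rounds=1)
        assert np.array_equal(a.fold_assignments, b.fold_assignments)

    def test_single_class_fold_rejected(self, rng):
        X = rng.standard_normal((6, 2))
        y = np.array([0, 0, 0, 0, 0, 1], dtype=float)
        arch = NetArchitecture(n_inputs=2, hidden_layers=[2], output="classifier")
        with pytest.raises(ValueError, match="single class|fewer folds|least populated"):
            cross_validate(X, y, arch, n_folds=3, seed=0, max_rounds=1)


class TestBayesopt:
    def test_quadratic_optimum_found_every_seed(self):
        for seed in range(5):
            best, trace = bayesopt_minimize(
                lambda p: (p["gamma"] - 0.3) ** 2, {"gamma": ("float", 0.0, 1.0)},
                n_iter=25, seed=seed,
            )
            assert abs(best["gamma"] - 0.3) < 0.1, f"seed {seed}"
            assert len(trace) == 25

    def test_discrete_grid_is_enumerated(self):
        scores = {0: 3.0, 1: 1.0, 2: 0.5, 3: 2.0}
        best, trace = bayesopt_minimize(
            lambda p: scores[p["hidden_nodes"]], {"hidden_nodes": ("int", 0, 3)},
            n_iter=4, seed=0, n_init=4,
        )
        assert best["hidden_nodes"] == 2
        assert sorted(t[0]["hidden_nodes"] for t in trace) == [0, 1, 2, 3]

    def test_constant_objective_runs_full_trace(self):
        _, trace = bayesopt_minimize(lambda p: 1.0, {"x": ("float", 0, 1)}, n_iter=8, seed=1)
        assert len(trace) == 8

    def test_incumbent_score_non_increasing(self):
        _, trace = bayesopt_minimize(
            lambda p: np.sin(5 * p["x"]) + p["x"] ** 2, {"x": ("float", 0, 1)}, n_iter=15, seed=2
        )
        scores = [s for _, s in trace]
        incumbents = np.minimum.accumulate(scores)
        assert all(b <= a + 1e-12 for a, b in zip(incumbents, incumbents[1:]))

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError, match="initial design"):
            bayesopt_minimize(lambda p: 0.0, {"x": ("float", 0, 1)}, n_iter=3, seed=0, n_init=5)

    def test_tune_rejects_unknown_hyperparameter(self, rng):
        with pytest.raises(ValueError, match="unknown hyperparameters"):
            bayesopt_tune(
                rng.standard_normal((10, 2)), rng.integers(0, 2, 10).astype(float),
                {"dropout": ("float", 0, 1)}, n_iter=5, n_folds=2,
            )
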