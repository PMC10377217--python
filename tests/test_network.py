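"""Network architecture, Jacobian, LM/Bayesian-regularization training."""

import dataclasses

import numpy as np
import pytest

from lbpanomaly.errors import ValidationError
from lbpanomaly.network import (FEATURE_COLUMNS, NetworkParams, TrainConfig,
                                build_feature_matrix, forward, init_network,
                                jacobian, load_model, save_model,
                                split_train_test, train)


class TestFeatureMatrix:
    def test_standardization(self, small_cohort, small_scores):
        fm = build_feature_matrix(small_cohort, small_scores)
        assert fm.values.shape == (len(small_cohort), 10)
        assert fm.columns == FEATURE_COLUMNS
        nonconst = fm.sd > 0
        assert np.all(np.abs(fm.values.mean(axis=0)[nonconst]) < 1e-9)
        assert np.allclose(fm.values.std(axis=0)[nonconst], 1.0)

    def test_destandardize_round_trip(self, small_cohort, small_scores):
        fm = build_feature_matrix(small_cohort, small_scores)
        raw = fm.destandardize(fm.values)
        again = (raw - fm.mean) / np.where(fm.sd == 0, 1.0, fm.sd)
        assert np.allclose(again[:, fm.sd > 0],
                           fm.values[:, fm.sd > 0], atol=1e-10)

    def test_identical_subjects_standardize_to_zero(self, small_cohort,
                                                    small_scores):
        one = small_cohort.iloc[[0] * 12].copy()
        one["id"] = range(1, 13)
        sc = small_scores.iloc[[0] * 12].copy()
        sc["id"] = range(1, 13)
        fm = build_feature_matrix(one, sc)
        assert np.all(fm.values == 0.0)
        assert np.all(fm.sd == 0.0)

    def test_missing_score_errors(self, small_cohort, small_scores):
        with pytest.raises(ValidationError):
            build_feature_matrix(small_cohort, small_scores.iloc[:-5])


class TestInitAndForward:
    def test_weight_count(self):
        p = init_network(10, 10, seed=0)
        assert p.n_weights == 850  # 10*20+20 + 20*20+20 + 10*20+10

    def test_init_deterministic(self):
        a = init_network(10, 10, seed=4).to_vector()
        b = init_network(10, 10, seed=4).to_vector()
        c = init_network(10, 10, seed=5).to_vector()
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_vector_round_trip(self):
        p = init_network(7, 3, seed=1)
        q = NetworkParams.from_vector(p.to_vector(), 7, 3)
        assert np.array_equal(p.W2, q.W2) and np.array_equal(p.b3, q.b3)

    def test_zero_params_zero_output(self):
        p = init_network(4, 2, seed=0)
        z = NetworkParams.from_vector(np.zeros(p.n_weights), 4, 2)
        out = forward(z, np.random.default_rng(0).normal(size=(5, 4)))
        assert np.allclose(out, 0.0)

    def test_saturating_inputs_stay_finite(self):
        p = init_network(3, 2, seed=2)
        out = forward(p, np.array([[1e6, -1e6, 1e6], [-1e6, 1e6, -1e6]]))
        assert np.all(np.isfinite(out))

    def test_shape_mismatch(self):
        p = init_network(3, 2, seed=0)
        with pytest.raises(ValidationError):
            forward(p, np.zeros((4, 5)))


class TestJacobian:
    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(0)
        p = init_network(4, 3, seed=2)
        X = rng.standard_normal((3, 4))
        w = p.to_vector()
        J = jacobian(p, X)
        eps = 1e-6
        fd = np.empty_like(J)
        for i in range(w.size):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            yp = forward(NetworkParams.from_vector(wp, 4, 3), X)
            ym = forward(NetworkParams.from_vector(wm, 4, 3), X)
            fd[:, i] = ((yp - ym) / (2 * eps)).ravel()
        scale = max(1.0, np.abs(fd).max())
        assert np.abs(J - fd).max() / scale < 1e-5


class TestSplit:
    def test_sizes(self):
        tr, te = split_train_test(10, 0.8, seed=0)
        assert len(tr) == 8 and len(te) == 2

    def test_partition(self):
        tr, te = split_train_test(101, 0.8, seed=3)
        assert sorted(np.concatenate([tr, te])) == list(range(101))
        assert set(tr).isdisjoint(te)

    def test_seeded(self):
        assert np.array_equal(split_train_test(50, 0.8, 9)[0],
                              split_train_test(50, 0.8, 9)[0])

    def test_invalid(self):
        with pytest.raises(ValidationError):
            split_train_test(1, 0.8, 0)
        with pytest.raises(ValidationError):
            split_train_test(10, 1.0, 0)


class TestTraining:
    def test_identity_line_reaches_near_machine_fit(self):
        x = np.linspace(-1, 1, 20).reshape(-1, 1)
        _, rep = train(x, TrainConfig(seed=0, mse_goal=1e-6,
                                      max_epochs=300))
        assert rep.final_mse <= 1e-4

    def test_gamma_bounded_every_epoch(self):
        x = np.linspace(-1, 1, 20).reshape(-1, 1)
        _, rep = train(x, TrainConfig(seed=0, mse_goal=1e-6,
                                      max_epochs=100))
        nw = 481  # 20+20 + 400+20 + 20+1
        assert all(0.0 <= g <= nw for g in rep.gamma_trace)

    def test_objective_decreases_within_each_accepted_step(self):
        x = np.linspace(-1, 1, 20).reshape(-1, 1)
        _, rep = train(x, TrainConfig(seed=1, mse_goal=1e-8,
                                      max_epochs=100))
        assert len(rep.f_after_trace) == rep.epochs
        assert all(fa < fb for fb, fa in
                   zip(rep.f_before_trace, rep.f_after_trace))

    def test_deterministic_given_seed(self):
        x = np.sin(np.linspace(0, 3, 40)).reshape(-1, 2)
        p1, r1 = train(x, TrainConfig(seed=6, max_epochs=30))
        p2, r2 = train(x, TrainConfig(seed=6, max_epochs=30))
        assert np.array_equal(p1.to_vector(), p2.to_vector())
        assert r1.mse_trace == r2.mse_trace

    def test_plain_lm_interpolates_linear_data(self):
        # alpha frozen at 0, one output: noiseless linear data is fit to
        # the least-squares (here: exact) solution at the training inputs
        x = np.linspace(-2, 2, 30).reshape(-1, 1)
        t = 2 * x + 1
        p, rep = train(x, TrainConfig(seed=0, mse_goal=1e-16,
                                      max_epochs=400, bayesian=False),
                       targets=t)
        pred = forward(p, x[rep.train_idx])
        assert np.abs(pred - t[rep.train_idx]).max() < 1e-6

    def test_regularization_shrinks_weights(self, default_cohort):
        from lbpanomaly.scoring import score_cohort
        sc = score_cohort(default_cohort)
        fm = build_feature_matrix(default_cohort, sc)
        cfg = TrainConfig(seed=3, max_epochs=40)
        p_bayes, _ = train(fm, cfg)
        p_plain, _ = train(fm, dataclasses.replace(cfg, bayesian=False))
        ew_bayes = float(p_bayes.to_vector() @ p_bayes.to_vector())
        ew_plain = float(p_plain.to_vector() @ p_plain.to_vector())
        assert ew_bayes < ew_plain

    def test_too_few_subjects(self):
        with pytest.raises(ValidationError):
            train(np.zeros((5, 3)), TrainConfig())


def test_model_save_load_round_trip(tmp_path, small_cohort, small_scores):
    fm = build_feature_matrix(small_cohort, small_scores)
    params, rep = train(fm, TrainConfig(seed=2, max_epochs=5))
    path = tmp_path / "model.json"
    save_model(path, params, fm, rep)
    loaded, lfm, meta = load_model(path)
    assert np.allclose(loaded.to_vector(), params.to_vector())
    assert np.allclose(lfm.mean, fm.mean)
    assert meta["epochs"] == rep.epochs
    x = fm.values[:7]
    assert np.allclose(forward(loaded, x), forward(params, x))
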