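"""Priors, kernels, the mixture-density network and the multi-round loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retsbi import sbi


class TestNormalize:
    BOUNDS = np.array([[2.0, 10.0], [-1.0, 3.0]])

    def test_endpoints(self):
        u = sbi.normalize_params(np.array([2.0, 3.0]), self.BOUNDS)
        np.testing.assert_allclose(u, [0.0, 1.0])

    def test_midpoint(self):
        u = sbi.normalize_params(np.array([6.0, 1.0]), self.BOUNDS)
        np.testing.assert_allclose(u, [0.5, 0.5])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_roundtrip_identity(self, a, b):
        u = np.array([a, b])
        theta = sbi.denormalize_params(u, self.BOUNDS)
        back = sbi.normalize_params(theta, self.BOUNDS)
        np.testing.assert_allclose(back, u, atol=1e-12)

    def test_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            sbi.normalize_params(np.array([1.0, 0.0]), self.BOUNDS)


class TestTruncatedSampler:
    def test_all_inside_box(self):
        prior = sbi.TruncatedNormalPrior([0.5], [0.3], [[0.0, 1.0]])
        s = prior.sample(10_000, np.random.default_rng(0))
        assert np.all((s >= 0.0) & (s <= 1.0))

    def test_half_normal_mean(self):
        prior = sbi.TruncatedNormalPrior([0.0], [1.0], [[0.0, np.inf]])
        s = prior.sample(100_000, np.random.default_rng(1))
        assert s.mean() == pytest.approx(math.sqrt(2 / math.pi), rel=0.01)

    def test_wide_box_matches_untruncated(self):
        prior = sbi.TruncatedNormalPrior([0.0], [1.0], [[-10.0, 10.0]])
        rng = np.random.default_rng(2)
        s = prior.sample(100_000, rng)
        assert s.mean() == pytest.approx(0.0, abs=0.02)
        assert s.std() == pytest.approx(1.0, rel=0.02)

    def test_hopeless_acceptance_errors(self):
        prior = sbi.TruncatedNormalPrior([0.0], [1e-3], [[5.0, 5.001]])
        with pytest.raises(RuntimeError, match="acceptance"):
            prior.sample(100, np.random.default_rng(3))

    def test_reproducible_by_seed(self):
        prior = sbi.TruncatedNormalPrior.unit_box(3)
        a = prior.sample(50, np.random.default_rng(9))
        b = prior.sample(50, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestKernel:
    def test_update_direct(self):
        x = np.zeros((20, 7))
        x[:, 0] = np.linspace(0.1, 1.1, 20)
        spec = sbi.kernel_update(x)
        assert spec.mu0 == pytest.approx(0.1)
        assert spec.sigma0 == pytest.approx(np.percentile(x[:, 0], 20) - 0.1)

    def test_degenerate_floor(self):
        x = np.full((10, 7), 0.4)
        spec = sbi.kernel_update(x)
        assert spec.sigma0 == pytest.approx(1e-3)

    def test_minimum_gets_largest_weight(self):
        x = np.zeros((30, 7))
        x[:, 0] = np.linspace(0.2, 2.0, 30)
        spec = sbi.kernel_update(x)
        w = sbi.kernel_weights(x, spec)
        assert np.argmax(w) == 0
        assert np.all((w > 0) & (w <= 1.0))

    def test_too_few_valid_errors(self):
        x = np.zeros((10, 7))
        valid = np.zeros(10, bool)
        valid[:3] = True
        with pytest.raises(ValueError, match="5 valid"):
            sbi.kernel_update(x, valid)


class TestMDN:
    def test_gradient_matches_numerical(self):
        rng = np.random.default_rng(0)
        net = sbi.MDN(x_dim=3, theta_dim=2, n_components=2, hidden=(5, 4),
                      seed=1)
        th = rng.normal(size=(6, 2))
        x = rng.normal(size=(6, 3))
        w = rng.uniform(0.2, 1.0, 6)
        net.x_mean = x.mean(0)
        net.x_std = x.std(0)
        _, grad = net.loss_and_grad(th, x, w)
        flat = net.get_flat()
        eps = 1e-6
        idx = rng.choice(len(flat), size=60, replace=False)
        for i in idx:
            f = flat.copy()
            f[i] += eps
            net.set_flat(f)
            lp, _ = net.loss_and_grad(th, x, w)
            f[i] -= 2 * eps
            net.set_flat(f)
            lm, _ = net.loss_and_grad(th, x, w)
            num = (lp - lm) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-7, rel=1e-4)

    def test_zero_weight_samples_have_no_influence(self):
        rng = np.random.default_rng(4)
        th = rng.normal(0.5, 0.1, size=(120, 2))
        x = rng.normal(size=(120, 3))
        w = np.ones(120)
        w[60:] = 0.0
        net_a = sbi.MDN(3, 2, seed=7)
        net_a.fit(th, x, w, epochs=150, seed=7)
        net_b = sbi.MDN(3, 2, seed=7)
        net_b.fit(th[:60], x[:60], np.ones(60), epochs=150, seed=7)
        np.testing.assert_allclose(net_a.get_flat(), net_b.get_flat(),
                                   atol=1e-12)

    def test_duplicated_dataset_same_optimum(self):
        rng = np.random.default_rng(5)
        th = rng.normal(0.5, 0.1, size=(80, 1))
        x = rng.normal(size=(80, 2))
        net_a = sbi.MDN(2, 1, seed=3)
        net_a.fit(th, x, np.ones(80), epochs=200, seed=3, val_frac=0.0)
        net_b = sbi.MDN(2, 1, seed=3)
        net_b.fit(np.vstack([th, th]), np.vstack([x, x]), np.ones(160),
                  epochs=200, seed=3, val_frac=0.0)
        gm_a = net_a.condition(np.zeros(2))
        gm_b = net_b.condition(np.zeros(2))
        np.testing.assert_allclose(gm_a.means, gm_b.means, atol=5e-3)

    def test_constant_head_ignores_evaluation_point(self):
        rng = np.random.default_rng(6)
        th = rng.normal(0.3, 0.05, size=(100, 2))
        x = rng.normal(size=(100, 4))
        net = sbi.MDN(4, 2, use_summaries=False, seed=2)
        net.fit(th, x, np.ones(100), epochs=200, seed=2)
        a = net.condition(np.zeros(4))
        b = net.condition(np.full(4, 5.0))
        np.testing.assert_allclose(a.means, b.means, atol=1e-12)

    def test_truncated_draws_inside_box(self):
        gm = sbi.GaussianMixture(np.array([1.0]), np.array([[0.5, 0.5]]),
                                 np.array([[[0.3, 0.0], [0.0, 0.3]]]))
        box = np.array([[0.0, 1.0], [0.0, 1.0]])
        s = gm.truncated(box).sample(2000, np.random.default_rng(0))
        assert np.all((s >= 0.0) & (s <= 1.0))

    def test_negligible_truncated_mass_errors(self):
        gm = sbi.GaussianMixture(np.array([1.0]), np.array([[50.0]]),
                                 np.array([[[0.01]]]),
                                 box=np.array([[0.0, 1.0]]))
        with pytest.raises(RuntimeError, match="mass"):
            gm.log_mass()


class TestRunInference:
    @staticmethod
    def gaussian_toy_simulator(noise=0.2):
        def simulator(theta, seed):
            rng = np.random.default_rng(seed)
            return "ok", theta + rng.normal(0.0, noise, size=len(theta))
        return simulator

    def test_seeded_repeat_identical(self):
        prior = sbi.TruncatedNormalPrior.unit_box(2)
        runs = []
        for _ in range(2):
            post, recs = sbi.run_inference(
                self.gaussian_toy_simulator(), prior, rounds=2,
                n_per_round=80, seed=42, hidden=(10,), epochs=120)
            runs.append((post, recs))
        np.testing.assert_array_equal(runs[0][1][0].thetas,
                                      runs[1][1][0].thetas)
        np.testing.assert_array_equal(runs[0][1][1].weights,
                                      runs[1][1][1].weights)
        np.testing.assert_allclose(runs[0][0].means, runs[1][0].means,
                                   atol=1e-12)

    def test_invalid_samples_get_zero_weight(self):
        calls = {"n": 0}

        def simulator(theta, seed):
            calls["n"] += 1
            if theta[0] > 0.8:
                return "unstable", np.array([np.nan, 0.0])
            return "ok", theta * 0.1

        prior = sbi.TruncatedNormalPrior.unit_box(2)
        post, recs = sbi.run_inference(simulator, prior, rounds=1,
                                       n_per_round=100, seed=0,
                                       hidden=(10,), epochs=100)
        rec = recs[0]
        assert np.all(rec.weights[~rec.valid] == 0.0)
        assert (~rec.valid).sum() > 0

    def test_posterior_draws_inside_prior_box(self):
        prior = sbi.TruncatedNormalPrior.unit_box(2)
        post, _ = sbi.run_inference(self.gaussian_toy_simulator(), prior,
                                    rounds=2, n_per_round=80, seed=3,
                                    hidden=(10,), epochs=120)
        s = post.sample(2000, np.random.default_rng(0))
        assert np.all((s >= 0.0) & (s <= 1.0))

    def test_all_invalid_aborts(self):
        def simulator(theta, seed):
            return "unstable", np.array([np.nan])

        prior = sbi.TruncatedNormalPrior.unit_box(1)
        with pytest.raises(RuntimeError, match="invalid"):
            sbi.run_inference(simulator, prior, rounds=1, n_per_round=20,
                              seed=0)
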