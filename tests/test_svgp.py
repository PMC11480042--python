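"""Sparse variational GP: kernel values, KL properties, ELBO behaviour,
predictive distribution and seeded determinism."""

import math

import numpy as np
import pytest

from reportuq.svgp import (KernelParams, SparseGPClassifier, SvgpConfig,
                           SvgpState, elbo_minibatch, gaussian_kl, kl_q_p,
                           rbf_ard, whitened_q_moments)

RNG = np.random.default_rng(7)


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        params = KernelParams(2.5, np.array([1.0, 3.0]))
        x = np.array([0.4, -1.2])
        assert rbf_ard(x, x, params) == pytest.approx(2.5)

    def test_huge_length_scales_approach_signal_variance(self):
        params = KernelParams(1.7, np.array([1e8, 1e8]))
        assert rbf_ard(np.zeros(2), np.ones(2), params) == pytest.approx(1.7, rel=1e-9)

    def test_hand_computed_value(self):
        params = KernelParams(1.0, np.array([1.0, 1.0]))
        out = rbf_ard(np.zeros(2), np.ones(2), params)
        assert out == pytest.approx(math.exp(-1.0), abs=1e-9)

    def test_symmetry_and_bound(self):
        params = KernelParams(1.3, np.array([0.7, 2.0, 1.1]))
        x, x2 = RNG.standard_normal(3), RNG.standard_normal(3)
        assert rbf_ard(x, x2, params) == pytest.approx(rbf_ard(x2, x, params))
        assert rbf_ard(x, x2, params) <= 1.3

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(-1.0, np.ones(2))
        with pytest.raises(ValueError):
            KernelParams(1.0, np.array([1.0, -2.0]))
        with pytest.raises(ValueError):
            rbf_ard(np.zeros(2), np.zeros(3), KernelParams(1.0, np.ones(2)))


def _random_state(m=4, d=3, num_classes=2, scale=0.5, rng=RNG):
    state = SvgpState(rng.standard_normal((m, d)), num_classes=num_classes,
                      signal_variance=float(rng.uniform(0.5, 2.0)),
                      length_scales=rng.uniform(0.5, 2.0, size=d), jitter=1e-8)
    state.m_w.value = rng.standard_normal((m, num_classes)) * scale
    for t in state.L_raw:
        t.value = rng.standard_normal((m, m)) * scale
    return state


class TestKL:
    def test_zero_at_prior(self):
        state = SvgpState(RNG.standard_normal((5, 2)), num_classes=3,
                          signal_variance=1.0, length_scales=np.ones(2))
        assert kl_q_p(state) == pytest.approx(0.0, abs=1e-12)

    def test_matches_unwhitened_closed_form(self):
        state = _random_state(num_classes=1)
        m, S, Kmm = whitened_q_moments(state, 0)
        assert kl_q_p(state) == pytest.approx(
            gaussian_kl(m, S, np.zeros(len(m)), Kmm), rel=1e-9)

    def test_nonnegative_on_random_states(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            assert kl_q_p(_random_state(rng=rng)) >= 0.0


class TestElbo:
    def test_degenerate_elbo_equals_log_likelihood(self):
        """With fresh variational parameters (q = whitened prior, KL = 0),
        zeroed noise draws and n_total = batch size, the ELBO reduces to the
        log softmax likelihood at the latent means."""
        X = RNG.standard_normal((6, 2))
        y = np.array([0, 1, 2, 0, 1, 2])
        state = SvgpState(RNG.standard_normal((4, 2)), num_classes=3,
                          signal_variance=1.0, length_scales=np.ones(2),
                          jitter=1e-8, mc_samples=3)
        eps = np.zeros((3, 6, 3))
        elbo = elbo_minibatch(state, X, y, n_total=6, eps=eps)
        from scipy.special import log_softmax as sp_log_softmax

        mu, _ = state.marginals(X)
        logp = sp_log_softmax(mu.value, axis=1)
        expected = logp[np.arange(6), y].sum()
        assert float(elbo.value) == pytest.approx(expected, rel=1e-9)

    def test_mc_variance_shrinks_with_sample_count(self):
        X = RNG.standard_normal((10, 2))
        y = np.array([0, 1, 2] * 3 + [0])
        state = _random_state(m=5, d=2, num_classes=3)

        def spread(mc):
            state.mc_samples = mc
            vals = []
            for s in range(30):
                rng = np.random.default_rng(1000 + s)
                vals.append(float(elbo_minibatch(state, X, y, 10, rng=rng).value))
            return np.var(vals)

        v1, v16 = spread(1), spread(16)
        assert v16 < v1 / 4  # O(1/S) scaling, with slack for MC noise

    def test_invalid_batch_rejected(self):
        state = _random_state(num_classes=3)
        with pytest.raises(ValueError):
            elbo_minibatch(state, np.zeros((0, 3)), np.zeros(0, dtype=int), 5,
                           rng=np.random.default_rng(0))


@pytest.fixture(scope="module")
def blob_fit(blob_data):
    cfg = SvgpConfig(num_inducing=30, seed=0, epochs=120)
    model = SparseGPClassifier(blob_data["X_train"], blob_data["y_train"], cfg)
    return model.fit()


class TestFitPredict:
    def test_blob_accuracy(self, blob_fit, blob_data):
        pred = blob_fit.predict(blob_data["X_test"])
        acc = np.mean(np.argmax(pred.probs, axis=1) == blob_data["y_test"])
        assert acc >= 0.9

    def test_training_curve_improves(self, blob_fit):
        hist = np.array(blob_fit.elbo_history)
        smooth = np.convolve(hist, np.ones(5) / 5, mode="valid")
        rise = smooth[-1] - smooth[0]
        assert rise > 0
        assert np.min(np.diff(smooth)) > -0.05 * rise  # non-decreasing after smoothing

    def test_probability_rows_on_simplex(self, blob_fit, blob_data):
        pred = blob_fit.predict(blob_data["X_test"])
        assert np.allclose(pred.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pred.probs >= 0)

    def test_cluster_point_predicted_as_its_class(self, blob_fit, blob_data):
        X, y = blob_data["X_train"], blob_data["y_train"]
        for c in range(3):
            centroid = X[y == c].mean(axis=0, keepdims=True)
            pred = blob_fit.predict(centroid)
            assert np.argmax(pred.probs[0]) == c

    def test_far_point_latent_variance_reverts_to_prior(self, blob_fit):
        state = blob_fit.state
        sv = float(np.exp(state.log_sv.value))
        far = np.full((1, 5), 1e6)
        pred = blob_fit.predict(far)
        assert np.allclose(pred.latent_variances, sv, atol=1e-6)

    def test_prior_reversion_monotone_along_ray(self, blob_fit):
        state = blob_fit.state
        anchor = state.Z.value.mean(axis=0)
        direction = np.ones(5) / np.sqrt(5)
        distances = np.array([0.0, 2.0, 5.0, 10.0, 30.0, 100.0])
        pts = anchor[None] + distances[:, None] * direction[None]
        var = blob_fit.predict(pts).latent_variances[:, 0]
        assert np.all(np.diff(var) >= -1e-9)

    def test_untrained_symmetric_state_predicts_uniform(self, blob_data):
        cfg = SvgpConfig(num_inducing=10, seed=0, epochs=120, mc_predict=400)
        model = SparseGPClassifier(blob_data["X_train"], blob_data["y_train"], cfg)
        from reportuq.svgp import SparseGPResults
        results = SparseGPResults(state=model._init_state(),
                                  classes=model.classes_, config=cfg)
        pred = results.predict(blob_data["X_test"][:5])
        assert np.allclose(pred.probs, 1 / 3, atol=0.05)

    def test_seeded_fit_is_reproducible(self, blob_data):
        cfg = SvgpConfig(num_inducing=8, seed=3, epochs=5)
        X, y = blob_data["X_train"][:90], blob_data["y_train"][:90]
        a = SparseGPClassifier(X, y, cfg).fit()
        b = SparseGPClassifier(X, y, cfg).fit()
        assert np.array_equal(a.predict(X[:10]).probs, b.predict(X[:10]).probs)
        assert a.elbo_history == b.elbo_history

    def test_missing_class_rejected(self, blob_data):
        mask = blob_data["y_train"] != 2
        with pytest.raises(ValueError, match="class"):
            SparseGPClassifier(blob_data["X_train"][mask],
                               blob_data["y_train"][mask], SvgpConfig())

    def test_dimension_mismatch_rejected(self, blob_fit):
        with pytest.raises(ValueError):
            blob_fit.predict(np.zeros((2, 7)))

    def test_summary_mentions_key_quantities(self, blob_fit):
        text = blob_fit.summary()
        assert "inducing points" in text and "length scales" in text
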