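import numpy as np
import pytest

from caliperase import vib
from caliperase.vib import (
    ClassifierConfig,
    DataError,
    GaussianPosterior,
    ShapeError,
    encode,
    init_model,
    kl_to_standard_normal,
    predict,
    train_classifier,
    vib_loss,
)
from caliperase.nnet import weights_checksum


def blob_set(n=80, side=16, seed=0, contrast=0.5):
    """Trivially separable crops: negatives flat, positives carry a dark blob."""
    rng = np.random.default_rng(seed)
    neg = rng.uniform(0.4, 0.6, (n, side, side))
    pos = rng.uniform(0.4, 0.6, (n, side, side))
    pos[:, 4:12, 4:12] *= 1 - contrast
    crops = np.concatenate([neg, pos])
    labels = np.array([0] * n + [1] * n)
    return crops, labels


class TestEncode:
    def test_sigma_is_softplus_of_zero_for_zeroed_head(self):
        model = init_model(ClassifierConfig(K=8), seed=0)
        model.params["W3"][:] = 0
        model.params["b3"][:] = 0
        post = encode(model, np.full((16, 16), 0.5))
        np.testing.assert_allclose(post.sigma, np.log(2.0))
        np.testing.assert_allclose(post.mu, 0.0)

    def test_sigma_strictly_positive_for_random_crops(self, rng):
        model = init_model(ClassifierConfig(K=16), seed=1)
        crops = rng.random((200, 16, 16))
        post = encode(model, crops)
        assert (post.sigma > 0).all()

    def test_dimensions_follow_bottleneck(self):
        model = init_model(ClassifierConfig(K=12), seed=2)
        post = encode(model, np.random.default_rng(0).random((5, 16, 16)))
        assert post.mu.shape == (5, 12) and post.sigma.shape == (5, 12)

    def test_wrong_crop_size_rejected(self):
        model = init_model(ClassifierConfig(), seed=0)
        with pytest.raises(ShapeError):
            encode(model, np.zeros((3, 20, 20)))


class TestKL:
    def test_standard_normal_is_zero(self):
        assert kl_to_standard_normal(
            GaussianPosterior(mu=np.zeros(4), sigma=np.ones(4))) == 0.0

    def test_unit_shift_closed_form(self):
        assert kl_to_standard_normal(
            GaussianPosterior(mu=np.array([1.0]), sigma=np.array([1.0]))) == 0.5

    @pytest.mark.parametrize("k", [1, 8, 32])
    def test_closed_form_matches_monte_carlo(self, k):
        rng = np.random.default_rng(k)
        for _ in range(5):
            mu = rng.normal(0, 1.5, k)
            sigma = rng.uniform(0.3, 2.0, k)
            closed = kl_to_standard_normal(GaussianPosterior(mu=mu, sigma=sigma))
            z = mu + sigma * rng.standard_normal((100_000, k))
            logp = (-0.5 * ((z - mu) / sigma) ** 2 - np.log(sigma)).sum(axis=1)
            logr = (-0.5 * z ** 2).sum(axis=1)
            samples = logp - logr
            se = samples.std(ddof=1) / np.sqrt(len(samples))
            assert abs(closed - samples.mean()) < 3 * se

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            GaussianPosterior(mu=np.zeros(2), sigma=np.array([1.0, 0.0]))


class TestVIBLoss:
    def test_total_is_class_plus_beta_rate(self):
        crops, labels = blob_set(20)
        model = init_model(ClassifierConfig(beta=0.37), seed=0)
        terms = vib_loss(model, crops, labels, n_mc=2, seed=1)
        assert terms.total == terms.class_term + 0.37 * terms.rate_term
        assert terms.rate_term >= 0

    def test_beta_zero_reduces_to_class_term(self):
        crops, labels = blob_set(20)
        model = init_model(ClassifierConfig(beta=0.0), seed=0)
        terms = vib_loss(model, crops, labels, seed=1)
        assert terms.total == terms.class_term

    def test_frozen_sigma_converges_to_deterministic_ce(self):
        """With sigma ~ 0 the MC class term equals cross-entropy at z = mu."""
        crops, labels = blob_set(30)
        model = init_model(ClassifierConfig(K=16), seed=3)
        model.params["b3"][16:] = -30.0  # softplus(-30) ~ 1e-13
        terms = vib_loss(model, crops, labels, n_mc=8, seed=0)
        from caliperase.nnet import cross_entropy
        post = encode(model, crops)
        logits = post.mu @ model.params["Wd"] + model.params["bd"]
        ce, _ = cross_entropy(logits, labels)
        assert terms.class_term == pytest.approx(ce, abs=1e-6)

    def test_empty_batch_rejected(self):
        model = init_model(ClassifierConfig(), seed=0)
        with pytest.raises(DataError):
            vib_loss(model, np.zeros((0, 16, 16)), np.zeros(0, dtype=int))


class TestTraining:
    def test_both_model_kinds_fit_separable_blobs(self):
        crops, labels = blob_set(60)
        for use_vib in (False, True):
            cfg = ClassifierConfig(use_vib=use_vib, epochs=20)
            model = train_classifier(crops, labels, cfg, seed=0)
            assert vib.accuracy(model, crops, labels) >= 0.95

    def test_conv_architecture_fits_separable_blobs(self):
        crops, labels = blob_set(60)
        cfg = ClassifierConfig(use_vib=False, arch="conv", epochs=20)
        model = train_classifier(crops, labels, cfg, seed=0)
        assert vib.accuracy(model, crops, labels) >= 0.95

    def test_seeded_determinism_of_final_weights(self):
        crops, labels = blob_set(40)
        cfg = ClassifierConfig(use_vib=True, epochs=5)
        a = train_classifier(crops, labels, cfg, seed=4)
        b = train_classifier(crops, labels, cfg, seed=4)
        assert weights_checksum(a.params) == weights_checksum(b.params)

    def test_near_baseline_when_beta_zero_and_sigma_collapsed(self):
        """A VIB model with beta=0 behaves like a stochastic-encoder baseline."""
        crops, labels = blob_set(60)
        base = train_classifier(crops, labels,
                                ClassifierConfig(use_vib=False, epochs=20), seed=0)
        stoch = train_classifier(crops, labels,
                                 ClassifierConfig(use_vib=True, beta=0.0,
                                                  epochs=20), seed=0)
        acc_b = vib.accuracy(base, crops, labels)
        acc_s = vib.accuracy(stoch, crops, labels)
        assert abs(acc_b - acc_s) <= 0.05

    def test_single_class_rejected(self):
        crops, _ = blob_set(10)
        with pytest.raises(DataError):
            train_classifier(crops, np.zeros(len(crops), dtype=int),
                             ClassifierConfig(epochs=1), seed=0)


class TestGradients:
    @pytest.mark.parametrize("arch", ["mlp", "conv"])
    def test_analytic_gradients_match_finite_differences(self, arch):
        """Backprop agrees with central finite differences on a tiny model."""
        cfg = ClassifierConfig(arch=arch, K=4, hidden=(6, 5), conv_channels=(2, 3),
                               input_side=8, use_vib=True, beta=0.2)
        model = init_model(cfg, seed=0)
        rng = np.random.default_rng(1)
        x = rng.random((3, 64))
        y = np.array([0, 1, 1])
        from caliperase.vib import _loss_and_grads
        _, grads = _loss_and_grads(model, x, y, n_mc=1,
                                   rng=np.random.default_rng(7))
        eps = 1e-6
        for name in model.params:
            flat = model.params[name].reshape(-1)
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = _loss_and_grads(model, x, y, 1, np.random.default_rng(7))
                flat[idx] = orig - eps
                lm, _ = _loss_and_grads(model, x, y, 1, np.random.default_rng(7))
                flat[idx] = orig
                numeric = (lp.total - lm.total) / (2 * eps)
                analytic = grads[name].reshape(-1)[idx]
                assert analytic == pytest.approx(numeric, abs=1e-4), \
                    f"{arch} grad mismatch at {name}[{idx}]"


class TestPredict:
    def test_probabilities_sum_to_one(self, rng):
        model = init_model(ClassifierConfig(), seed=0)
        crops = rng.random((40, 16, 16))
        for mode in ("mean", "sample"):
            probs = predict(model, crops, mode=mode, n_samples=4, seed=0)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_mean_mode_deterministic(self, rng):
        model = init_model(ClassifierConfig(), seed=0)
        crops = rng.random((10, 16, 16))
        np.testing.assert_array_equal(predict(model, crops),
                                      predict(model, crops))

    def test_sample_mode_converges(self, rng):
        model = init_model(ClassifierConfig(), seed=0)
        crops = rng.random((5, 16, 16))
        estimates = [predict(model, crops, mode="sample", n_samples=256,
                             seed=s)[:, 1] for s in range(6)]
        se = np.std(estimates, axis=0, ddof=1).max() / np.sqrt(len(estimates))
        assert se < 0.01
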