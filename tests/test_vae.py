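import numpy as np
import pytest

import vaeda
from vaeda import VaeConfig, build_model, embed, gaussian_nll, kl_divergence, train, vae_loss
from vaeda.clustering import ClusterLabels
from vaeda.vae import categorical_cross_entropy


def _cfg(**kw):
    defaults = dict(latent_dim=3, hidden_units=16, rng_seed=0, dtype=np.float64, batch_size=32)
    defaults.update(kw)
    return VaeConfig(**defaults)


class TestLossTerms:
    def test_kl_identities(self):
        assert kl_divergence(np.zeros(5), np.ones(5)) == 0.0
        e1 = np.eye(5)[0]
        assert np.isclose(kl_divergence(e1, np.ones(5)), 0.5)

    def test_kl_nonnegative_and_zero_only_at_prior(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=(50, 4))
        sigma = np.exp(rng.normal(size=(50, 4)) * 0.5)
        kl = kl_divergence(mu, sigma)
        assert np.all(kl >= 0)
        assert np.all(kl[np.any((mu != 0) | (sigma != 1), axis=1)] > 0)

    def test_cce_zero_for_perfect_prediction(self):
        onehot = np.eye(3)
        assert np.allclose(categorical_cross_entropy(onehot, onehot + 1e-15), 0.0, atol=1e-9)

    def test_beta_zero_reduces_to_plain_vae_loss(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 6))
        mu_d, sigma_d = rng.normal(size=(4, 6)), np.abs(rng.normal(size=(4, 6))) + 0.1
        mu_e, sigma_e = rng.normal(size=(4, 2)), np.abs(rng.normal(size=(4, 2))) + 0.1
        zeta = np.full((4, 3), 1 / 3)
        onehot = np.eye(3)[[0, 1, 2, 0]]
        plain = gaussian_nll(x, mu_d, sigma_d) + kl_divergence(mu_e, sigma_e)
        np.testing.assert_allclose(
            vae_loss(x, onehot, mu_d, sigma_d, mu_e, sigma_e, zeta, beta=0.0), plain
        )
        assert np.all(
            vae_loss(x, onehot, mu_d, sigma_d, mu_e, sigma_e, zeta, beta=10.0) > plain
        )


class TestModelStructure:
    def test_output_shapes(self):
        model = build_model(n_features=20, n_clusters=4, cfg=_cfg())
        x = np.random.default_rng(0).normal(size=(7, 20))
        out = model.forward(x, training=False)
        assert out["mu_e"].shape == (7, 3)
        assert out["sigma_e"].shape == (7, 3)
        assert out["mu_d"].shape == (7, 20)
        assert out["zeta"].shape == (7, 4)

    def test_softmax_rows_sum_to_one_and_sigmas_positive(self):
        model = build_model(n_features=10, n_clusters=3, cfg=_cfg())
        x = np.random.default_rng(1).normal(size=(5, 10)) * 100
        out = model.forward(x, training=False)
        np.testing.assert_allclose(out["zeta"].sum(axis=1), 1.0, atol=1e-6)
        assert np.all(out["sigma_e"] > 0)
        assert np.all(out["sigma_d"] > 0)

    def test_single_cluster_omits_classifier(self):
        model = build_model(n_features=10, n_clusters=1, cfg=_cfg())
        out = model.forward(np.zeros((2, 10)), training=False)
        assert out["zeta"] is None


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """The analytic gradient of the mean composite loss agrees with a
        central-difference approximation on every parameter tensor."""
        cfg = _cfg(latent_dim=2, hidden_units=5, dropout_rate=0.45)
        model = build_model(n_features=4, n_clusters=3, cfg=cfg)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 4))
        onehot = np.eye(3)[rng.integers(0, 3, size=6)]
        eps = rng.standard_normal((6, 2))

        # freeze dropout masks: rate 0 for the analytic/numeric comparison
        for layer in (model.enc_drop, model.dec_drop):
            layer.rate = 0.0
        # use batch statistics on both sides (training=True) so the loss is a
        # deterministic function of the parameters
        out = model.forward(x, training=True, eps=eps)
        model.backward(out, onehot)

        def loss_fn():
            return model.loss(model.forward(x, training=True, eps=eps), onehot)

        h = 1e-6
        for layer in model.layers:
            for name, param in layer.params.items():
                grad = layer.grads[name]
                flat = param.ravel()
                for idx in [0, flat.size // 2, flat.size - 1]:
                    orig = flat[idx]
                    flat[idx] = orig + h
                    up = loss_fn()
                    flat[idx] = orig - h
                    down = loss_fn()
                    flat[idx] = orig
                    numeric = (up - down) / (2 * h)
                    assert np.isclose(grad.ravel()[idx], numeric, rtol=1e-4, atol=1e-6), (
                        f"{type(layer).__name__}.{name}[{idx}]"
                    )


def _blob_training_setup(two_blobs, **cfg_kw):
    values, membership = two_blobs
    x = (values - values.mean(0)) / values.std(0)
    c = ClusterLabels(np.asarray(membership), 2)
    cfg = _cfg(**{**dict(max_epochs=60, patience=10), **cfg_kw})
    return x, c, cfg


class TestTraining:
    def test_loss_decreases_on_small_fixture(self, two_blobs):
        x, c, cfg = _blob_training_setup(two_blobs)
        model, history = train(x, c, cfg)
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_patience_zero_stops_at_first_non_improvement(self, two_blobs):
        x, c, cfg = _blob_training_setup(two_blobs, patience=0, max_epochs=50)
        _, history = train(x, c, cfg)
        n = len(history["val_loss"])
        assert n < 50
        # every epoch before the last improved on the running best
        best = np.inf
        for v in history["val_loss"][:-1]:
            assert v < best
            best = v
        assert history["val_loss"][-1] >= best

    def test_same_seed_same_history(self, two_blobs):
        x, c, cfg = _blob_training_setup(two_blobs, max_epochs=8, patience=20)
        _, h1 = train(x, c, cfg)
        _, h2 = train(x, c, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_nonfinite_loss_aborts_with_epoch(self, two_blobs):
        x, c, cfg = _blob_training_setup(two_blobs, max_epochs=10)
        x = x.copy()
        x[0, 0] = np.inf  # poisons the reconstruction likelihood
        with pytest.raises(RuntimeError, match="epoch"):
            train(x, c, cfg)


class TestEmbed:
    def test_shape_and_determinism(self, two_blobs):
        x, c, cfg = _blob_training_setup(two_blobs, max_epochs=10)
        model, _ = train(x, c, cfg)
        z1 = embed(model, x)
        z2 = embed(model, x)
        assert z1.Z.shape == (x.shape[0], cfg.latent_dim)
        np.testing.assert_array_equal(z1.Z, z2.Z)
        assert z1.source == "posterior_mean"

    def test_permutation_equivariance(self, two_blobs):
        x, c, cfg = _blob_training_setup(two_blobs, max_epochs=10)
        model, _ = train(x, c, cfg)
        perm = np.random.default_rng(0).permutation(x.shape[0])
        np.testing.assert_allclose(embed(model, x[perm]).Z, embed(model, x).Z[perm], atol=1e-10)

    def test_feature_mismatch_errors(self, two_blobs):
        x, c, cfg = _blob_training_setup(two_blobs, max_epochs=2)
        model, _ = train(x, c, cfg)
        with pytest.raises(ValueError, match="feature dimension"):
            embed(model, x[:, :5])

    def test_latent_space_separates_blobs(self, two_blobs):
        """A knn(k=5) vote on Z recovers blob labels: the embedding preserves
        local label structure."""
        from sklearn.neighbors import KNeighborsClassifier

        values, membership = two_blobs
        x, c, cfg = _blob_training_setup(two_blobs, max_epochs=40)
        model, _ = train(x, c, cfg)
        z = embed(model, x).Z
        acc = KNeighborsClassifier(n_neighbors=5).fit(z, membership).score(z, membership)
        assert acc >= 0.95
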