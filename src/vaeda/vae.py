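"""Cluster-aware variational autoencoder for the augmented expression data.

The model learns a d-dimensional latent representation Z of the stacked
real + simulated matrix.  It has three parts:

* an encoder  (input -> dense(256) -> batch-norm -> dropout -> diagonal
  Normal head giving mu_e, sigma_e),
* a decoder   (latent -> dense(256) -> batch-norm -> dropout -> diagonal
  Normal head giving mu_d, sigma_d over the features), and
* a cluster classifier (latent -> batch-norm -> softmax over clusters).

The per-example loss is

    -log N(x | mu_d, sigma_d)  +  KL( N(mu_e, sigma_e) || N(0, I) )
        +  beta * CCE(c, zeta)

so the latent space must both reconstruct expression and linearly separate
the Leiden clusters; beta (default 20,000) balances the two objectives.
Training uses the reparameterization trick, the Adamax optimizer, a
multiplicative learning-rate decay of 0.75 per epoch starting after epoch 3,
a 10% validation split and early stopping (patience 20, best weights
restored).  The embedding is the deterministic posterior mean mu_e.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from ._nn import Adamax, BatchNorm, Dense, Dropout, ReLU, sigmoid, softplus
from .io_preprocess import TransformedMatrix

log = logging.getLogger("vaeda")

__all__ = [
    "VaeConfig",
    "LatentEmbedding",
    "ClusterAwareVAE",
    "build_model",
    "train",
    "embed",
    "gaussian_nll",
    "kl_divergence",
    "categorical_cross_entropy",
    "vae_loss",
]

_SIGMA_FLOOR = 1e-5


@dataclass
class VaeConfig:
    latent_dim: int = 5
    hidden_units: int = 256
    dropout_rate: float = 0.3
    beta: float = 20_000.0
    learning_rate: float = 0.001
    decay_rate: float = 0.75  # multiplicative, per epoch, applied after epoch 3
    decay_start_epoch: int = 3
    validation_fraction: float = 0.10
    patience: int = 20
    max_epochs: int = 500
    batch_size: int = 128
    rng_seed: int = 0
    dtype: type = np.float32

    def __post_init__(self) -> None:
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in (0, 1)")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass
class LatentEmbedding:
    """Latent matrix Z (rows x latent_dim), taken as the posterior mean."""

    Z: np.ndarray
    source: str = "posterior_mean"

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("latent embedding contains non-finite entries")
        if self.source not in ("posterior_mean", "posterior_sample"):
            raise ValueError("source must be posterior_mean or posterior_sample")


# ---------------------------------------------------------------------------
# Loss terms (also used standalone in tests and the ablation comparison)
# ---------------------------------------------------------------------------


def gaussian_nll(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Per-example negative log-likelihood under a diagonal Normal."""
    return np.sum(
        0.5 * np.log(2.0 * np.pi) + np.log(sigma) + 0.5 * ((x - mu) / sigma) ** 2, axis=-1
    )


def kl_divergence(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Per-example KL( N(mu, diag sigma^2) || N(0, I) ), closed form.

    0.5 * sum_k ( mu_k^2 + sigma_k^2 - 1 - log sigma_k^2 ); zero exactly at
    mu = 0, sigma = 1.
    """
    return 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma), axis=-1)


def categorical_cross_entropy(onehot: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Per-example CCE -sum_c onehot_c log(probs_c)."""
    return -np.sum(onehot * np.log(np.clip(probs, 1e-12, None)), axis=-1)


def vae_loss(
    x: np.ndarray,
    c_onehot: np.ndarray | None,
    mu_d: np.ndarray,
    sigma_d: np.ndarray,
    mu_e: np.ndarray,
    sigma_e: np.ndarray,
    zeta: np.ndarray | None,
    beta: float,
) -> np.ndarray:
    """Per-example composite loss; with beta = 0 this is the plain VAE loss."""
    out = gaussian_nll(x, mu_d, sigma_d) + kl_divergence(mu_e, sigma_e)
    if zeta is not None and c_onehot is not None and beta != 0.0:
        out = out + beta * categorical_cross_entropy(c_onehot, zeta)
    return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=1, keepdims=True)


class ClusterAwareVAE:
    """Encoder/decoder/classifier triple with hand-rolled backprop."""

    def __init__(self, n_features: int, n_clusters: int, cfg: VaeConfig) -> None:
        if n_features < 1 or n_clusters < 1:
            raise ValueError("n_features and n_clusters must be >= 1")
        self.n_features = n_features
        self.n_clusters = n_clusters
        self.cfg = cfg
        self.has_classifier = n_clusters > 1
        if not self.has_classifier:
            log.warning("single cluster: classifier term omitted from the model")
        d, h, dt = cfg.latent_dim, cfg.hidden_units, cfg.dtype
        rng = np.random.default_rng(cfg.rng_seed)
        self._rng = rng
        # encoder
        self.enc_dense = Dense(n_features, h, rng, dtype=dt)
        self.enc_bn = BatchNorm(h, dtype=dt)
        self.enc_relu = ReLU()
        self.enc_drop = Dropout(cfg.dropout_rate, rng)
        self.enc_head = Dense(h, 2 * d, rng, dtype=dt)
        # decoder
        self.dec_dense = Dense(d, h, rng, dtype=dt)
        self.dec_bn = BatchNorm(h, dtype=dt)
        self.dec_relu = ReLU()
        self.dec_drop = Dropout(cfg.dropout_rate, rng)
        self.dec_head = Dense(h, 2 * n_features, rng, dtype=dt)
        # classifier
        self.cls_bn = BatchNorm(d, dtype=dt) if self.has_classifier else None
        self.cls_dense = Dense(d, n_clusters, rng, dtype=dt) if self.has_classifier else None

    @property
    def layers(self) -> list:
        out = [
            self.enc_dense, self.enc_bn, self.enc_relu, self.enc_drop, self.enc_head,
            self.dec_dense, self.dec_bn, self.dec_relu, self.dec_drop, self.dec_head,
        ]
        if self.has_classifier:
            out += [self.cls_bn, self.cls_dense]
        return out

    # -- forward pieces -----------------------------------------------------

    def encode(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, np.ndarray]:
        h = self.enc_drop.forward(
            self.enc_relu.forward(self.enc_bn.forward(self.enc_dense.forward(x, training), training), training),
            training,
        )
        raw = self.enc_head.forward(h, training)
        d = self.cfg.latent_dim
        self._enc_raw_sigma = raw[:, d:]
        mu = raw[:, :d]
        sigma = softplus(raw[:, d:]) + _SIGMA_FLOOR
        return mu, sigma

    def decode(self, z: np.ndarray, training: bool) -> tuple[np.ndarray, np.ndarray]:
        h = self.dec_drop.forward(
            self.dec_relu.forward(self.dec_bn.forward(self.dec_dense.forward(z, training), training), training),
            training,
        )
        raw = self.dec_head.forward(h, training)
        p = self.n_features
        self._dec_raw_sigma = raw[:, p:]
        mu = raw[:, :p]
        sigma = softplus(raw[:, p:]) + _SIGMA_FLOOR
        return mu, sigma

    def classify(self, z: np.ndarray, training: bool) -> np.ndarray | None:
        if not self.has_classifier:
            return None
        return _softmax(self.cls_dense.forward(self.cls_bn.forward(z, training), training))

    def forward(
        self, x: np.ndarray, training: bool, eps: np.ndarray | None = None
    ) -> dict[str, np.ndarray | None]:
        mu_e, sigma_e = self.encode(x, training)
        if eps is None:
            z = mu_e
        else:
            z = mu_e + sigma_e * eps
        mu_d, sigma_d = self.decode(z, training)
        zeta = self.classify(z, training)
        return {
            "mu_e": mu_e, "sigma_e": sigma_e, "z": z, "eps": eps,
            "mu_d": mu_d, "sigma_d": sigma_d, "zeta": zeta, "x": x,
        }

    def loss(self, out: dict, c_onehot: np.ndarray | None) -> float:
        per_example = vae_loss(
            out["x"], c_onehot, out["mu_d"], out["sigma_d"],
            out["mu_e"], out["sigma_e"], out["zeta"], self.cfg.beta,
        )
        return float(per_example.mean())

    # -- backward -----------------------------------------------------------

    def backward(self, out: dict, c_onehot: np.ndarray | None) -> None:
        """Accumulate mean-loss gradients into every layer's ``grads``."""
        x, mu_d, sigma_d = out["x"], out["mu_d"], out["sigma_d"]
        mu_e, sigma_e, eps = out["mu_e"], out["sigma_e"], out["eps"]
        m = x.shape[0]

        # reconstruction NLL wrt decoder head outputs
        d_mu_d = (mu_d - x) / sigma_d**2 / m
        d_sigma_d = (1.0 / sigma_d - (x - mu_d) ** 2 / sigma_d**3) / m
        d_raw_sigma_d = d_sigma_d * sigmoid(self._dec_raw_sigma)  # softplus'
        g = np.concatenate([d_mu_d, d_raw_sigma_d], axis=1)
        g = self.dec_head.backward(g)
        g = self.dec_drop.backward(g)
        g = self.dec_relu.backward(g)
        g = self.dec_bn.backward(g)
        dz = self.dec_dense.backward(g)

        # classifier CCE wrt z
        if self.has_classifier and c_onehot is not None and self.cfg.beta != 0.0:
            d_logits = self.cfg.beta * (out["zeta"] - c_onehot) / m
            g = self.cls_dense.backward(d_logits)
            dz = dz + self.cls_bn.backward(g)

        # KL wrt encoder distribution parameters
        d_mu_e = mu_e / m
        d_sigma_e = (sigma_e - 1.0 / sigma_e) / m

        # reparameterization: z = mu_e + sigma_e * eps
        d_mu_e = d_mu_e + dz
        if eps is not None:
            d_sigma_e = d_sigma_e + dz * eps
        d_raw_sigma_e = d_sigma_e * sigmoid(self._enc_raw_sigma)
        g = np.concatenate([d_mu_e, d_raw_sigma_e], axis=1)
        g = self.enc_head.backward(g)
        g = self.enc_drop.backward(g)
        g = self.enc_relu.backward(g)
        g = self.enc_bn.backward(g)
        self.enc_dense.backward(g)

    # -- state snapshots for early stopping ---------------------------------

    def get_state(self) -> dict:
        state = {"params": [copy.deepcopy(l.params) for l in self.layers]}
        state["bn"] = [
            (l.running_mean.copy(), l.running_var.copy())
            for l in self.layers
            if isinstance(l, BatchNorm)
        ]
        return state

    def set_state(self, state: dict) -> None:
        for layer, params in zip(self.layers, state["params"]):
            for k in layer.params:
                layer.params[k][...] = params[k]
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        for layer, (mean, var) in zip(bns, state["bn"]):
            layer.running_mean[...] = mean
            layer.running_var[...] = var


def build_model(n_features: int, n_clusters: int, cfg: VaeConfig) -> ClusterAwareVAE:
    return ClusterAwareVAE(n_features, n_clusters, cfg)


def _onehot(assignments: np.ndarray, n_clusters: int, dtype) -> np.ndarray:
    out = np.zeros((assignments.size, n_clusters), dtype=dtype)
    out[np.arange(assignments.size), assignments] = 1.0
    return out


def train(
    M: TransformedMatrix | np.ndarray,
    c,
    cfg: VaeConfig,
    model: ClusterAwareVAE | None = None,
) -> tuple[ClusterAwareVAE, dict[str, list[float]]]:
    """Fit the VAE on the transformed matrix with cluster labels ``c``.

    Returns the trained model (best validation weights restored) and the
    per-epoch train/validation loss history.  Validation uses the
    deterministic posterior mean (no sampling, no dropout) so early stopping
    is not noise-driven; the monitored quantity is the full loss including
    the beta-weighted classifier term.
    """
    values = M.values if isinstance(M, TransformedMatrix) else np.asarray(M)
    x_all = np.ascontiguousarray(values, dtype=cfg.dtype)
    assignments = np.asarray(c.assignments if hasattr(c, "assignments") else c, dtype=np.int64)
    n = x_all.shape[0]
    if assignments.shape != (n,):
        raise ValueError("cluster labels must align with matrix rows")
    n_clusters = int(assignments.max()) + 1

    if model is None:
        model = build_model(x_all.shape[1], n_clusters, cfg)
    onehot_all = _onehot(assignments, model.n_clusters, cfg.dtype) if model.has_classifier else None

    rng = np.random.default_rng(cfg.rng_seed + 1)  # data order; model init uses rng_seed
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training rows")
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    opt = Adamax(model.layers, lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.get_state()
    wait = 0

    for epoch in range(1, cfg.max_epochs + 1):
        if epoch > cfg.decay_start_epoch:
            opt.lr = cfg.learning_rate * cfg.decay_rate ** (epoch - cfg.decay_start_epoch)
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            x = x_all[batch]
            eps = rng.standard_normal((x.shape[0], cfg.latent_dim)).astype(cfg.dtype)
            out = model.forward(x, training=True, eps=eps)
            c_batch = onehot_all[batch] if onehot_all is not None else None
            loss = model.loss(out, c_batch)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            model.backward(out, c_batch)
            opt.step()
            epoch_loss += loss * x.shape[0]
        train_loss = epoch_loss / order.size

        out = model.forward(x_all[val_idx], training=False, eps=None)
        val_loss = model.loss(out, onehot_all[val_idx] if onehot_all is not None else None)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            wait = 0
        else:
            wait += 1
            if wait >= max(cfg.patience, 1) or cfg.patience == 0:
                log.info("early stopping at epoch %d (best val %.4f)", epoch, best_val)
                break

    model.set_state(best_state)
    return model, history


def embed(model: ClusterAwareVAE, M: TransformedMatrix | np.ndarray) -> LatentEmbedding:
    """Deterministic latent representation: encoder posterior means."""
    values = M.values if isinstance(M, TransformedMatrix) else np.asarray(M)
    if values.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {values.shape[1]} does not match model ({model.n_features})"
        )
    mu, _ = model.encode(np.ascontiguousarray(values, dtype=model.cfg.dtype), training=False)
    return LatentEmbedding(Z=mu, source="posterior_mean")
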