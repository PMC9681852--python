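"""A 3-layer (input, latent, output) denoising autoencoder in plain numpy.

The network is deliberately tiny: a sigmoid (or linear) encoder to a
P-dimensional latent space and a linear decoder back to feature space,
trained with Adam on mean squared reconstruction error plus an L2 weight
penalty and a KL-divergence sparsity penalty on the mean encoder
activations.  With P = 2 and a few hundred genes the whole model is a pair
of small dense matrices, so there is no need for a deep-learning framework;
a numpy implementation is exactly reproducible under a seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ParameterError, TrainingError


@dataclasses.dataclass
class AutoencoderConfig:
    """Hyperparameters of the denoising autoencoder.

    Defaults are the pipeline's standard settings: a 2-D latent space,
    sigmoid encoder / linear decoder, L2 weight 0.05, sparsity weight 0.9
    (target activation 0.05), Adam with learning rate 1e-5, 20 epochs,
    batch size 64, and weights initialized uniformly on [0, 1].
    """

    latent_dim: int = 2
    encoder_activation: str = "sigmoid"  # "sigmoid" or "linear"
    l2_weight: float = 0.05
    sparsity_weight: float = 0.9
    sparsity_target: float = 0.05
    learning_rate: float = 1e-5
    max_epochs: int = 20
    batch_size: int = 64
    init: str = "uniform"  # "uniform": U[0, 1]; "scaled": symmetric Glorot-style
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ParameterError(f"latent_dim must be >= 1, got {self.latent_dim}")
        if self.encoder_activation not in ("sigmoid", "linear"):
            raise ParameterError(f"unknown encoder activation {self.encoder_activation!r}")
        if self.init not in ("uniform", "scaled"):
            raise ParameterError(f"unknown init scheme {self.init!r}")
        for name in ("learning_rate", "max_epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Autoencoder:
    """Encoder h = act(W x + b), decoder x' = W' h + b'."""

    def __init__(self, n_features: int, cfg: AutoencoderConfig):
        if cfg.latent_dim >= n_features:
            raise ParameterError(
                f"latent_dim {cfg.latent_dim} must be smaller than n_features {n_features}"
            )
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        P, m = cfg.latent_dim, n_features
        if cfg.init == "uniform":
            self.W = rng.uniform(0.0, 1.0, (P, m))
            self.b = rng.uniform(0.0, 1.0, P)
            self.W2 = rng.uniform(0.0, 1.0, (m, P))
            self.b2 = rng.uniform(0.0, 1.0, m)
        else:
            s1 = np.sqrt(6.0 / (P + m))
            self.W = rng.uniform(-s1, s1, (P, m))
            self.b = np.zeros(P)
            self.W2 = rng.uniform(-s1, s1, (m, P))
            self.b2 = np.zeros(m)
        self._adam_state = {
            name: (np.zeros_like(getattr(self, name)), np.zeros_like(getattr(self, name)))
            for name in ("W", "b", "W2", "b2")
        }
        self._adam_t = 0
        self._shuffle_rng = rng

    def encode(self, X: np.ndarray) -> np.ndarray:
        Z = X @ self.W.T + self.b
        return _sigmoid(Z) if self.cfg.encoder_activation == "sigmoid" else Z

    def decode(self, H: np.ndarray) -> np.ndarray:
        return H @ self.W2.T + self.b2

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))

    def _loss_and_grads(self, X: np.ndarray):
        cfg = self.cfg
        n = X.shape[0]
        H = self.encode(X)
        Xr = self.decode(H)
        E = Xr - X
        recon = float((E ** 2).sum(axis=1).mean())
        l2 = cfg.l2_weight * float((self.W ** 2).sum() + (self.W2 ** 2).sum())

        dE = 2.0 * E / n
        gW2 = dE.T @ H + 2.0 * cfg.l2_weight * self.W2
        gb2 = dE.sum(axis=0)
        dH = dE @ self.W2

        sparsity = 0.0
        if cfg.encoder_activation == "sigmoid" and cfg.sparsity_weight > 0:
            rho = cfg.sparsity_target
            rho_hat = np.clip(H.mean(axis=0), 1e-8, 1.0 - 1e-8)
            sparsity = cfg.sparsity_weight * float(
                (rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))).sum()
            )
            d_rho = cfg.sparsity_weight * (-rho / rho_hat + (1 - rho) / (1 - rho_hat)) / n
            dH = dH + d_rho[None, :]

        if cfg.encoder_activation == "sigmoid":
            dZ = dH * H * (1.0 - H)
        else:
            dZ = dH
        gW = dZ.T @ X + 2.0 * cfg.l2_weight * self.W
        gb = dZ.sum(axis=0)

        loss = recon + l2 + sparsity
        return loss, {"W": gW, "b": gb, "W2": gW2, "b2": gb2}

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for name, g in grads.items():
            m, v = self._adam_state[name]
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g ** 2
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            param = getattr(self, name)
            param -= self.cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def fit(self, X: np.ndarray) -> list[float]:
        """Train on rows of X (already scaled to [0, 1]); returns per-epoch mean losses."""
        n = X.shape[0]
        epoch_losses: list[float] = []
        for _ in range(int(self.cfg.max_epochs)):
            order = self._shuffle_rng.permutation(n)
            batch_losses = []
            for start in range(0, n, int(self.cfg.batch_size)):
                batch = X[order[start:start + int(self.cfg.batch_size)]]
                loss, grads = self._loss_and_grads(batch)
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"non-finite loss {loss} at epoch {len(epoch_losses)}; "
                        f"|W|max={np.abs(self.W).max():.3g}, |W'|max={np.abs(self.W2).max():.3g}"
                    )
                self._adam_step(grads)
                batch_losses.append(loss)
            epoch_losses.append(float(np.mean(batch_losses)))
        return epoch_losses
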