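"""Multimodal autoencoder with a shared latent layer.

Each omics modality m gets its own encoder E_m (one hidden layer of width
min(p_m, 500) with ReLU); the encoder outputs are concatenated and linearly
projected to a shared latent representation h (default width 100). Four
decoders g_m reconstruct each modality from h. Training minimizes the
weighted reconstruction loss

    L = alpha * MSE(X_CNA,  g_1(h)) + beta  * MSE(X_MET,  g_2(h))
      + gamma * MSE(X_mRNA, g_3(h)) + delta * MSE(X_RPPA, g_4(h)),

with (alpha, beta, gamma, delta) = (0.2, 0.2, 0.3, 0.3) summing to 1, so
the lower-noise transcriptomic and proteomic layers carry slightly more
weight. The autoencoder is trained unsupervised on training-fold samples
only and then embeds the whole cohort.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .datatypes import LatentEmbedding, Modality, MultiOmicsDataset, OmicsMatrix

__all__ = ["AEConfig", "MultimodalAutoencoder", "ae_loss", "fit_and_embed"]

DEFAULT_WEIGHTS = (0.2, 0.2, 0.3, 0.3)  # (CNA, MET, mRNA, RPPA)


@dataclass
class AEConfig:
    loss_weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS
    latent_dim: int = 100
    max_hidden: int = 500          # per-modality encoder width cap
    epochs: int = 150
    learning_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.loss_weights, dtype=float)
        if (w < 0).any():
            raise ValueError("loss weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"loss weights must sum to 1, got {w.sum()!r}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


def ae_loss(
    x: list[np.ndarray], x_hat: list[nn.Tensor | np.ndarray],
    weights: tuple[float, ...] = DEFAULT_WEIGHTS,
) -> nn.Tensor:
    """Weighted sum of per-modality mean squared reconstruction errors."""
    if not (len(x) == len(x_hat) == len(weights)):
        raise ValueError("x, x_hat and weights must have equal length")
    total = nn.Tensor(0.0)
    for xm, xh, w in zip(x, x_hat, weights):
        xh = xh if isinstance(xh, nn.Tensor) else nn.Tensor(xh)
        total = total + float(w) * nn.weighted_mse(np.asarray(xm, float), xh)
    return total


class MultimodalAutoencoder:
    """Four encoders -> concat -> shared latent -> four decoders."""

    def __init__(self, feature_dims: tuple[int, int, int, int], config: AEConfig):
        self.config = config
        self.feature_dims = tuple(feature_dims)
        rng = np.random.default_rng(config.seed)
        d = config.latent_dim
        if d > min(feature_dims):
            import warnings

            warnings.warn(
                f"latent_dim {d} exceeds the smallest modality width "
                f"{min(feature_dims)}", stacklevel=2,
            )
        self.encoders = []
        self.decoders = []
        hidden = [min(p, config.max_hidden) for p in feature_dims]
        for p, h in zip(feature_dims, hidden):
            self.encoders.append(nn.Linear(p, h, rng))
        self.to_latent = nn.Linear(sum(hidden), d, rng)
        for p, h in zip(feature_dims, hidden):
            self.decoders.append((nn.Linear(d, h, rng), nn.Linear(h, p, rng)))

    @property
    def params(self) -> list[nn.Parameter]:
        out = []
        for enc in self.encoders:
            out += enc.params
        out += self.to_latent.params
        for d1, d2 in self.decoders:
            out += d1.params + d2.params
        return out

    def encode(self, xs: list[np.ndarray]) -> nn.Tensor:
        hs = [nn.relu(enc(nn.Tensor(x))) for enc, x in zip(self.encoders, xs)]
        return self.to_latent(nn.concat(hs))

    def forward(self, xs: list[np.ndarray]) -> tuple[nn.Tensor, list[nn.Tensor]]:
        h = self.encode(xs)
        recon = [d2(nn.relu(d1(h))) for d1, d2 in self.decoders]
        return h, recon

    def fit(self, xs: list[np.ndarray], log: list[float] | None = None) -> "MultimodalAutoencoder":
        """Full-batch Adam on the weighted reconstruction loss."""
        opt = nn.Adam(self.params, lr=self.config.learning_rate)
        for epoch in range(self.config.epochs):
            opt.zero_grad()
            _, recon = self.forward(xs)
            loss = ae_loss(xs, recon, self.config.loss_weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite autoencoder loss at epoch {epoch}")
            loss.backward()
            opt.step()
            if log is not None:
                log.append(float(loss.data))
        return self

    def embed(self, xs: list[np.ndarray]) -> np.ndarray:
        return self.encode(xs).data


def fit_and_embed(
    dataset: MultiOmicsDataset | dict[Modality, OmicsMatrix],
    config: AEConfig | None = None,
    train_mask: np.ndarray | None = None,
    loss_log: list[float] | None = None,
) -> LatentEmbedding:
    """Train the autoencoder and embed every sample.

    ``train_mask`` restricts the training rows (e.g. to the training fold);
    the returned embedding always covers all samples. Deterministic for a
    given config seed.
    """
    config = config or AEConfig()
    omics = dataset.omics if isinstance(dataset, MultiOmicsDataset) else dataset
    mats = [omics[m] for m in Modality.ordered() if m in omics]
    ids = list(mats[0].sample_ids)
    xs_all = [m.values for m in mats]
    for x in xs_all:
        if not np.isfinite(x).all():
            raise ValueError("autoencoder input contains missing values; impute first")
    xs_train = xs_all if train_mask is None else [x[train_mask] for x in xs_all]
    model = MultimodalAutoencoder(tuple(x.shape[1] for x in xs_all), config)
    model.fit(xs_train, log=loss_log)
    return LatentEmbedding(sample_ids=ids, values=model.embed(xs_all), source="AE")
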