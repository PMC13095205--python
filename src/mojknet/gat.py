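"""Graph attention classifier over the concatenated final embedding.

The final patient representation is the column concatenation of the five
branch embeddings (four omics branches + the patient-level branch). A graph
attention layer on the fused consensus network then weights each patient's
neighbors adaptively:

    e_ij     = LeakyReLU( a^T [W h_i || W h_j] ),  j in N~(i)  (self included)
    alpha_ij = softmax_j(e_ij)
    h_i'     = ReLU( sum_j alpha_ij W h_j )

with multi-head attention (default 2 heads, concatenated) followed by a
linear softmax head. Attention uses the fused network's edge *structure*
(plus guaranteed self-loops); edge strengths are left to the learned
coefficients. The LeakyReLU negative slope of the attention logits is 0.2.

Training is transductive: full-graph forward, cross-entropy on training
nodes only, predictions read off for the test nodes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .datatypes import AffinityGraph, LatentEmbedding

__all__ = ["GATConfig", "concat_embeddings", "GATClassifier", "gat_attention",
           "train_gat"]

_NEG_INF = -1e9  # attention mask for non-edges


@dataclass
class GATConfig:
    hidden_dim: int = 100
    heads: int = 2
    leaky_slope: float = 0.2
    dropout: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heads < 1:
            raise ValueError("need at least one attention head")
        if not (0 < self.leaky_slope < 1):
            raise ValueError("leaky_slope must lie in (0, 1)")


def concat_embeddings(parts: list[LatentEmbedding]) -> LatentEmbedding:
    """Column-concatenate branch embeddings into the final representation."""
    if not parts:
        raise ValueError("no embeddings to concatenate")
    ids = list(parts[0].sample_ids)
    for p in parts[1:]:
        if list(p.sample_ids) != ids:
            raise ValueError("embeddings have misaligned sample ids")
    values = np.concatenate([p.values for p in parts], axis=1)
    return LatentEmbedding(sample_ids=ids, values=values, source="MOJKNET_FINAL")


def _edge_mask(graph: AffinityGraph | np.ndarray) -> np.ndarray:
    """Additive attention mask: 0 on edges and the diagonal, -1e9 elsewhere."""
    A = graph.weights if isinstance(graph, AffinityGraph) else np.asarray(graph, float)
    adj = A > 0
    np.fill_diagonal(adj, True)  # every node attends to itself
    return np.where(adj, 0.0, _NEG_INF)


class _Head:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.lin = nn.Linear(n_in, n_out, rng, bias=False)
        bound = np.sqrt(6.0 / (n_out + 1))
        self.a_src = nn.Parameter(rng.uniform(-bound, bound, size=(n_out, 1)))
        self.a_dst = nn.Parameter(rng.uniform(-bound, bound, size=(n_out, 1)))

    @property
    def params(self):
        return self.lin.params + [self.a_src, self.a_dst]


def gat_attention(
    h: np.ndarray | nn.Tensor,
    adjacency: AffinityGraph | np.ndarray,
    head: _Head,
    slope: float = 0.2,
    attn_dropout: nn.Tensor | None = None,
) -> tuple[nn.Tensor, nn.Tensor]:
    """Single-head attention pass; returns (node outputs, attention matrix).

    Attention rows are softmax-normalized over each node's neighborhood
    (self-loop included), so every row sums to 1.
    """
    h = h if isinstance(h, nn.Tensor) else nn.Tensor(h)
    Wh = head.lin(h)
    s_src = Wh @ head.a_src           # n x 1
    s_dst = Wh @ head.a_dst           # n x 1
    logits = nn.leaky_relu(s_src + s_dst.T, slope) + nn.Tensor(_edge_mask(adjacency))
    att = nn.softmax_rows(logits)
    if attn_dropout is not None:
        att = att * attn_dropout
    return att @ Wh, att


class GATClassifier:
    """One multi-head attention layer + linear softmax head."""

    def __init__(self, n_features: int, n_classes: int, config: GATConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.heads = [
            _Head(n_features, config.hidden_dim, rng) for _ in range(config.heads)
        ]
        self.out = nn.Linear(config.hidden_dim * config.heads, n_classes, rng)
        self._drop_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x6741]).generate_state(1)[0]
        )

    @property
    def params(self) -> list[nn.Parameter]:
        out = list(self.out.params)
        for hd in self.heads:
            out += hd.params
        return out

    def forward(self, X: np.ndarray, graph: AffinityGraph | np.ndarray,
                training: bool = False) -> tuple[nn.Tensor, list[nn.Tensor]]:
        x = nn.Tensor(X)
        if training and self.config.dropout > 0:
            x = x * nn.dropout_mask(self._drop_rng, x.shape, self.config.dropout)
        outs, atts = [], []
        n = X.shape[0]
        for hd in self.heads:
            adrop = None
            if training and self.config.dropout > 0:
                adrop = nn.dropout_mask(self._drop_rng, (n, n), self.config.dropout)
            o, a = gat_attention(x, graph, hd, self.config.leaky_slope, adrop)
            outs.append(o)
            atts.append(a)
        hidden = nn.relu(nn.concat(outs))
        if training and self.config.dropout > 0:
            hidden = hidden * nn.dropout_mask(self._drop_rng, hidden.shape,
                                              self.config.dropout)
        return self.out(hidden), atts


def train_gat(
    embedding: LatentEmbedding,
    fused: AffinityGraph,
    labels: np.ndarray,
    train_mask: np.ndarray,
    config: GATConfig,
    log: list[tuple[int, float]] | None = None,
    n_classes: int | None = None,
) -> tuple[np.ndarray, np.ndarray, "GATClassifier"]:
    """Train the classifier transductively.

    Returns (predicted class per node, class probabilities per node, model).
    Deterministic for a given config seed. ``n_classes`` defaults to the
    number implied by the training labels.
    """
    if list(embedding.sample_ids) != list(fused.sample_ids):
        raise ValueError("embedding and fused graph must share sample order")
    y = np.asarray(labels, dtype=np.int64)
    mask = np.asarray(train_mask, dtype=bool)
    if n_classes is None:
        n_classes = int(y.max()) + 1
    model = GATClassifier(embedding.d, n_classes, config)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    for epoch in range(config.epochs):
        opt.zero_grad()
        logits, _ = model.forward(embedding.values, fused, training=True)
        loss = nn.masked_cross_entropy(logits, y, mask)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite classifier loss at epoch {epoch}")
        loss.backward()
        opt.step()
        if log is not None:
            log.append((epoch, float(loss.data)))
    logits, _ = model.forward(embedding.values, fused, training=False)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    return logits.data.argmax(axis=1), probs, model


def attention_matrices(model: GATClassifier, embedding: LatentEmbedding,
                       fused: AffinityGraph) -> list[np.ndarray]:
    """Per-head attention coefficient matrices of the trained model."""
    _, atts = model.forward(embedding.values, fused, training=False)
    return [a.data for a in atts]
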