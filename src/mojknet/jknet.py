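"""Jumping-knowledge graph network branches.

Node update follows graph-convolution message passing on the weighted
patient graph with self-loops,

    H(l) = ReLU( A_hat @ H(l-1) @ W(l) + b(l) ),
    A_hat = D~^{-1/2} (A + I) D~^{-1/2},

so each layer mixes a patient's representation with its graph neighborhood
(the neighborhood includes the node itself). The jumping-knowledge step
then aggregates the representations of *all* depths 0..L into one final
representation — ``cat`` (column concatenation, the default) or ``max``
(elementwise maximum) — which preserves shallow, unsmoothed signal even
when L is large and thereby mitigates over-smoothing. ``last`` keeps only
layer L and reduces the branch to a plain GCN; it exists for the ablation
harness.

Layer 0 is a linear projection of the input features to the hidden width,
so raw omics blocks of ~10^4 features do not dwarf the hidden layers in the
concatenation.

Each branch is trained transductively: logits are computed for every
patient, but cross-entropy is averaged over training-fold patients only.
The branch's latent output is the pre-head jumping-knowledge aggregate for
all patients.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .datatypes import AffinityGraph, LatentEmbedding, Modality, MultiOmicsDataset

__all__ = ["JKConfig", "GraphBatch", "normalized_adjacency", "jk_layer",
           "jk_aggregate", "JKBranch", "train_jk_branch", "run_input1",
           "run_input2"]


@dataclass
class JKConfig:
    n_layers: int = 2
    hidden_dim: int = 100
    mode: str = "cat"              # cat | max | last (last = plain GCN)
    dropout: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one propagation layer")
        if self.mode not in ("cat", "max", "last"):
            raise ValueError(f"unknown jumping-knowledge mode {self.mode!r}")


@dataclass
class GraphBatch:
    features: np.ndarray
    adjacency: AffinityGraph
    labels: np.ndarray | None = None
    train_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.adjacency.n:
            raise ValueError("feature rows must align with adjacency sample ids")


def normalized_adjacency(graph: AffinityGraph | np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops on the weighted adjacency."""
    A = graph.weights if isinstance(graph, AffinityGraph) else np.asarray(graph, float)
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    A = A + np.eye(A.shape[0])
    d = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def jk_layer(h_prev: np.ndarray | nn.Tensor, adjacency: AffinityGraph | np.ndarray,
             W: np.ndarray | nn.Parameter) -> np.ndarray | nn.Tensor:
    """One propagation step: ReLU(A_hat @ h_prev @ W)."""
    A_hat = normalized_adjacency(adjacency)
    if isinstance(h_prev, nn.Tensor) or isinstance(W, nn.Parameter):
        h_prev = h_prev if isinstance(h_prev, nn.Tensor) else nn.Tensor(h_prev)
        W = W if isinstance(W, nn.Tensor) else nn.Tensor(W)
        out = nn.relu(nn.Tensor(A_hat) @ h_prev @ W)
        if not np.isfinite(out.data).all():
            raise FloatingPointError("non-finite propagation output")
        return out
    out = np.maximum(A_hat @ np.asarray(h_prev, float) @ np.asarray(W, float), 0.0)
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite propagation output")
    return out


def jk_aggregate(layer_outputs: list, mode: str = "cat"):
    """Aggregate per-depth representations h(0..L) into the final representation."""
    if not layer_outputs:
        raise ValueError("need at least one layer output")
    tensors = [h if isinstance(h, nn.Tensor) else nn.Tensor(h) for h in layer_outputs]
    if mode == "cat":
        out = nn.concat(tensors) if len(tensors) > 1 else tensors[0]
    elif mode == "max":
        widths = {t.shape[1] for t in tensors}
        if len(widths) != 1:
            raise ValueError("max-mode aggregation requires equal widths")
        out = tensors[0]
        for t in tensors[1:]:
            out = nn.maximum(out, t)
    elif mode == "last":
        out = tensors[-1]
    else:
        raise ValueError(f"unknown jumping-knowledge mode {mode!r}")
    if not any(isinstance(h, nn.Tensor) for h in layer_outputs):
        return out.data
    return out


class JKBranch:
    """JK stack with an auxiliary softmax head for branch-level supervision."""

    def __init__(self, n_features: int, n_classes: int, config: JKConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        self.proj = nn.Linear(n_features, h, rng)           # layer 0 (linear)
        self.layers = [nn.Linear(h, h, rng) for _ in range(config.n_layers)]
        agg_width = h * (config.n_layers + 1) if config.mode == "cat" else h
        self.head = nn.Linear(agg_width, n_classes, rng)
        self._drop_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x6A6B]).generate_state(1)[0]
        )

    @property
    def params(self) -> list[nn.Parameter]:
        out = self.proj.params + self.head.params
        for lay in self.layers:
            out += lay.params
        return out

    def forward(self, X: np.ndarray, A_hat: np.ndarray, training: bool = False):
        A = nn.Tensor(A_hat)
        h = self.proj(nn.Tensor(X))
        outs = [h]
        for lin in self.layers:
            h_in = outs[-1]
            if training and self.config.dropout > 0:
                h_in = h_in * nn.dropout_mask(self._drop_rng, h_in.shape,
                                              self.config.dropout)
            h_next = nn.relu(lin(A @ h_in))
            outs.append(h_next)
        agg = jk_aggregate(outs, self.config.mode)
        return agg, self.head(agg)


def train_jk_branch(
    batch: GraphBatch, config: JKConfig, source: str = "JK",
    log: list[tuple[int, float, float]] | None = None,
    n_classes: int | None = None,
) -> tuple[LatentEmbedding, dict]:
    """Train one branch transductively; return (latent for all nodes, report).

    The report carries training accuracy and, when some nodes fall outside
    the training mask, accuracy on those held-out nodes. ``n_classes``
    defaults to the number implied by the labels.
    """
    if batch.labels is None or batch.train_mask is None:
        raise ValueError("training a branch requires labels and a train mask")
    y = np.asarray(batch.labels, dtype=np.int64)
    mask = np.asarray(batch.train_mask, dtype=bool)
    if len(np.unique(y[mask])) < 2:
        raise ValueError("training mask covers a single class")
    if n_classes is None:
        n_classes = int(y.max()) + 1
    A_hat = normalized_adjacency(batch.adjacency)
    model = JKBranch(batch.features.shape[1], n_classes, config)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    for epoch in range(config.epochs):
        opt.zero_grad()
        _, logits = model.forward(batch.features, A_hat, training=True)
        loss = nn.masked_cross_entropy(logits, y, mask)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite branch loss at epoch {epoch}")
        loss.backward()
        opt.step()
        if log is not None:
            pred = logits.data.argmax(axis=1)
            log.append((epoch, float(loss.data), float((pred[mask] == y[mask]).mean())))
    agg, logits = model.forward(batch.features, A_hat, training=False)
    pred = logits.data.argmax(axis=1)
    report = {
        "train_accuracy": float((pred[mask] == y[mask]).mean()),
        "n_train": int(mask.sum()),
        "mode": config.mode,
        "n_layers": config.n_layers,
    }
    if (~mask).any():
        report["heldout_accuracy"] = float((pred[~mask] == y[~mask]).mean())
    ids = list(batch.adjacency.sample_ids)
    return LatentEmbedding(sample_ids=ids, values=agg.data, source=source), report


def run_input1(
    dataset: MultiOmicsDataset,
    graphs: dict[Modality, AffinityGraph],
    config: JKConfig,
    train_mask: np.ndarray,
    features: dict[Modality, np.ndarray] | None = None,
    modalities: tuple[Modality, ...] | None = None,
) -> tuple[dict[Modality, LatentEmbedding], dict[Modality, dict]]:
    """Train one JK branch per omics modality on raw features + its graph.

    ``features`` may supply standardized feature matrices; otherwise the
    dataset values are used directly. Per-branch seeds are derived from the
    config seed and modality name so branches are independent.
    """
    modalities = modalities or tuple(m for m in Modality.ordered() if m in dataset.omics)
    embeddings, reports = {}, {}
    for m in modalities:
        X = features[m] if features is not None else dataset.omics[m].values
        cfg = JKConfig(**{**config.__dict__,
                          "seed": _branch_seed(config.seed, m.value)})
        batch = GraphBatch(features=X, adjacency=graphs[m], labels=dataset.y,
                           train_mask=train_mask)
        emb, rep = train_jk_branch(batch, cfg, source=f"JK_{m.value}",
                                   n_classes=dataset.n_classes)
        embeddings[m], reports[m] = emb, rep
    return embeddings, reports


def run_input2(
    ae_latent: LatentEmbedding,
    fused: AffinityGraph,
    config: JKConfig,
    labels: np.ndarray,
    train_mask: np.ndarray,
    n_classes: int | None = None,
) -> tuple[LatentEmbedding, dict]:
    """Train the patient-level branch: autoencoder latent + fused network."""
    if list(ae_latent.sample_ids) != list(fused.sample_ids):
        raise ValueError("autoencoder latent and fused graph must align")
    cfg = JKConfig(**{**config.__dict__, "seed": _branch_seed(config.seed, "patient")})
    batch = GraphBatch(features=ae_latent.values, adjacency=fused, labels=labels,
                       train_mask=train_mask)
    emb, rep = train_jk_branch(batch, cfg, source="JK_patient",
                               n_classes=n_classes)
    return emb, rep


def _branch_seed(seed: int, name: str) -> int:
    import zlib

    return int((seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1))
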