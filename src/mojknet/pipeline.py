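"""End-to-end orchestration: preprocess -> graphs -> fusion -> branches -> classifier.

The pipeline is transductive: per-omics affinity graphs and the fused
consensus network are built once from all patients (globally standardized
features), and unlabeled test-fold patients participate in the graph
structure but never in any loss. Within each cross-validation fold,
feature standardization statistics, autoencoder training rows and all
supervised losses are restricted to the training fold.

One global seed fans out to per-stage seeds through a stage-name hash, so
every stage is independently reproducible.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import build_affinity_graph
from .autoencoder import AEConfig, fit_and_embed
from .datatypes import AffinityGraph, LatentEmbedding, Modality, MultiOmicsDataset, SplitPlan
from .evaluation import (MetricsReport, SurvivalTable, assign_risk_groups,
                         concordance_index, fold_confusion, logrank_test,
                         macro_metrics)
from .gat import GATConfig, concat_embeddings, train_gat
from .jknet import JKConfig, run_input1, run_input2
from .omics_io import make_splits, read_bundle, standardize_features
from .snf import fuse_graphs

__all__ = ["TrainConfig", "PipelineResult", "run_full", "run_ablation",
           "export_embeddings_pca", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed and the stage name."""
    return int((seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1))


@dataclass
class TrainConfig:
    """Every tunable of the pipeline with its selected default."""

    # graph construction / fusion
    knn_k: int = 20
    snf_mu: float = 0.5
    snf_iters: int = 20
    distance: str = "sqeuclidean"
    # autoencoder
    ae_weights: tuple[float, float, float, float] = (0.2, 0.2, 0.3, 0.3)
    ae_latent_dim: int = 100
    ae_epochs: int = 150
    ae_lr: float = 0.001
    # jumping-knowledge branches
    jk_hidden: int = 100
    jk_epochs: int = 150
    jk_lr: float = 0.001
    jk_dropout: float = 0.5
    jk_mode: str = "cat"
    input1_layers: int = 2       # 3 for the coadread profile
    input2_layers: int = 2       # 4 for the coadread profile
    # graph attention classifier
    gat_hidden: int = 100
    gat_epochs: int = 150
    gat_lr: float = 0.001
    gat_dropout: float = 0.5
    gat_heads: int = 2
    gat_alpha: float = 0.2
    # evaluation protocol
    n_folds: int = 5
    holdout: bool = False        # 75/25 stratified split instead of k-fold CV
    seed: int = 0
    profile: str = "default"     # "coadread" selects the deeper branch depths

    def __post_init__(self) -> None:
        if self.profile == "coadread":
            self.input1_layers = max(self.input1_layers, 3)
            self.input2_layers = max(self.input2_layers, 4)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "TrainConfig":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        for key in ("ae_weights",):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)


@dataclass
class PipelineResult:
    metrics: MetricsReport
    predictions: pd.DataFrame
    final_embedding: LatentEmbedding
    fused_graph: AffinityGraph
    survival: SurvivalTable | None
    survival_stats: dict | None
    snf_max_change: list[float]
    branch_reports: dict
    split: SplitPlan

    def metrics_json(self) -> str:
        payload = self.metrics.as_dict()
        if self.survival_stats:
            payload["survival"] = self.survival_stats
        payload["snf_final_max_change"] = self.snf_max_change[-1]
        return json.dumps(payload, indent=2, sort_keys=True)


def _standardize_all(dataset: MultiOmicsDataset,
                     train_mask: np.ndarray) -> dict[Modality, np.ndarray]:
    """Z-score every modality with statistics from the training rows."""
    out = {}
    for mod, mat in dataset.omics.items():
        train_ids = [s for s, m in zip(mat.sample_ids, train_mask) if m]
        out[mod] = standardize_features(mat.subset_samples(train_ids), mat).values
    return out


def build_graphs(dataset: MultiOmicsDataset, config: TrainConfig
                 ) -> tuple[dict[Modality, AffinityGraph], AffinityGraph, list[float]]:
    """Per-omics affinity graphs + fused consensus, from all patients.

    Cross-diffusion leaves the consensus network near-dense, so the copy
    used as graph *structure* downstream is k-NN re-sparsified: without
    this, neighborhood aggregation and attention span the whole cohort and
    wash out local similarity structure. The returned fused graph is the
    sparsified one; the dense consensus stays available via the fusion API.
    """
    full = np.ones(dataset.n_samples, dtype=bool)
    feats = _standardize_all(dataset, full)
    graphs = {}
    for mod in dataset.omics:
        mat = dataset.omics[mod]
        std = type(mat)(modality=mat.modality, sample_ids=list(mat.sample_ids),
                        feature_ids=list(mat.feature_ids), values=feats[mod],
                        missing_mask=np.zeros_like(mat.missing_mask))
        graphs[mod] = build_affinity_graph(std, k=config.knn_k, mu=config.snf_mu,
                                           metric=config.distance)
    fused, state = fuse_graphs([graphs[m] for m in Modality.ordered() if m in graphs],
                               k=config.knn_k, t_max=config.snf_iters)
    from .affinity import knn_sparsify

    fused_sparse = knn_sparsify(fused.weights, k=config.knn_k,
                                sample_ids=list(fused.sample_ids),
                                modality="fused", warn_disconnected=False)
    return graphs, fused_sparse, state.max_change


def _fold_embedding(
    dataset: MultiOmicsDataset,
    graphs: dict[Modality, AffinityGraph],
    fused: AffinityGraph,
    config: TrainConfig,
    train_mask: np.ndarray,
    exclude: set[str] = frozenset(),
    jk_mode: str | None = None,
    gcn_branches: set[str] = frozenset(),
) -> tuple[LatentEmbedding, dict]:
    """Train AE + branches for one fold and concatenate the kept embeddings.

    ``exclude`` drops branch embeddings by name ("CNA", ..., "Patients")
    before concatenation; ``gcn_branches`` switches the named branches
    ("input1"/"input2") to last-layer-only aggregation (plain GCN).
    """
    feats = _standardize_all(dataset, train_mask)
    mode = jk_mode or config.jk_mode
    ae_cfg = AEConfig(loss_weights=config.ae_weights, latent_dim=config.ae_latent_dim,
                      epochs=config.ae_epochs, learning_rate=config.ae_lr,
                      seed=stage_seed(config.seed, "autoencoder"))
    ae_latent = fit_and_embed(dataset, ae_cfg, train_mask=train_mask)

    jk1 = JKConfig(n_layers=config.input1_layers, hidden_dim=config.jk_hidden,
                   mode="last" if "input1" in gcn_branches else mode,
                   dropout=config.jk_dropout, learning_rate=config.jk_lr,
                   epochs=config.jk_epochs, seed=stage_seed(config.seed, "input1"))
    embs1, reports = run_input1(dataset, graphs, jk1, train_mask, features=feats)

    jk2 = JKConfig(n_layers=config.input2_layers, hidden_dim=config.jk_hidden,
                   mode="last" if "input2" in gcn_branches else mode,
                   dropout=config.jk_dropout, learning_rate=config.jk_lr,
                   epochs=config.jk_epochs, seed=stage_seed(config.seed, "input2"))
    emb2, rep2 = run_input2(ae_latent, fused, jk2, dataset.y, train_mask,
                            n_classes=dataset.n_classes)

    parts = []
    for mod in Modality.ordered():
        if mod in embs1 and mod.value not in exclude:
            parts.append(embs1[mod])
    if "Patients" not in exclude:
        parts.append(emb2)
    final = concat_embeddings(parts)
    report = {m.value: r for m, r in reports.items()}
    report["Patients"] = rep2
    return final, report


def run_full(
    dataset: MultiOmicsDataset | str | Path,
    config: TrainConfig | None = None,
    outdir: str | Path | None = None,
    exclude: set[str] = frozenset(),
    jk_mode: str | None = None,
    gcn_branches: set[str] = frozenset(),
) -> PipelineResult:
    """Run the full pipeline with per-fold training and transductive graphs.

    ``dataset`` may be an in-memory cohort or a bundle directory path.
    Writes metrics, predictions, embeddings, survival analysis and PCA
    coordinates under ``outdir`` when given.
    """
    config = config or TrainConfig()
    if not isinstance(dataset, MultiOmicsDataset):
        dataset = read_bundle(dataset)
    y = dataset.y
    n_classes = dataset.n_classes
    split = make_splits(dataset, n_folds=config.n_folds,
                        seed=stage_seed(config.seed, "splits"), stratified=True,
                        holdout=config.holdout)
    graphs, fused, snf_change = build_graphs(dataset, config)

    per_fold, confusions = [], []
    pred_rows = []
    branch_reports = {}
    for fold in split.test_folds:
        train_mask = split.train_mask(fold)
        test_mask = split.test_mask(fold)
        emb, reports = _fold_embedding(dataset, graphs, fused, config, train_mask,
                                       exclude=exclude, jk_mode=jk_mode,
                                       gcn_branches=gcn_branches)
        gat_cfg = GATConfig(hidden_dim=config.gat_hidden, heads=config.gat_heads,
                            leaky_slope=config.gat_alpha, dropout=config.gat_dropout,
                            learning_rate=config.gat_lr, epochs=config.gat_epochs,
                            seed=stage_seed(config.seed, f"gat_fold{fold}"))
        pred, probs, _ = train_gat(emb, fused, y, train_mask, gat_cfg,
                                   n_classes=n_classes)
        per_fold.append(macro_metrics(y[test_mask], pred[test_mask], n_classes))
        confusions.append(fold_confusion(y[test_mask], pred[test_mask], n_classes))
        branch_reports[f"fold{fold}"] = reports
        for i in np.flatnonzero(test_mask):
            pred_rows.append({
                "sample_id": dataset.sample_ids[i], "fold": fold,
                "true": int(y[i]), "predicted": int(pred[i]),
                **{f"p_class{c}": float(probs[i, c]) for c in range(n_classes)},
            })

    metrics = MetricsReport(per_fold=per_fold, confusions=confusions,
                            n_classes=n_classes)
    predictions = pd.DataFrame(pred_rows)

    # final model on all labeled patients, for visualization + survival
    full_mask = np.ones(dataset.n_samples, dtype=bool)
    final_emb, _ = _fold_embedding(dataset, graphs, fused, config, full_mask,
                                   exclude=exclude, jk_mode=jk_mode,
                                   gcn_branches=gcn_branches)

    survival_table, survival_stats = None, None
    if dataset.survival is not None:
        surv = dataset.survival
        ok = surv["observed"].to_numpy(bool) if "observed" in surv else np.ones(len(surv), bool)
        if ok.sum() >= 10:
            emb_ok = LatentEmbedding(
                sample_ids=[s for s, o in zip(dataset.sample_ids, ok) if o],
                values=final_emb.values[ok], source=final_emb.source)
            survival_table = assign_risk_groups(
                emb_ok, surv.loc[ok, "time"].to_numpy(float),
                surv.loc[ok, "event"].to_numpy(int),
                seed=stage_seed(config.seed, "survival"))
            chi2, p = logrank_test(survival_table)
            cidx = concordance_index(
                survival_table.table["risk_score"], survival_table.table["time"],
                survival_table.table["event"])
            survival_stats = {"logrank_chi2": chi2, "logrank_p": p, "c_index": cidx}

    result = PipelineResult(
        metrics=metrics, predictions=predictions, final_embedding=final_emb,
        fused_graph=fused, survival=survival_table, survival_stats=survival_stats,
        snf_max_change=snf_change, branch_reports=branch_reports, split=split,
    )
    if outdir is not None:
        _write_results(result, dataset, config, Path(outdir))
    return result


def _write_results(result: PipelineResult, dataset: MultiOmicsDataset,
                   config: TrainConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "metrics.json").write_text(result.metrics_json())
    (outdir / "config.json").write_text(config.to_json())
    result.predictions.to_csv(outdir / "predictions.csv", index=False)
    result.final_embedding.to_frame().to_csv(outdir / "embedding.csv")
    pca = export_embeddings_pca(result.final_embedding, dataset.y)
    pca.to_csv(outdir / "embedding_pca.csv", index=False)
    if result.survival is not None:
        result.survival.table.to_csv(outdir / "survival_groups.csv")


def run_ablation(
    dataset: MultiOmicsDataset | str | Path,
    config: TrainConfig | None = None,
    which: str = "exclude_one_omics",
) -> pd.DataFrame:
    """Ablation harnesses: modality knockouts, JK-vs-GCN, single branches.

    * ``exclude_one_omics``: one column per removed branch (CNA, MET, mRNA,
      RPPA, Patients) plus the all-modalities reference.
    * ``jk_vs_gcn_input1`` / ``jk_vs_gcn_input2``: jumping-knowledge
      aggregation vs last-layer-only (plain GCN) on the named branch.
    * ``single_branch``: classification from each branch embedding alone.
    """
    config = config or TrainConfig()
    if not isinstance(dataset, MultiOmicsDataset):
        dataset = read_bundle(dataset)
    rows = []

    def add(label: str, res: PipelineResult) -> None:
        mean, sd = res.metrics.mean, res.metrics.sd
        rows.append({
            "variant": label,
            "macro_precision_pct": round(100 * mean[0], 2),
            "macro_precision_sd_pct": round(100 * sd[0], 2),
            "macro_recall_pct": round(100 * mean[1], 2),
            "macro_recall_sd_pct": round(100 * sd[1], 2),
            "macro_f1_pct": round(100 * mean[2], 2),
            "macro_f1_sd_pct": round(100 * sd[2], 2),
        })

    branches = [m.value for m in Modality.ordered() if m in dataset.omics] + ["Patients"]
    if which == "exclude_one_omics":
        for name in branches:
            add(name, run_full(dataset, config, exclude={name}))
        add("All", run_full(dataset, config))
    elif which in ("jk_vs_gcn_input1", "jk_vs_gcn_input2"):
        branch = which.rsplit("_", 1)[1]
        add("JK", run_full(dataset, config))
        add("GCN", run_full(dataset, config, gcn_branches={branch}))
    elif which == "single_branch":
        for name in branches:
            others = set(branches) - {name}
            add(name, run_full(dataset, config, exclude=others))
    else:
        raise ValueError(f"unknown ablation {which!r}")
    return pd.DataFrame(rows)


def export_embeddings_pca(embedding: LatentEmbedding, labels: np.ndarray
                          ) -> pd.DataFrame:
    """First two principal components of the centered embedding, with labels."""
    from sklearn.decomposition import PCA

    X = embedding.values
    if X.shape[0] < 3:
        raise ValueError("PCA projection needs at least 3 samples")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("constant embedding; nothing to project")
    coords = PCA(n_components=2, random_state=0).fit_transform(X - X.mean(axis=0))
    return pd.DataFrame({
        "sample_id": embedding.sample_ids,
        "PC1": coords[:, 0],
        "PC2": coords[:, 1],
        "label": np.asarray(labels),
    })
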