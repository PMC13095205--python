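"""Classification metrics and survival analysis.

Classification is scored with macro-averaged precision, recall and F1
(unweighted mean over classes; a class never predicted contributes
precision 0), reported per fold and as mean +/- sd across folds.

Prognostic evaluation turns the final patient embedding into a scalar risk
score via a ridge-penalized Cox proportional-hazards head (linear predictor
of a partial-likelihood fit on a PCA-reduced embedding), splits patients
into high/low risk at the median score (ties to low), and compares the
groups with Kaplan-Meier curves, the log-rank chi-square test

    chi2 = (O1 - E1)^2 / V1        (1 df),

where O1/E1/V1 are the observed/expected event counts and hypergeometric
variance accumulated over event times in the high-risk group, and the
concordance index (fraction of comparable patient pairs whose risk ordering
matches their survival ordering; risk ties count 1/2).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_cindex
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .datatypes import LatentEmbedding

__all__ = ["MetricsReport", "SurvivalTable", "macro_metrics", "kaplan_meier",
           "logrank_test", "concordance_index", "cox_risk_scores",
           "assign_risk_groups"]


# ---------------------------------------------------------------------------
# classification metrics

@dataclass
class MetricsReport:
    """Per-fold macro metrics with mean and sd."""

    per_fold: list[tuple[float, float, float]]
    confusions: list[np.ndarray] = field(default_factory=list)
    n_classes: int = 0

    def _col(self, i: int) -> np.ndarray:
        return np.array([f[i] for f in self.per_fold])

    @property
    def mean(self) -> tuple[float, float, float]:
        return tuple(float(self._col(i).mean()) for i in range(3))

    @property
    def sd(self) -> tuple[float, float, float]:
        return tuple(float(self._col(i).std(ddof=1)) if len(self.per_fold) > 1 else 0.0
                     for i in range(3))

    def as_dict(self) -> dict:
        names = ("macro_precision", "macro_recall", "macro_f1")
        mean, sd = self.mean, self.sd
        out = {
            "n_folds": len(self.per_fold),
            "n_classes": self.n_classes,
            "per_fold": [
                {n: round(100 * v, 2) for n, v in zip(names, fold)}
                for fold in self.per_fold
            ],
        }
        for i, n in enumerate(names):
            out[n + "_mean_pct"] = round(100 * mean[i], 2)
            out[n + "_sd_pct"] = round(100 * sd[i], 2)
        return out


def macro_metrics(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int
) -> tuple[float, float, float]:
    """Macro-averaged (precision, recall, F1) over all ``n_classes`` classes."""
    y, p = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if y.min() < 0 or y.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
        raise ValueError("labels outside [0, n_classes)")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, p, labels=np.arange(n_classes), average="macro", zero_division=0
    )
    return float(prec), float(rec), float(f1)


def fold_confusion(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    return confusion_matrix(true_labels, predicted_labels, labels=np.arange(n_classes))


# ---------------------------------------------------------------------------
# survival

@dataclass
class SurvivalTable:
    """Per-patient survival with model risk scores and median-split groups."""

    table: pd.DataFrame  # columns: time, event, risk_score, risk_group

    def __post_init__(self) -> None:
        need = {"time", "event", "risk_score", "risk_group"}
        if not need <= set(self.table.columns):
            raise ValueError(f"survival table needs columns {sorted(need)}")
        if (self.table["time"] <= 0).any():
            raise ValueError("survival times must be positive")

    def group(self, which: str) -> pd.DataFrame:
        return self.table[self.table["risk_group"] == which]


def kaplan_meier(table: SurvivalTable | pd.DataFrame, group: str | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival curve S(t) for one risk group (or all patients).

    Returns (times, survival probabilities) including the t=0, S=1 anchor.
    """
    df = table.group(group) if isinstance(table, SurvivalTable) and group else (
        table.table if isinstance(table, SurvivalTable) else table)
    if len(df) == 0:
        raise ValueError("empty group")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    km = KaplanMeierFitter()
    km.fit(df["time"], event_observed=df["event"])
    sf = km.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(table: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test (high vs low risk): returns (chi2, p)."""
    hi, lo = table.group("high"), table.group("low")
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both risk groups must be non-empty")
    res = _ll_logrank(hi["time"], lo["time"],
                      event_observed_A=hi["event"], event_observed_B=lo["event"])
    return float(res.test_statistic), float(res.p_value)


def concordance_index(risk_scores, times, events) -> float:
    """C-index: concordant comparable pairs / all comparable pairs.

    A pair (i, j) with t_i < t_j and event_i = 1 is comparable; it is
    concordant when the shorter-lived patient carries the higher risk.
    Risk ties count 1/2.
    """
    risk = np.asarray(risk_scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if not (len(risk) == len(t) == len(e)):
        raise ValueError("inputs must align")
    # lifelines scores concordance of *higher prediction ~ longer survival*
    return float(_ll_cindex(t, -risk, e))


# ---------------------------------------------------------------------------
# risk scores from the learned embedding

def cox_risk_scores(
    X: np.ndarray, times: np.ndarray, events: np.ndarray,
    ridge: float = 0.1, lr: float = 0.05, n_iter: int = 500,
    return_model: bool = False,
):
    """Linear predictor of a ridge Cox proportional-hazards fit.

    Negative log partial likelihood with Breslow handling of tied event
    times, minimized by plain gradient descent; adequate for the low-
    dimensional standardized inputs this head receives. With
    ``return_model`` a callable scoring new samples is returned instead of
    the training-sample scores.
    """
    X = np.asarray(X, float)
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    n, p = X.shape
    # standardize columns for conditioning; constant columns drop out
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    order = np.argsort(-t, kind="stable")   # decreasing time
    Z, e_ord = Z[order], e[order]
    beta = np.zeros(p)
    for _ in range(n_iter):
        eta = Z @ beta
        eta -= eta.max()
        w = np.exp(eta)
        cum_w = np.cumsum(w)                       # risk-set sums (t_i <= current)
        cum_wz = np.cumsum(w[:, None] * Z, axis=0)
        grad = (Z - cum_wz / cum_w[:, None]) * e_ord[:, None]
        g = grad.sum(axis=0) - ridge * beta
        beta = beta + lr * g / max(e_ord.sum(), 1.0)
    if return_model:
        return lambda Xnew: ((np.asarray(Xnew, float) - mu) / sd) @ beta
    return ((np.asarray(X, float) - mu) / sd) @ beta


def assign_risk_groups(
    embedding: LatentEmbedding,
    times: np.ndarray,
    events: np.ndarray,
    seed: int = 0,
    n_components: int = 8,
) -> SurvivalTable:
    """Fit the Cox head on the embedding and median-split into risk groups.

    The embedding is first reduced by PCA (deterministic, at most
    ``n_components`` axes) for numerical conditioning. Risk scores are
    produced *out-of-fold*: the Cox head is fitted on four fifths of the
    patients and scores the held-out fifth, so a patient's own survival
    time never informs their score and the scores carry no in-sample
    optimism. Scores strictly above the median are "high" risk; ties go to
    "low".
    """
    from sklearn.decomposition import PCA
    from sklearn.model_selection import KFold

    t = np.asarray(times, float)
    e = np.asarray(events, int)
    X = embedding.values
    k = int(min(n_components, X.shape[0] - 1, X.shape[1]))
    if k >= 1 and k < X.shape[1]:
        X = PCA(n_components=k, random_state=seed).fit_transform(X)
    risk = np.empty(len(t))
    n_splits = min(5, len(t) // 2)
    if n_splits < 2:
        raise ValueError("too few patients for out-of-fold risk scoring")
    for train_idx, test_idx in KFold(n_splits=n_splits, shuffle=True,
                                     random_state=seed).split(X):
        head = cox_risk_scores(X[train_idx], t[train_idx], e[train_idx],
                               return_model=True)
        risk[test_idx] = head(X[test_idx])
    if np.ptp(risk) < 1e-12:
        raise ValueError(
            "degenerate (constant) risk scores; inspect the embedding and "
            "survival inputs"
        )
    med = np.median(risk)
    group = np.where(risk > med, "high", "low")
    df = pd.DataFrame(
        {"time": t, "event": e, "risk_score": risk, "risk_group": group},
        index=embedding.sample_ids,
    )
    return SurvivalTable(table=df)
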