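"""Held-out performance metrics, per-gene ROC, pooled fold changes, PCA.

AUC here is the probability that a randomly chosen positive (fibrosis)
sample scores above a randomly chosen negative one, with ties counted half —
identical to the trapezoidal area under the ROC curve and to the
Mann–Whitney U statistic divided by n1*n2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .exceptions import MetricError
from .expression import ExpressionMatrix, log_transform
from .screen import welch_t


def auc_score(labels, scores) -> float:
    """All-pairs AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(labels) != len(scores):
        raise MetricError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise MetricError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


@dataclass
class EvalReport:
    """ROC/PR curves, confusion matrix and accuracy for one classifier track."""

    roc_points: np.ndarray      # (n, 2) of (FPR, TPR)
    auc: float
    pr_points: np.ndarray       # (n, 2) of (recall, precision)
    confusion: np.ndarray       # rows = truth (WH, F), cols = predicted
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "roc_points": self.roc_points.tolist(),
            "pr_points": self.pr_points.tolist(),
        }


def confusion_and_pr(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Evaluate continuous fibrosis scores against binary truth.

    ``predicted = scores >= threshold``. Confusion rows are truth
    (WH=0 first), columns predicted.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise MetricError("evaluation needs both classes in the holdout")
    predicted = (scores >= threshold).astype(int)
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    cm = confusion_matrix(labels, predicted, labels=[0, 1])
    return EvalReport(
        roc_points=np.column_stack([fpr, tpr]),
        auc=auc_score(labels, scores),
        pr_points=np.column_stack([recall[::-1], precision[::-1]]),
        confusion=cm,
        accuracy=float(np.trace(cm) / cm.sum()),
    )


def per_gene_roc(holdout: ExpressionMatrix, gene: str) -> tuple[float, str]:
    """Single-gene AUC on the holdout, orientation-corrected.

    Uses the gene's expression as the score; returns ``(auc, direction)``
    where direction is "F_high" when fibrosis samples score higher, "F_low"
    otherwise, and "flat" for a constant gene (AUC 0.5).
    """
    if gene not in holdout.gene_ids:
        raise KeyError(f"gene {gene!r} not in matrix")
    x = holdout.values.loc[gene].to_numpy(dtype=float)
    if np.all(x == x[0]):
        return 0.5, "flat"
    raw = auc_score(holdout.y, x)
    if raw >= 0.5:
        return raw, "F_high"
    return 1.0 - raw, "F_low"


def pooled_log2fc(
    m: ExpressionMatrix, gene: str, offset: float = 1.0
) -> dict:
    """Pooled fibrosis-vs-wound-healing fold change for one gene.

    ``log2fc = log2(mean over F samples / mean over WH samples)`` on the
    linear (FPKM) scale, pooling all days. When either pooled mean is zero
    the configured offset is added inside the ratio and the record flagged.
    The Welch p-value is computed on per-sample ``log2(value + offset)``.
    """
    if gene not in m.gene_ids:
        raise KeyError(f"gene {gene!r} not in matrix")
    vals = m.values.loc[gene].to_numpy(dtype=float)
    f, wh = vals[m.condition_mask("F")], vals[m.condition_mask("WH")]
    mean_f, mean_wh = float(f.mean()), float(wh.mean())
    flagged = mean_f == 0 or mean_wh == 0
    if flagged:
        log2fc = float(np.log2((mean_f + offset) / (mean_wh + offset)))
    else:
        log2fc = float(np.log2(mean_f / mean_wh))
    _, _, p = welch_t(np.log2(f + offset), np.log2(wh + offset))
    return {
        "gene_id": gene,
        "mean_F": mean_f,
        "mean_WH": mean_wh,
        "log2fc": log2fc,
        "p_value": p,
        "zero_mean_offset_applied": flagged,
    }


def condition_log2_ci(
    m: ExpressionMatrix, gene: str, offset: float = 1.0, level: float = 0.95
) -> pd.DataFrame:
    """Per-condition mean of log2(value+offset) with a t-based CI (bar-plot data)."""
    rows = []
    vals = m.values.loc[gene].to_numpy(dtype=float)
    for cond in ("WH", "F"):
        x = np.log2(vals[m.condition_mask(cond)] + offset)
        n = len(x)
        mean = x.mean()
        se = x.std(ddof=1) / np.sqrt(n)
        half = stats.t.ppf(0.5 + level / 2, df=n - 1) * se
        rows.append({"condition": cond, "mean_log2": mean, "ci_low": mean - half,
                     "ci_high": mean + half, "n": n})
    return pd.DataFrame(rows)


def pca_projection(m: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """First two principal components of the samples (QC for class separation).

    Genes are mean-centered; input should already be on a log scale. Returns
    per-sample coordinates and the fraction of variance explained per PC.
    """
    if m.n_samples < 3:
        raise MetricError("PCA needs at least 3 samples")
    X = m.X  # samples x genes
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    frame = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "PC1": coords[:, 0],
            "PC2": coords[:, 1],
            "condition": m.condition.to_numpy(),
            "day": m.day.to_numpy(),
        }
    ).set_index("sample_id")
    return frame, pca.explained_variance_ratio_


def log2_fpkm_export(m: ExpressionMatrix, genes, offset: float = 1.0) -> pd.DataFrame:
    """log2(FPKM+offset) table for a gene panel (heatmap/visualization export)."""
    sub = m.subset_genes(list(genes))
    return log_transform(sub, offset).values
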