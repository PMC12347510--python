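"""Permutation feature importance measured as out-of-fold AUC drop.

One engine serves both the SVM and random-forest tracks: the classifier is
fitted once per stratified training fold, a baseline out-of-fold AUC is
recorded, and each candidate feature is then shuffled across samples
(others held fixed) to measure the mean drop in that AUC. The AUC is
averaged over folds (not pooled), so decision-function scales that differ
between folds cannot distort the baseline. Importance is computed on
training data only — never the holdout — so feature pruning cannot leak
validation information.

Degenerate probes: with very strong, mutually redundant features the
out-of-fold AUC can sit at 1.0 and stay there under every permutation of
every probed feature — the probe then carries no evidence against any gene.
When that happens (every probed gene has drop exactly 0 with zero spread)
the probed panel is retained unchanged and a warning is logged; a zero drop
for an individual gene while others register drops still means "not
retained", matching the pruning rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImportanceScore:
    gene_id: str
    mean_auc_drop: float
    sd_auc_drop: float
    retained: bool


def _score_samples(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def permutation_importance_auc(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    gene_ids,
    probe_genes=None,
    n_permutations: int = 100,
    n_folds: int = 3,
    seed: int = 0,
) -> list[ImportanceScore]:
    """Per-feature permutation importance as mean out-of-fold AUC drop.

    Parameters
    ----------
    estimator : sklearn classifier (unfitted template)
        Cloned and fitted per stratified fold on all columns of ``X``.
    X, y : arrays
        Training design matrix (samples x genes in ``gene_ids``) and labels.
    gene_ids : sequence of str
        Column names of ``X`` (the model's feature set).
    probe_genes : sequence of str, optional
        Genes to score; defaults to all of ``gene_ids``. A probe gene outside
        the model's feature set has importance exactly 0 (the model never
        sees it).

    Notes
    -----
    Importance of gene g = baseline fold-averaged OOF AUC − mean over
    ``n_permutations`` seeded shuffles of g's column of the permuted AUC.
    A constant column shuffles to itself, so its importance is exactly 0;
    such genes are flagged not-retained.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    gene_ids = [str(g) for g in gene_ids]
    probe_genes = gene_ids if probe_genes is None else [str(g) for g in probe_genes]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    folds = [
        (tr, te, clone(estimator).fit(X[tr], y[tr])) for tr, te in skf.split(X, y)
    ]

    baseline = np.mean(
        [roc_auc_score(y[te], _score_samples(mdl, X[te])) for _, te, mdl in folds]
    )
    col = {g: j for j, g in enumerate(gene_ids)}

    results: dict[str, tuple[float, float]] = {}
    for gene in probe_genes:
        j = col.get(gene)
        if j is None or np.all(X[:, j] == X[0, j]):
            # outside the model's feature set, or constant: shuffling is a no-op
            results[gene] = (0.0, 0.0)
            continue
        perms = np.stack([rng.permutation(X[:, j]) for _ in range(n_permutations)])
        # batched scoring: one predict per fold covering all permutations
        fold_aucs = np.zeros((n_folds, n_permutations))
        for fi, (_, te, mdl) in enumerate(folds):
            Xte = X[te]
            tiled = np.repeat(Xte[None, :, :], n_permutations, axis=0)
            tiled[:, :, j] = perms[:, te]
            scores = _score_samples(mdl, tiled.reshape(-1, d)).reshape(
                n_permutations, len(te)
            )
            yte = y[te]
            for k in range(n_permutations):
                fold_aucs[fi, k] = roc_auc_score(yte, scores[k])
        drops = baseline - fold_aucs.mean(axis=0)
        results[gene] = (float(drops.mean()), float(drops.std(ddof=0)))

    flat_probe = all(mu == 0.0 and sd == 0.0 for mu, sd in results.values())
    out: list[ImportanceScore] = []
    for gene in probe_genes:
        mu, sd = results[gene]
        in_model = gene in col and not np.all(X[:, col[gene]] == X[0, col[gene]])
        retained = mu > 0 or (flat_probe and in_model)
        out.append(ImportanceScore(gene, mu, sd, retained))
    if flat_probe and any(s.retained for s in out):
        logger.warning(
            "permutation probe was flat (OOF AUC saturated); retaining the "
            "probed panel unchanged"
        )
    return out


def importance_frame(scores: list[ImportanceScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "mean_auc_drop": [s.mean_auc_drop for s in scores],
            "sd_auc_drop": [s.sd_auc_drop for s in scores],
            "retained": [s.retained for s in scores],
        }
    ).set_index("gene_id")
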