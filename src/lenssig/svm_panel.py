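"""Linear-SVM gene ranking, permutation pruning, and a calibrated RBF classifier.

Stage one fits a single linear soft-margin SVM on the screened, z-scored
training matrix and ranks genes by the absolute magnitude of their weights.
Stage two computes permutation importance (out-of-fold AUC drop; see
:mod:`lenssig.importance`) for the top ``top_k`` genes and drops any whose
mean drop is not strictly positive. Stage three fits an RBF-kernel SVM on
the retained panel, with Platt-sigmoid probability calibration by K-fold
fitting on training data only.

Sign convention for decision values: negative predicts fibrosis, positive
predicts wound healing.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .exceptions import ParameterError
from .expression import ExpressionMatrix
from .importance import ImportanceScore, importance_frame, permutation_importance_auc
from .stability_lasso import _standardize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SvmParams:
    top_k: int = 5
    C: float = 1.0
    rbf_gamma: float | str = "scale"   # sklearn's 1/(d * mean feature variance)
    n_permutations: int = 100
    calibration_folds: int = 3
    importance_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1 or self.C <= 0:
            raise ParameterError("top_k >= 1 and C > 0 required")
        if isinstance(self.rbf_gamma, str) and self.rbf_gamma != "scale":
            raise ParameterError("rbf_gamma must be 'scale' or a positive real")


@dataclass
class SvmPanelResults:
    """Fitted SVM track: ranking, importances, panel, calibrated classifier."""

    model: "SvmPanel"
    ranking: pd.Series                      # |w_g|, descending
    importances: list[ImportanceScore]
    panel: list[str]                        # retained genes (importance > 0)
    _clf: CalibratedClassifierCV | None = None
    _raw_svc: SVC | None = None
    _mean: np.ndarray | None = None
    _sd: np.ndarray | None = None
    _panel_idx: list[int] = field(default_factory=list)

    @property
    def has_panel(self) -> bool:
        return bool(self.panel)

    def _panel_X(self, m: ExpressionMatrix) -> np.ndarray:
        X = m.subset_genes(self.panel).X
        return (X - self._mean) / np.where(self._sd > 0, self._sd, 1.0)

    def prob_WH(self, m: ExpressionMatrix) -> np.ndarray:
        """Calibrated P(wound healing) per sample (0.5 when no panel)."""
        return 1.0 - self.predict_proba(m)

    def predict_proba(self, m: ExpressionMatrix) -> np.ndarray:
        """Calibrated P(fibrosis) per sample."""
        if self._clf is None:
            return np.full(m.n_samples, 0.5)
        return self._clf.predict_proba(self._panel_X(m))[:, 1]

    def decision_value(self, m: ExpressionMatrix) -> np.ndarray:
        """Signed distance to the RBF margin; negative side = fibrosis."""
        if self._raw_svc is None:
            return np.zeros(m.n_samples)
        # libsvm's positive side is class 1 (fibrosis); flip to the figure
        # convention: negative predicts F, positive predicts WH.
        return -self._raw_svc.decision_function(self._panel_X(m))

    def importance_frame(self) -> pd.DataFrame:
        return importance_frame(self.importances)

    def summary(self) -> str:
        k = self.model.params.top_k
        lines = [
            "Linear-SVM ranking + calibrated RBF classifier",
            "=" * 48,
            f"top-{k} by |coefficient|:",
        ]
        for g in self.ranking.index[:k]:
            lines.append(f"  {g:<20s} |w|={self.ranking[g]:.4f}")
        lines.append("permutation importance (OOF AUC drop):")
        for s in self.importances:
            tag = "kept" if s.retained else "dropped"
            lines.append(f"  {s.gene_id:<20s} {s.mean_auc_drop:+.4f} ({tag})")
        lines.append(f"final RBF panel: {', '.join(self.panel) or '(empty)'}")
        return "\n".join(lines)


class SvmPanel:
    """SVM feature-selection track built from a screened training matrix."""

    def __init__(self, train: ExpressionMatrix, params: SvmParams | None = None):
        self.train = train
        self.params = params or SvmParams()
        if len(np.unique(train.y)) < 2:
            raise ParameterError("training data must contain both classes")
        if self.params.top_k > train.n_genes:
            raise ParameterError("top_k exceeds the number of screened genes")

    def rank_linear_svm(self) -> pd.Series:
        """|w_g| from one linear SVM fit, descending; ties broken by gene id."""
        X, y = self.train.X, self.train.y
        Xs, _, _ = _standardize(X)
        svc = SVC(kernel="linear", C=self.params.C, tol=1e-7, random_state=0)
        svc.fit(Xs, y)
        w = np.abs(svc.coef_.ravel())
        s = pd.Series(w, index=self.train.gene_ids.astype(str), name="abs_coef")
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return s.loc[order]

    def fit(self) -> SvmPanelResults:
        p = self.params
        ranking = self.rank_linear_svm()
        top = list(ranking.index[: p.top_k])

        sub = self.train.subset_genes(top)
        Xs, mu, sd = _standardize(sub.X)
        y = sub.y
        template = SVC(kernel="rbf", C=p.C, gamma=p.rbf_gamma, random_state=0)
        scores = permutation_importance_auc(
            template,
            Xs,
            y,
            top,
            n_permutations=p.n_permutations,
            n_folds=p.importance_folds,
            seed=p.seed,
        )
        panel = [s.gene_id for s in scores if s.retained]
        res = SvmPanelResults(self, ranking, scores, panel)
        if not panel:
            logger.warning("SVM track: no gene survived permutation pruning")
            return res

        psub = self.train.subset_genes(panel)
        Xp, mu, sd = _standardize(psub.X)
        res._mean, res._sd = mu, sd
        folds = p.calibration_folds
        min_class = int(min(np.bincount(y, minlength=2)))
        if min_class < folds:
            logger.warning("calibration folds reduced from %d to %d", folds, min_class)
            folds = max(2, min_class)
        base = SVC(kernel="rbf", C=p.C, gamma=p.rbf_gamma, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny folds trigger benign convergence chatter
            clf = CalibratedClassifierCV(base, method="sigmoid", cv=folds)
            clf.fit(Xp, y)
        res._clf = clf
        res._raw_svc = SVC(kernel="rbf", C=p.C, gamma=p.rbf_gamma, random_state=0).fit(Xp, y)
        logger.info("SVM track: panel of %d genes", len(panel))
        return res


# -- thin functional surface ------------------------------------------------

def rank_linear_svm(train: ExpressionMatrix, params: SvmParams | None = None) -> pd.Series:
    return SvmPanel(train, params).rank_linear_svm()


def fit_calibrated_rbf(
    train: ExpressionMatrix, genes, params: SvmParams | None = None
) -> SvmPanelResults:
    """Fit the calibrated RBF classifier directly on a given gene panel."""
    genes = [str(g) for g in genes]
    if not genes:
        raise ParameterError("gene panel must be non-empty")
    params = params or SvmParams()
    sub = train.subset_genes(genes)
    if params.top_k > len(genes):
        params = dataclasses.replace(params, top_k=len(genes))
    model = SvmPanel(sub, params)
    scores = [ImportanceScore(g, np.nan, np.nan, True) for g in genes]
    res = SvmPanelResults(model, pd.Series(np.nan, index=genes), scores, genes)
    Xp, mu, sd = _standardize(sub.X)
    res._mean, res._sd = mu, sd
    y = sub.y
    folds = min(params.calibration_folds, int(min(np.bincount(y, minlength=2))))
    folds = max(2, folds)
    base = SVC(kernel="rbf", C=params.C, gamma=params.rbf_gamma, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = CalibratedClassifierCV(base, method="sigmoid", cv=folds)
        clf.fit(Xp, y)
    res._clf = clf
    res._raw_svc = SVC(kernel="rbf", C=params.C, gamma=params.rbf_gamma, random_state=0).fit(Xp, y)
    return res
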