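"""Random-forest track: Gini ranking, permutation confirmation, reduced refit.

A forest of classification trees (50% of features considered at each split)
is fitted on the screened training matrix; genes are ranked by mean decrease
in Gini impurity (normalized to sum to 1). The top ``top_k_examine`` genes
are probed with out-of-fold permutation AUC importance, and the final panel
is the ``top_k_final`` genes by Gini among those with strictly positive
permutation importance. A reduced forest refit on the panel supplies holdout
probabilities (fraction of trees voting fibrosis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .exceptions import ParameterError
from .expression import ExpressionMatrix
from .importance import ImportanceScore, importance_frame, permutation_importance_auc

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RfParams:
    n_trees: int = 500
    max_features_fraction: float = 0.5
    max_depth: int | None = None
    top_k_examine: int = 10
    top_k_final: int = 3
    n_permutations: int = 100
    importance_folds: int = 3
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.max_features_fraction <= 1:
            raise ParameterError("max_features_fraction must lie in (0, 1]")
        if self.top_k_final > self.top_k_examine:
            raise ParameterError("top_k_final must not exceed top_k_examine")


@dataclass
class ForestPanelResults:
    """Fitted RF track: Gini importances, permutation scores, reduced forest."""

    model: "ForestPanel"
    gini_importance: pd.Series          # normalized, descending
    importances: list[ImportanceScore]  # for the examined top genes
    panel: list[str]
    _forest: RandomForestClassifier | None = None
    _reduced: RandomForestClassifier | None = None

    @property
    def has_panel(self) -> bool:
        return bool(self.panel)

    def predict_proba(self, m: ExpressionMatrix) -> np.ndarray:
        """P(fibrosis) from the reduced forest (0.5 everywhere if no panel)."""
        if self._reduced is None:
            return np.full(m.n_samples, 0.5)
        X = m.subset_genes(self.panel).X
        return self._reduced.predict_proba(X)[:, 1]

    def importance_frame(self) -> pd.DataFrame:
        return importance_frame(self.importances)

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Random-forest Gini selection",
            "=" * 48,
            f"trees: {p.n_trees}   features/split: {p.max_features_fraction:.0%}",
            f"top-{p.top_k_examine} by Gini importance:",
        ]
        for g in self.gini_importance.index[: p.top_k_examine]:
            lines.append(f"  {g:<20s} gini={self.gini_importance[g]:.4f}")
        lines.append("permutation confirmation (OOF AUC drop):")
        for s in self.importances:
            tag = "kept" if s.retained else "dropped"
            lines.append(f"  {s.gene_id:<20s} {s.mean_auc_drop:+.4f} ({tag})")
        lines.append(f"final panel: {', '.join(self.panel) or '(empty)'}")
        return "\n".join(lines)


class ForestPanel:
    """Random-forest feature-selection track built from training data."""

    def __init__(self, train: ExpressionMatrix, params: RfParams | None = None):
        self.train = train
        self.params = params or RfParams()
        if len(np.unique(train.y)) < 2:
            raise ParameterError("training data must contain both classes")

    def _make_forest(self) -> RandomForestClassifier:
        p = self.params
        return RandomForestClassifier(
            n_estimators=p.n_trees,
            max_features=p.max_features_fraction,
            max_depth=p.max_depth,
            bootstrap=p.bootstrap,
            random_state=p.seed % (2**31),
        )

    def fit_rf(self) -> tuple[RandomForestClassifier, pd.Series]:
        """Full-matrix forest and its normalized Gini importances (descending)."""
        forest = self._make_forest().fit(self.train.X, self.train.y)
        imp = forest.feature_importances_  # sklearn already normalizes to sum 1
        s = pd.Series(imp, index=self.train.gene_ids.astype(str), name="gini")
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return forest, s.loc[order]

    def fit(self) -> ForestPanelResults:
        p = self.params
        forest, gini = self.fit_rf()
        examine = list(gini.index[: min(p.top_k_examine, len(gini))])

        sub = self.train.subset_genes(examine)
        scores = permutation_importance_auc(
            self._make_forest(),
            sub.X,
            sub.y,
            examine,
            n_permutations=p.n_permutations,
            n_folds=p.importance_folds,
            seed=p.seed,
        )
        positive = {s.gene_id for s in scores if s.retained}
        panel = [g for g in examine if g in positive][: p.top_k_final]
        if len(panel) < p.top_k_final:
            logger.warning(
                "RF panel shrank to %d gene(s): only those had positive "
                "permutation importance",
                len(panel),
            )
        res = ForestPanelResults(self, gini, scores, panel, _forest=forest)
        if panel:
            res._reduced = self._make_forest().fit(
                self.train.subset_genes(panel).X, self.train.y
            )
        logger.info("RF track: panel of %d genes", len(panel))
        return res


def fit_rf(train: ExpressionMatrix, params: RfParams | None = None):
    """Functional surface: forest plus normalized Gini importances."""
    return ForestPanel(train, params).fit_rf()
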