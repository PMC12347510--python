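"""Bootstrap stability selection with L1-penalized logistic regression.

The track has two stages. Stage one repeats, ``n_bootstrap`` times, a
stratified 75% subsample of the training samples (without replacement),
z-scores genes on that subsample, fits an L1-logistic ("LASSO") model at a
penalty chosen by fast internal cross-validation, and records which genes
received nonzero coefficients. A gene's selection frequency is the fraction
of bootstraps in which it was selected; genes at or above ``freq_threshold``
form the *stable* set. Stage two refits an L1-logistic path on the stable
genes only, picks the penalty by K-fold stratified cross-validated binomial
deviance, and refits once on all training data; genes keeping nonzero
coefficients are the final sparse panel.

Model/Results layout: build :class:`StabilityLasso` from a training
:class:`~lenssig.expression.ExpressionMatrix`, call :meth:`~StabilityLasso.fit`,
and read frequencies, the stable set, the final coefficients and holdout
predictions off the returned :class:`StabilityLassoResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .exceptions import ParameterError, SelectionEmptyError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

_MAX_SUBSAMPLE_RETRIES = 20


@dataclass(frozen=True)
class StabilityParams:
    """Knobs of the stability-selection track.

    ``lambda_grid`` defaults to 100 log-spaced penalties from the data-driven
    lambda_max (smallest penalty with empty support) down three decades.
    Inside each bootstrap the penalty is chosen by 3-fold CV over a coarse
    sub-grid (every ``bootstrap_grid_stride``-th value) for speed; the final
    refit searches the full grid.
    """

    n_bootstrap: int = 200
    subsample_fraction: float = 0.75
    freq_threshold: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 3
    bootstrap_grid_stride: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction < 1:
            raise ParameterError("subsample_fraction must lie in (0, 1)")
        if not 0 < self.freq_threshold <= 1:
            raise ParameterError("freq_threshold must lie in (0, 1]")
        if self.n_bootstrap < 1 or self.cv_folds < 2 or self.n_lambda < 2:
            raise ParameterError("n_bootstrap >= 1, cv_folds >= 2, n_lambda >= 2 required")


def _standardize(X: np.ndarray, mean=None, sd=None):
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd


def lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty zeroing every coefficient of the L1-logistic path.

    From the KKT condition at the null model (intercept only):
    ``lambda_max = max_j |x_j' (y - ybar)| / n`` on standardized features.
    """
    n = len(y)
    resid = y - y.mean()
    return float(np.abs(X_std.T @ resid).max() / n)


def _lasso_fit(X_std: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # liblinear minimizes C * sum(loss) + ||w||_1; mean-loss penalty lam -> C = 1/(n*lam)
    C = 1.0 / (len(y) * lam)
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-6,
        random_state=0,
    )
    return model.fit(X_std, y)


try:  # low-overhead path for the bootstrap loop (thousands of tiny fits)
    from sklearn.svm._base import _fit_liblinear as _liblinear_train
except ImportError:  # pragma: no cover - fall back to the estimator API
    _liblinear_train = None


def _lasso_coefs(X_std: np.ndarray, y: np.ndarray, lam: float):
    """(coef, intercept) of the L1-logistic fit at penalty ``lam``."""
    if _liblinear_train is None:  # pragma: no cover
        m = _lasso_fit(X_std, y, lam)
        return m.coef_.ravel(), float(m.intercept_[0])
    C = 1.0 / (len(y) * lam)
    coef, intercept, _ = _liblinear_train(
        X_std, y, C, fit_intercept=True, intercept_scaling=1.0,
        class_weight=None, penalty="l1", dual=False, verbose=0,
        max_iter=2000, tol=1e-6, random_state=0,
        multi_class="ovr", loss="logistic_regression",
    )
    return coef.ravel(), float(np.asarray(intercept).ravel()[0])


def _binomial_deviance(X, y, coef, intercept) -> float:
    eta = X @ coef + intercept
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = np.finfo(float).eps
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _cv_deviance(X_std, y, grid, n_folds, seed) -> np.ndarray:
    """Mean cross-validated binomial deviance for each penalty in ``grid``.

    ``X_std`` is expected to be standardized already; folds reuse that
    scaling (re-standardizing on 4-sample folds only adds noise).
    """
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    dev = np.zeros(len(grid))
    for tr, te in skf.split(X_std, y):
        for i, lam in enumerate(grid):
            coef, intercept = _lasso_coefs(X_std[tr], y[tr], lam)
            dev[i] += _binomial_deviance(X_std[te], y[te], coef, intercept)
    return dev / n_folds


@dataclass
class StabilityLassoResults:
    """Fitted stability-selection track.

    Attributes
    ----------
    selection_frequencies : pandas.Series
        Per-gene fraction of bootstraps with a nonzero coefficient.
    stable_genes : list of str
        Genes with frequency >= threshold, ordered by descending frequency
        then gene id.
    selected_genes : list of str
        Genes with nonzero coefficients in the final cross-validated refit
        (empty when the stable set was empty).
    coef_ : pandas.Series
        Final coefficients on the standardized scale, indexed by stable gene.
    """

    model: "StabilityLasso"
    selection_frequencies: pd.Series
    stable_genes: list[str]
    lambda_: float | None = None
    intercept_: float | None = None
    coef_: pd.Series | None = None
    selected_genes: list[str] = field(default_factory=list)
    _train_mean: np.ndarray | None = None
    _train_sd: np.ndarray | None = None

    @property
    def has_panel(self) -> bool:
        return bool(self.selected_genes)

    def predict_proba(self, m: ExpressionMatrix) -> np.ndarray:
        """P(fibrosis) for each sample; 0.5 everywhere if no panel survived."""
        if self.coef_ is None:
            return np.full(m.n_samples, 0.5)
        X = m.subset_genes(self.stable_genes).X
        Xs = (X - self._train_mean) / np.where(self._train_sd > 0, self._train_sd, 1.0)
        eta = self.intercept_ + Xs @ self.coef_.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def frequency_frame(self) -> pd.DataFrame:
        return self.selection_frequencies.rename("frequency").to_frame()

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Stability-selection LASSO",
            "=" * 48,
            f"bootstraps: {p.n_bootstrap}   subsample: {p.subsample_fraction:.0%}"
            f"   threshold: {p.freq_threshold}",
            f"stable genes ({len(self.stable_genes)}):",
        ]
        for g in self.stable_genes:
            lines.append(f"  {g:<20s} freq={self.selection_frequencies[g]:.3f}")
        if self.coef_ is not None:
            lines.append(f"final refit at lambda*={self.lambda_:.4g}:")
            for g in self.selected_genes:
                lines.append(f"  {g:<20s} beta={self.coef_[g]:+.4f}")
        else:
            lines.append("final refit: no panel (stable set empty)")
        return "\n".join(lines)


class StabilityLasso:
    """Bootstrap-LASSO stability selection model for a training matrix.

    Parameters
    ----------
    train : ExpressionMatrix
        Log-scale training matrix restricted to screened genes.
    params : StabilityParams, optional
    """

    def __init__(self, train: ExpressionMatrix, params: StabilityParams | None = None):
        self.train = train
        self.params = params or StabilityParams()
        if min(np.bincount(train.y, minlength=2)) < 2:
            raise ParameterError("both classes need >=2 training samples")

    # -- stage one -------------------------------------------------------

    def selection_frequencies(self) -> pd.Series:
        """Run the bootstrap loop and return per-gene selection frequencies."""
        p = self.params
        X, y = self.train.X, self.train.y
        rng = np.random.default_rng(p.seed)
        X_full_std, _, _ = _standardize(X)
        lmax = lambda_max(X_full_std, y)
        grid = np.geomspace(lmax, lmax * p.lambda_min_ratio, p.n_lambda)
        coarse = grid[:: p.bootstrap_grid_stride]

        idx_by_class = [np.flatnonzero(y == c) for c in (0, 1)]
        n_draw = [int(np.ceil(p.subsample_fraction * len(ix))) for ix in idx_by_class]
        counts = np.zeros(X.shape[1])

        with sklearn.config_context(assume_finite=True):
            self._bootstrap_loop(X, y, rng, idx_by_class, n_draw, coarse, lmax, counts)

        return pd.Series(counts / p.n_bootstrap, index=self.train.gene_ids, name="frequency")

    def _bootstrap_loop(self, X, y, rng, idx_by_class, n_draw, coarse, lmax, counts):
        p = self.params
        for b in range(p.n_bootstrap):
            for _ in range(_MAX_SUBSAMPLE_RETRIES):
                take = np.concatenate(
                    [
                        rng.choice(ix, size=nd, replace=False)
                        for ix, nd in zip(idx_by_class, n_draw)
                    ]
                )
                yb = y[take]
                if len(np.unique(yb)) == 2:
                    break
            else:  # pragma: no cover - stratified draw always has both classes
                raise RuntimeError("subsample degenerated to one class")
            Xb, _, _ = _standardize(X[take])
            min_class = min(np.bincount(yb, minlength=2))
            if min_class >= p.cv_folds:
                sub_seed = int(rng.integers(2**31))
                dev = _cv_deviance(Xb, yb, coarse, p.cv_folds, sub_seed)
                lam = coarse[int(np.argmin(dev))]
            else:
                lam = lmax / 10.0  # fallback when folds would degenerate
            coef, _ = _lasso_coefs(Xb, yb, lam)
            counts += coef != 0

    # -- stage two -------------------------------------------------------

    def cv_refit(self, stable_genes: list[str]):
        """Pick lambda* by K-fold CV deviance on the stable genes; refit on all data.

        Returns ``(lambda_, intercept, coef Series, train_mean, train_sd)``.
        Raises :class:`SelectionEmptyError` when the stable set is empty.
        """
        if not stable_genes:
            raise SelectionEmptyError("stable gene set is empty; no LASSO panel")
        p = self.params
        sub = self.train.subset_genes(stable_genes)
        X, y = sub.X, sub.y
        Xs, mu, sd = _standardize(X)
        lmax = lambda_max(Xs, y)
        grid = np.geomspace(lmax, lmax * p.lambda_min_ratio, p.n_lambda)
        dev = _cv_deviance(X, y, grid, p.cv_folds, p.seed)
        # ties broken toward the larger penalty (sparser model)
        lam = float(grid[int(np.argmin(dev))])
        model = _lasso_fit(Xs, y, lam)
        coef = pd.Series(model.coef_.ravel(), index=stable_genes)
        return lam, float(model.intercept_[0]), coef, mu, sd

    def fit(self) -> StabilityLassoResults:
        """Run both stages; an empty stable set yields a panel-less result."""
        freqs = self.selection_frequencies()
        stable = sorted(
            freqs.index[freqs >= self.params.freq_threshold],
            key=lambda g: (-freqs[g], str(g)),
        )
        res = StabilityLassoResults(self, freqs, [str(g) for g in stable])
        if not stable:
            logger.warning("stability selection: no gene reached the frequency threshold")
            return res
        lam, intercept, coef, mu, sd = self.cv_refit(res.stable_genes)
        res.lambda_ = lam
        res.intercept_ = intercept
        res.coef_ = coef
        res.selected_genes = [str(g) for g in coef.index[coef != 0]]
        res._train_mean = mu
        res._train_sd = sd
        logger.info(
            "stability selection: %d stable, %d in final panel",
            len(stable),
            len(res.selected_genes),
        )
        return res


# -- thin functional surface ------------------------------------------------

def stability_select(train: ExpressionMatrix, params: StabilityParams | None = None):
    """Frequencies and stable set only (stage one)."""
    model = StabilityLasso(train, params)
    freqs = model.selection_frequencies()
    thr = model.params.freq_threshold
    stable = sorted(freqs.index[freqs >= thr], key=lambda g: (-freqs[g], str(g)))
    return freqs, [str(g) for g in stable]


def cv_refit(train: ExpressionMatrix, stable_genes, params: StabilityParams | None = None):
    """Stage two alone: cross-validated penalty choice and full-data refit."""
    model = StabilityLasso(train, params)
    lam, intercept, coef, _, _ = model.cv_refit(list(stable_genes))
    return lam, intercept, coef
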