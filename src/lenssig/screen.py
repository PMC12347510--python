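"""Univariate screen: Welch's t-test plus a mean-difference filter.

Before any supervised model sees the data, the transcriptome is reduced to
genes that differ between wound healing (WH) and fibrosis (F) by at least
``diff_threshold`` in mean expression AND reach Welch p <= ``alpha``. By
default the mean difference is taken on the TPM scale and the test on
log2(TPM+1); both scales are configurable since a practitioner may prefer
the filter entirely on one scale.

No multiplicity correction is applied at this stage: the screen is a
pre-filter for model training, not an inference procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConsistencyError, ParameterError
from .expression import ExpressionMatrix, fpkm_to_tpm, log_transform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    diff_threshold: float = 1.0
    alpha: float = 0.05
    diff_scale: str = "tpm"        # {"tpm", "log2tpm"}
    test_scale: str = "log2tpm"    # {"tpm", "log2tpm"}
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.diff_threshold < 0:
            raise ParameterError("diff_threshold must be >= 0")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")
        for name in ("diff_scale", "test_scale"):
            if getattr(self, name) not in ("tpm", "log2tpm"):
                raise ParameterError(f"{name} must be 'tpm' or 'log2tpm'")


def welch_t(x, y):
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with ``t = (mean(x) - mean(y)) / sqrt(sx2/n1 + sy2/n2)``
    using unbiased variances, the Welch–Satterthwaite degrees of freedom, and
    the two-sided p-value. When both sample variances are zero the statistic
    is undefined and ``(nan, nan, nan)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("welch_t requires at least two observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        return (np.nan, np.nan, np.nan)
    res = stats.ttest_ind(x, y, equal_var=False)
    return (float(res.statistic), float(res.df), float(res.pvalue))


def _scaled(m: ExpressionMatrix, scale: str, offset: float) -> np.ndarray:
    """Return gene x sample values on the requested scale from any unit."""
    if m.unit == "FPKM":
        m = fpkm_to_tpm(m)
    if m.unit == "TPM":
        if scale == "tpm":
            return m.values.to_numpy()
        return log_transform(m, offset).values.to_numpy()
    # already log-transformed: only usable as the log scale
    if scale != "log2tpm":
        raise ConsistencyError(f"cannot recover TPM scale from unit {m.unit}")
    return m.values.to_numpy()


def screen_genes(m: ExpressionMatrix, params: ScreenParams | None = None) -> pd.DataFrame:
    """Per-gene Welch test and mean-difference filter.

    Returns a DataFrame indexed by gene id with columns ``mean_WH``,
    ``mean_F``, ``mean_diff`` (signed, WH − F, on ``params.diff_scale``),
    ``t``, ``df``, ``p`` (on ``params.test_scale``) and the boolean ``kept``.
    Genes with zero variance in both groups get ``p = NaN`` and are dropped
    with a logged warning.
    """
    params = params or ScreenParams()
    wh = m.condition_mask("WH")
    f = m.condition_mask("F")
    if wh.sum() < 2 or f.sum() < 2:
        raise ConsistencyError("screen requires >=2 samples per condition")

    diff_vals = _scaled(m, params.diff_scale, params.log_offset)
    test_vals = _scaled(m, params.test_scale, params.log_offset)

    mean_wh = diff_vals[:, wh].mean(axis=1)
    mean_f = diff_vals[:, f].mean(axis=1)
    mean_diff = mean_wh - mean_f

    a, b = test_vals[:, wh], test_vals[:, f]
    degenerate = (np.var(a, axis=1, ddof=1) == 0) & (np.var(b, axis=1, ddof=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (zero-variance) genes produce NaN statistics on purpose
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        t, df, p = res.statistic, res.df, res.pvalue
    t = np.where(degenerate, np.nan, t)
    df = np.where(degenerate, np.nan, df)
    p = np.where(degenerate, np.nan, p)

    kept = (np.abs(mean_diff) >= params.diff_threshold) & (p <= params.alpha)
    kept &= ~degenerate
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero variance in both conditions dropped", int(degenerate.sum())
        )
    result = pd.DataFrame(
        {
            "mean_WH": mean_wh,
            "mean_F": mean_f,
            "mean_diff": mean_diff,
            "t": t,
            "df": df,
            "p": p,
            "kept": kept,
        },
        index=m.gene_ids,
    )
    logger.info("screen: %d of %d genes kept", int(kept.sum()), m.n_genes)
    return result


def kept_genes(screen_result: pd.DataFrame) -> list[str]:
    """Gene ids passing the screen, in matrix order."""
    return list(screen_result.index[screen_result["kept"]])
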