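"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a 2-condition (wound healing vs fibrosis) x 3-day x
3-replicate bulk expression experiment: per-gene log2 baselines drawn
uniformly, a minority of planted condition-differential genes with a fixed
log2 effect size, mean-zero per-(gene, day) nuisance shifts, log-scale
Gaussian noise, and per-sample lognormal library-size factors applied after
back-transforming to the linear (FPKM-like) scale. Companion generators emit
GMT gene-set collections (one set enriched for planted fibrosis genes plus
size-matched random sets) and a long-format Ct fixture whose fold changes
follow the planted expression ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .expression import ExpressionMatrix


@dataclass(frozen=True)
class SimSpec:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the design the pipeline targets: 18 samples (2
    conditions x 3 days x 3 replicates), a few thousand genes, planted
    log2 effects of 3 against unit log2 noise.
    """

    n_genes: int = 2000
    n_planted_f: int = 20
    n_planted_wh: int = 10
    effect_size: float = 3.0          # log2 units
    noise_sd: float = 1.0             # log2 units
    baseline_log2_min: float = 0.0
    baseline_log2_max: float = 10.0
    day_effect_sd: float = 0.25
    library_size_cv: float = 0.1
    n_days: int = 3
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_f + self.n_planted_wh >= self.n_genes:
            raise ParameterError("planted gene counts must be < n_genes")
        if self.effect_size < 0 or self.noise_sd < 0 or self.day_effect_sd < 0:
            raise ParameterError("effect and noise magnitudes must be >= 0")
        if self.library_size_cv < 0:
            raise ParameterError("library_size_cv must be >= 0")
        if self.baseline_log2_min > self.baseline_log2_max:
            raise ParameterError("baseline range inverted")


def generate_expression(spec: SimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate an FPKM-like matrix and its planted-gene truth table.

    Per gene g and sample s:
    ``log2 expr = b_g + effect(g, condition(s)) + dayshift(g, day(s)) + N(0, sd^2)``
    then ``2**(.)`` and a per-sample lognormal library factor. The truth table
    lists planted genes with their target condition and signed log2 effect
    (positive = up in fibrosis).
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = 2 * spec.n_days * spec.n_reps

    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    sample_ids, condition, day, rep = [], [], [], []
    for cond in ("WH", "F"):
        for d in range(1, spec.n_days + 1):
            for r in range(1, spec.n_reps + 1):
                sample_ids.append(f"{cond}_D{d}_R{r}")
                condition.append(cond)
                day.append(d)
                rep.append(r)
    condition = np.array(condition)
    day = np.array(day)

    baseline = rng.uniform(spec.baseline_log2_min, spec.baseline_log2_max, spec.n_genes)
    planted_f = rng.choice(spec.n_genes, spec.n_planted_f, replace=False)
    remaining = np.setdiff1d(np.arange(spec.n_genes), planted_f)
    planted_wh = rng.choice(remaining, spec.n_planted_wh, replace=False)

    effect = np.zeros((spec.n_genes, n_samples))
    effect[np.ix_(planted_f, condition == "F")] = spec.effect_size
    effect[np.ix_(planted_wh, condition == "WH")] = spec.effect_size

    # nuisance day shifts shared by every replicate of a day (both conditions)
    day_shift = rng.normal(0.0, spec.day_effect_sd, (spec.n_genes, spec.n_days))
    log2_expr = (
        baseline[:, None]
        + effect
        + day_shift[:, day - 1]
        + rng.normal(0.0, spec.noise_sd, (spec.n_genes, n_samples))
    )

    linear = np.power(2.0, log2_expr)
    if spec.library_size_cv > 0:
        sigma = np.sqrt(np.log1p(spec.library_size_cv**2))
        factors = rng.lognormal(-sigma**2 / 2, sigma, n_samples)
        linear = linear * factors

    values = pd.DataFrame(linear, index=gene_ids, columns=sample_ids)
    m = ExpressionMatrix(
        values=values,
        condition=pd.Series(condition, index=sample_ids),
        day=pd.Series(day, index=sample_ids),
        unit="FPKM",
        replicate=pd.Series(rep, index=sample_ids),
    )

    rows = [
        {"gene_id": gene_ids[i], "condition": "F", "log2_effect": spec.effect_size}
        for i in sorted(planted_f)
    ] + [
        {"gene_id": gene_ids[i], "condition": "WH", "log2_effect": -spec.effect_size}
        for i in sorted(planted_wh)
    ]
    truth = pd.DataFrame(rows, columns=["gene_id", "condition", "log2_effect"])
    return m, truth


def generate_gene_sets(
    truth: pd.DataFrame,
    spec: SimSpec,
    set_size: int = 30,
    n_random_sets: int = 20,
) -> dict[str, list[str]]:
    """GMT collection: one fibrosis-planted set plus size-matched random sets."""
    rng = np.random.default_rng(spec.seed + 1)
    gene_ids = np.array([f"G{i:05d}" for i in range(spec.n_genes)])
    planted = truth.loc[truth["condition"] == "F", "gene_id"].tolist()
    pool = np.setdiff1d(gene_ids, np.array(planted))
    pad = max(0, set_size - len(planted))
    enriched = planted + list(rng.choice(pool, pad, replace=False))
    sets = {"planted_fibrosis": enriched[:set_size] if len(enriched) > set_size else enriched}
    for k in range(n_random_sets):
        sets[f"random_{k:02d}"] = list(rng.choice(gene_ids, set_size, replace=False))
    return sets


def generate_ct_fixture(
    truth: pd.DataFrame,
    spec: SimSpec,
    genes: list[str] | None = None,
    n_null_genes: int = 2,
    n_experiments: int = 3,
    n_technical: int = 3,
    reference_gene: str = "GAPDH",
    ct_intercept: float = 30.0,
    ct_noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format Ct table whose fold changes track the planted effects.

    Ct = intercept - log2(relative expression) + N(0, ct_noise_sd^2); the
    reference gene is constant across conditions, so dCt differences recover
    the planted log2 effects. Returns (Ct table, planted-fold table).
    """
    rng = np.random.default_rng(spec.seed + 2)
    if genes is None:
        planted = truth["gene_id"].tolist()[: 4]
        genes = planted + [f"NULL{i}" for i in range(n_null_genes)]
    effect_by_gene = dict(zip(truth["gene_id"], truth["log2_effect"]))

    rows = []
    fold_rows = []
    for gene in genes:
        # positive planted effect = up in fibrosis; WH is the qPCR baseline
        log2_effect = effect_by_gene.get(gene, 0.0)
        base_log2 = rng.uniform(2.0, 6.0)
        fold_rows.append({"gene": gene, "planted_fold_F_vs_WH": 2.0 ** log2_effect})
        for exp in range(1, n_experiments + 1):
            for cond in ("WH", "F"):
                log2_expr = base_log2 + (log2_effect if cond == "F" else 0.0)
                ct_true = ct_intercept - log2_expr
                for tr in range(1, n_technical + 1):
                    rows.append(
                        {
                            "experiment": f"E{exp}",
                            "condition": cond,
                            "gene": gene,
                            "technical_rep": tr,
                            "ct": ct_true + rng.normal(0.0, ct_noise_sd),
                        }
                    )
    ref_ct = ct_intercept - rng.uniform(8.0, 12.0)
    for exp in range(1, n_experiments + 1):
        for cond in ("WH", "F"):
            for tr in range(1, n_technical + 1):
                rows.append(
                    {
                        "experiment": f"E{exp}",
                        "condition": cond,
                        "gene": reference_gene,
                        "technical_rep": tr,
                        "ct": ref_ct + rng.normal(0.0, ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(fold_rows).set_index("gene")
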