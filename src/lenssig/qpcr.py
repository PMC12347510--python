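"""Relative qPCR quantification by the comparative-Ct (delta-delta-Ct) method.

Technical replicates are averaged to one Ct per (experiment, condition,
gene); dCt = Ct_target - Ct_reference normalizes input amounts within a
plate; ddCt = dCt - mean dCt of the baseline condition; fold change =
2^-ddCt under the standard assumption of one doubling per cycle. Fold
changes are summarized as mean +/- SEM over biological replicates
(independent experiments), and conditions are compared with Welch's t-test
on the per-experiment dCt values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError, ParameterError
from .screen import welch_t

REQUIRED_COLUMNS = ("experiment", "condition", "gene", "technical_rep", "ct")


def load_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct CSV with columns experiment,condition,gene,technical_rep,ct."""
    table = pd.read_csv(path)
    return validate_ct_table(table)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise FormatError("Ct values must be positive cycle counts")
    return table


@dataclass
class DdctResults:
    """Per-gene fold changes relative to the baseline condition."""

    table: pd.DataFrame            # gene x [mean_fold, sem, p_value, fold_<exp>...]
    per_experiment: pd.DataFrame   # long: gene, experiment, condition, dct, ddct, fold
    reference_gene: str
    baseline_condition: str

    def summary(self) -> str:
        lines = [
            f"ddCt quantification (reference {self.reference_gene}, "
            f"baseline {self.baseline_condition})",
            "=" * 48,
            f"{'gene':<12s} {'mean fold':>10s} {'SEM':>8s} {'Welch p':>9s}",
        ]
        for gene, row in self.table.iterrows():
            lines.append(
                f"{gene:<12s} {row['mean_fold']:>10.3f} {row['sem']:>8.3f} "
                f"{row['p_value']:>9.4f}"
            )
        return "\n".join(lines)


class DeltaDeltaCt:
    """ddCt model over a long-format Ct table.

    Parameters
    ----------
    table : DataFrame
        Columns ``experiment, condition, gene, technical_rep, ct``.
    target_genes : list of str
        Genes to quantify (the reference gene is excluded automatically).
    reference_gene : str
        Housekeeping gene used for within-sample normalization (GAPDH by
        convention in this assay).
    baseline_condition : str
        Condition whose mean dCt anchors the fold changes (its mean fold is
        exactly 1 by construction).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        target_genes,
        reference_gene: str = "GAPDH",
        baseline_condition: str = "WH",
    ):
        self.table = validate_ct_table(table)
        self.target_genes = [g for g in target_genes if g != reference_gene]
        if not self.target_genes:
            raise ParameterError("no target genes to quantify")
        self.reference_gene = reference_gene
        self.baseline_condition = baseline_condition

    def fit(self) -> DdctResults:
        # one Ct per (experiment, condition, gene): mean over technical reps
        ct = (
            self.table.groupby(["experiment", "condition", "gene"])["ct"]
            .mean()
            .rename("ct")
        )
        ref = ct.xs(self.reference_gene, level="gene")
        conditions = sorted(self.table["condition"].unique())
        if self.baseline_condition not in conditions:
            raise ConsistencyError(
                f"baseline condition {self.baseline_condition!r} absent from table"
            )
        experiments = sorted(self.table["experiment"].unique())
        for exp in experiments:
            for cond in conditions:
                if (exp, cond) not in ref.index:
                    raise ConsistencyError(
                        f"reference gene {self.reference_gene!r} missing for "
                        f"experiment {exp!r}, condition {cond!r}"
                    )

        long_rows = []
        summary_rows = []
        for gene in self.target_genes:
            try:
                gct = ct.xs(gene, level="gene")
            except KeyError:
                raise ConsistencyError(f"gene {gene!r} absent from Ct table") from None
            dct = gct - ref.loc[gct.index]
            base = dct.xs(self.baseline_condition, level="condition")
            ddct = dct - base.mean()
            fold = np.power(2.0, -ddct)
            for (exp, cond), f in fold.items():
                long_rows.append(
                    {
                        "gene": gene,
                        "experiment": exp,
                        "condition": cond,
                        "dct": dct.loc[(exp, cond)],
                        "ddct": ddct.loc[(exp, cond)],
                        "fold": f,
                    }
                )
            other = [c for c in conditions if c != self.baseline_condition]
            comparison = other[0] if other else self.baseline_condition
            folds_cmp = fold.xs(comparison, level="condition")
            dct_cmp = dct.xs(comparison, level="condition")
            # Welch on per-experiment dCt values (the biological-replicate unit)
            _, _, p = welch_t(dct_cmp.to_numpy(), base.to_numpy())
            if np.isnan(p) and np.isclose(dct_cmp.mean(), base.mean()):
                p = 1.0   # zero variance, identical means: no evidence of difference
            row = {
                "gene": gene,
                "mean_fold": float(folds_cmp.mean()),
                "sem": float(folds_cmp.std(ddof=1) / np.sqrt(len(folds_cmp))),
                "p_value": p,
            }
            for exp in experiments:
                row[f"fold_{exp}"] = float(folds_cmp.loc[exp])
            summary_rows.append(row)

        return DdctResults(
            table=pd.DataFrame(summary_rows).set_index("gene"),
            per_experiment=pd.DataFrame(long_rows),
            reference_gene=self.reference_gene,
            baseline_condition=self.baseline_condition,
        )


def ddct_analysis(
    table: pd.DataFrame,
    target_genes,
    reference_gene: str = "GAPDH",
    baseline_condition: str = "WH",
) -> DdctResults:
    """Functional surface over :class:`DeltaDeltaCt`."""
    return DeltaDeltaCt(table, target_genes, reference_gene, baseline_condition).fit()
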