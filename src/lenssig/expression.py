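"""Expression-matrix container, normalization, and train/holdout splitting.

The central data structure is :class:`ExpressionMatrix`: a genes x samples
matrix of non-negative expression values tagged with its unit (FPKM, TPM, or
a log2 lineage string) plus per-sample condition ("WH" wound healing / "F"
fibrosis) and day labels. All downstream stages consume this object.

Normalization follows the standard FPKM -> TPM rescaling (each sample column
is divided by its FPKM total and multiplied by 1e6, so TPM columns sum to one
million) followed by ``log2(x + offset)`` variance stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    ConsistencyError,
    DegenerateSampleError,
    FormatError,
    ParameterError,
    SplitError,
    UnitError,
)

CONDITIONS = ("WH", "F")
#: class coding used by every classifier track: fibrosis is the positive class
POSITIVE_CONDITION = "F"

TPM_TOTAL = 1e6
_TPM_RTOL = 1e-6


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with per-sample labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.
    condition : pandas.Series
        Per-sample label in {"WH", "F"}, indexed like ``values.columns``.
    day : pandas.Series
        Per-sample integer day in {1, 2, 3}, indexed like ``values.columns``.
    unit : str
        One of "FPKM", "TPM", or a log lineage tag such as "log2(TPM+1)".
    """

    values: pd.DataFrame
    condition: pd.Series
    day: pd.Series
    unit: str = "FPKM"
    replicate: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.condition = pd.Series(self.condition, index=self.values.columns)
        self.day = pd.Series(self.day, index=self.values.columns)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample ids: {list(dupes[:5])}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)]
            raise FormatError(f"missing values in genes: {list(bad[:5])}")
        if len(self.condition) != self.n_samples or len(self.day) != self.n_samples:
            raise ConsistencyError("condition/day labels do not match sample count")
        unknown = set(self.condition.unique()) - set(CONDITIONS)
        if unknown:
            raise ConsistencyError(f"unknown condition labels: {sorted(unknown)}")
        if self.unit in ("FPKM", "TPM") and (self.values.to_numpy() < 0).any():
            raise FormatError(f"negative values not allowed in {self.unit} matrix")
        if self.unit == "TPM":
            sums = self.values.to_numpy().sum(axis=0)
            if not np.allclose(sums, TPM_TOTAL, rtol=_TPM_RTOL):
                raise ConsistencyError("TPM columns must sum to 1e6")

    # -- basic accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Samples x genes design matrix (the ML orientation)."""
        return self.values.to_numpy().T

    @property
    def y(self) -> np.ndarray:
        """Binary labels with fibrosis (``F``) coded 1, wound healing 0."""
        return (self.condition.to_numpy() == POSITIVE_CONDITION).astype(int)

    def condition_mask(self, condition: str) -> np.ndarray:
        return self.condition.to_numpy() == condition

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return replace(
            self,
            values=self.values.loc[list(gene_ids)],
            condition=self.condition,
            day=self.day,
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return replace(
            self,
            values=self.values[sample_ids],
            condition=self.condition[sample_ids],
            day=self.day[sample_ids],
            replicate=None if self.replicate is None else self.replicate[sample_ids],
        )


@dataclass(frozen=True)
class SplitSpec:
    """How to draw the held-out validation set: per-class size and RNG seed."""

    n_holdout_per_class: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_holdout_per_class < 1:
            raise ParameterError("n_holdout_per_class must be positive")


def load_expression(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read a TSV expression matrix plus a sample-metadata TSV.

    The matrix file has gene ids in the first column and sample ids in the
    header; the metadata file maps ``sample_id`` to ``condition`` and ``day``.
    Values are taken to be FPKM. Sample order follows the metadata table.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["."])
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"sample_id", "condition", "day"}
    if not required.issubset(meta.columns):
        raise FormatError(f"metadata must have columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in metadata")
    matrix_samples = set(values.columns)
    meta_samples = set(meta["sample_id"])
    if matrix_samples != meta_samples:
        raise ConsistencyError(
            f"sample sets differ: matrix-only {sorted(matrix_samples - meta_samples)[:3]}, "
            f"metadata-only {sorted(meta_samples - matrix_samples)[:3]}"
        )
    order = meta["sample_id"].tolist()
    meta = meta.set_index("sample_id")
    replicate = meta["replicate"] if "replicate" in meta.columns else None
    return ExpressionMatrix(
        values=values[order],
        condition=meta.loc[order, "condition"],
        day=meta.loc[order, "day"].astype(int),
        unit="FPKM",
        replicate=None if replicate is None else replicate.loc[order],
    )


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so gene abundances sum to one million (TPM).

    ``TPM[g, s] = FPKM[g, s] / sum_g FPKM[g, s] * 1e6``. This removes the
    residual between-sample depth differences FPKM leaves behind; within a
    sample the gene ranking is unchanged.
    """
    if m.unit != "FPKM":
        raise UnitError(f"fpkm_to_tpm requires FPKM input, got {m.unit}")
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateSampleError(f"all-zero sample columns: {list(zero.index)}")
    return replace(m, values=m.values / totals * TPM_TOTAL, unit="TPM")


def log_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Apply ``log2(x + offset)`` to stabilize variance.

    The unit tag records the lineage, e.g. ``log2(TPM+1)``, so downstream
    stages can assert they received the scale they expect.
    """
    if offset <= 0:
        raise ParameterError(f"offset must be > 0, got {offset}")
    if m.unit not in ("FPKM", "TPM"):
        raise UnitError(f"log_transform requires linear-scale input, got {m.unit}")
    off = f"{offset:g}"
    return replace(m, values=np.log2(m.values + offset), unit=f"log2({m.unit}+{off})")


def make_holdout_split(
    m: ExpressionMatrix, spec: SplitSpec
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Draw a class-stratified holdout set; the rest becomes training data.

    The draw is stratified by condition only (a 5-per-class holdout cannot be
    balanced over three days of three replicates). Deterministic under
    ``spec.seed``; train and holdout partition the samples exactly.
    """
    rng = np.random.default_rng(spec.seed)
    holdout_ids: list[str] = []
    for cond in CONDITIONS:
        ids = np.asarray(m.sample_ids[m.condition_mask(cond)])
        if len(ids) <= spec.n_holdout_per_class:
            raise SplitError(
                f"class {cond} has {len(ids)} samples; cannot hold out "
                f"{spec.n_holdout_per_class} and keep any for training"
            )
        if len(ids) - spec.n_holdout_per_class < 2:
            raise SplitError(f"class {cond} would retain <2 training samples")
        holdout_ids.extend(rng.choice(ids, size=spec.n_holdout_per_class, replace=False))
    holdout_set = set(holdout_ids)
    train_ids = [s for s in m.sample_ids if s not in holdout_set]
    # keep original sample order within each part
    holdout_ids = [s for s in m.sample_ids if s in holdout_set]
    return m.subset_samples(train_ids), m.subset_samples(holdout_ids)
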