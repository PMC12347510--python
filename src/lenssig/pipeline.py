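"""End-to-end orchestration: normalize -> split -> screen -> three selection
tracks -> holdout evaluation -> per-gene ROC -> pooled fold changes ->
optional per-gene GSEA and ddCt quantification.

Every stage writes its artifact as TSV/JSON into the run directory, stamped
with the configuration hash and global seed; holdout samples never reach a
feature-selection stage (asserted by test). The three tracks are reported
independently — no vote merging — and each selected gene is labelled WH- or
F-associated by the sign of the training-set WH − F mean log2 difference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import confusion_and_pr, pca_projection, per_gene_roc, pooled_log2fc
from .expression import (
    ExpressionMatrix,
    SplitSpec,
    fpkm_to_tpm,
    load_expression,
    log_transform,
    make_holdout_split,
)
from .forest_panel import ForestPanel, RfParams
from .gsea import GeneSetEnrichment, GseaParams, read_gmt
from .qpcr import DeltaDeltaCt, load_ct_table
from .screen import ScreenParams, kept_genes, screen_genes
from .stability_lasso import StabilityLasso, StabilityParams
from .svm_panel import SvmPanel, SvmParams

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every block has usable defaults."""

    matrix_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    ct_path: str | None = None
    out_dir: str = "lenssig_run"
    seed: int = 0
    log_offset: float = 1.0
    split: SplitSpec = field(default_factory=SplitSpec)
    screen: ScreenParams = field(default_factory=ScreenParams)
    lasso: StabilityParams = field(default_factory=StabilityParams)
    svm: SvmParams = field(default_factory=SvmParams)
    rf: RfParams = field(default_factory=RfParams)
    gsea: GseaParams = field(default_factory=GseaParams)
    qpcr_reference: str = "GAPDH"
    qpcr_baseline: str = "WH"

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate one global seed into every seeded block."""
        return dataclasses.replace(
            self,
            seed=seed,
            split=dataclasses.replace(self.split, seed=seed),
            lasso=dataclasses.replace(self.lasso, seed=seed + 1),
            svm=dataclasses.replace(self.svm, seed=seed + 2),
            rf=dataclasses.replace(self.rf, seed=seed + 3),
            gsea=dataclasses.replace(self.gsea, seed=seed + 4),
        )

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


@dataclass
class PipelineResult:
    """In-memory view of a finished run (artifacts also live in ``out_dir``)."""

    config: RunConfig
    train: ExpressionMatrix
    holdout: ExpressionMatrix
    screen_result: pd.DataFrame
    lasso_results: object
    svm_results: object
    rf_results: object
    eval_reports: dict
    per_gene_auc: pd.DataFrame
    fold_changes: pd.DataFrame
    consensus: pd.DataFrame
    gsea_results: dict = field(default_factory=dict)
    ddct_results: object = None

    def holdout_auc(self, track: str) -> float:
        return self.eval_reports[track].auc

    def summary(self) -> str:
        lines = [
            "lenssig pipeline summary",
            "=" * 48,
            f"train {self.train.n_samples} samples / holdout {self.holdout.n_samples}; "
            f"{int(self.screen_result['kept'].sum())} of {len(self.screen_result)} "
            "genes passed the univariate screen",
        ]
        for track, res in (
            ("lasso", self.lasso_results),
            ("svm", self.svm_results),
            ("rf", self.rf_results),
        ):
            panel = getattr(res, "selected_genes", None)
            if panel is None:
                panel = res.panel
            rep = self.eval_reports[track]
            lines.append(
                f"{track:>5s}: panel [{', '.join(panel) or '-'}] "
                f"holdout AUC={rep.auc:.3f} acc={rep.accuracy:.3f}"
            )
        return "\n".join(lines)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise type(err)(f"[stage {name}] {err}") from err
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def _write_tsv(frame: pd.DataFrame, path: Path, meta: dict) -> None:
    frame.to_csv(path, sep="\t")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def run_pipeline(
    config: RunConfig,
    matrix: ExpressionMatrix | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full workflow.

    ``matrix`` may be passed directly (e.g. from the synthetic generator);
    otherwise it is loaded from ``config.matrix_path``/``metadata_path``.
    With ``write=True`` all artifacts land in ``config.out_dir``.
    """
    if matrix is None:
        if config.matrix_path is None:
            raise ValueError("either a matrix or matrix_path/metadata_path is required")
        matrix = load_expression(config.matrix_path, config.metadata_path)
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "log_offset": config.log_offset}

    # normalize and keep two parallel matrices: TPM-derived log2 values for
    # modeling, raw FPKM for visualization-scale fold changes
    tpm = _stage("normalize")(fpkm_to_tpm)(matrix)
    log_tpm = log_transform(tpm, config.log_offset)

    train_log, holdout_log = _stage("split")(make_holdout_split)(log_tpm, config.split)
    train_ids = list(train_log.sample_ids)
    train_tpm = tpm.subset_samples(train_ids)

    screen_result = _stage("screen")(screen_genes)(train_tpm, config.screen)
    kept = kept_genes(screen_result)
    train_screened = train_log.subset_genes(kept)

    lasso_res = _stage("lasso")(lambda: StabilityLasso(train_screened, config.lasso).fit())()
    svm_res = _stage("svm")(lambda: SvmPanel(train_screened, config.svm).fit())()
    rf_res = _stage("rf")(lambda: ForestPanel(train_screened, config.rf).fit())()

    y_hold = holdout_log.y
    scores = {
        "lasso": lasso_res.predict_proba(holdout_log),
        "svm": svm_res.predict_proba(holdout_log),
        "rf": rf_res.predict_proba(holdout_log),
    }
    eval_reports = {
        track: _stage(f"evaluate[{track}]")(confusion_and_pr)(y_hold, s)
        for track, s in scores.items()
    }

    panels = {
        "lasso": list(lasso_res.selected_genes),
        "svm": list(svm_res.panel),
        "rf": list(rf_res.panel),
    }
    consensus_genes = sorted({g for p in panels.values() for g in p})

    rows = []
    for gene in consensus_genes:
        auc, direction = per_gene_roc(holdout_log, gene)
        rows.append({"gene_id": gene, "auc": auc, "direction": direction})
    per_gene = pd.DataFrame(rows, columns=["gene_id", "auc", "direction"])
    per_gene = per_gene.set_index("gene_id") if rows else per_gene

    fc_rows = [pooled_log2fc(matrix, g, config.log_offset) for g in consensus_genes]
    fold_changes = pd.DataFrame(
        fc_rows,
        columns=["gene_id", "mean_F", "mean_WH", "log2fc", "p_value",
                 "zero_mean_offset_applied"],
    )
    fold_changes = fold_changes.set_index("gene_id") if fc_rows else fold_changes

    # association label from training means only (no holdout leakage)
    cons_rows = []
    for gene in consensus_genes:
        tracks = [t for t, p in panels.items() if gene in p]
        diff = screen_result.loc[gene, "mean_diff"]  # WH - F on the screen scale
        cons_rows.append(
            {
                "gene_id": gene,
                "tracks": "+".join(tracks),
                "mean_diff_WH_minus_F": diff,
                "association": "WH" if diff > 0 else "F",
            }
        )
    consensus = pd.DataFrame(
        cons_rows, columns=["gene_id", "tracks", "mean_diff_WH_minus_F", "association"]
    )
    consensus = consensus.set_index("gene_id") if cons_rows else consensus

    result = PipelineResult(
        config=config,
        train=train_log,
        holdout=holdout_log,
        screen_result=screen_result,
        lasso_results=lasso_res,
        svm_results=svm_res,
        rf_results=rf_res,
        eval_reports=eval_reports,
        per_gene_auc=per_gene,
        fold_changes=fold_changes,
        consensus=consensus,
    )

    if config.gmt_path:
        sets = read_gmt(config.gmt_path)
        for gene in consensus_genes:
            enr = _stage(f"gsea[{gene}]")(
                lambda g=gene: GeneSetEnrichment(log_tpm, g, sets, config.gsea).fit()
            )()
            result.gsea_results[gene] = enr

    if config.ct_path:
        ct = load_ct_table(config.ct_path)
        targets = sorted(set(ct["gene"]) - {config.qpcr_reference})
        result.ddct_results = _stage("qpcr")(
            lambda: DeltaDeltaCt(ct, targets, config.qpcr_reference,
                                 config.qpcr_baseline).fit()
        )()

    if write:
        _write_tsv(screen_result, out / "screen_result.tsv", meta)
        _write_tsv(lasso_res.frequency_frame(), out / "lasso_frequencies.tsv", meta)
        if lasso_res.coef_ is not None:
            (out / "lasso_final_model.json").write_text(
                json.dumps(
                    {
                        "lambda": lasso_res.lambda_,
                        "intercept": lasso_res.intercept_,
                        "coefficients": lasso_res.coef_.to_dict(),
                        **meta,
                    },
                    indent=1,
                )
            )
        _write_tsv(svm_res.ranking.to_frame(), out / "svm_ranking.tsv", meta)
        _write_tsv(svm_res.importance_frame(), out / "svm_importance.tsv", meta)
        decisions = pd.DataFrame(
            {
                "sample_id": holdout_log.sample_ids,
                "decision_value": svm_res.decision_value(holdout_log),
                "prob_WH": svm_res.prob_WH(holdout_log),
                "predicted": np.where(scores["svm"] >= 0.5, "F", "WH"),
                "truth": holdout_log.condition.to_numpy(),
            }
        ).set_index("sample_id")
        _write_tsv(decisions, out / "svm_decision_values.tsv", meta)
        _write_tsv(rf_res.gini_importance.to_frame(), out / "rf_gini.tsv", meta)
        _write_tsv(rf_res.importance_frame(), out / "rf_permutation.tsv", meta)
        rf_pred = pd.DataFrame(
            {
                "sample_id": holdout_log.sample_ids,
                "prob_F": scores["rf"],
                "truth": holdout_log.condition.to_numpy(),
            }
        ).set_index("sample_id")
        _write_tsv(rf_pred, out / "rf_holdout_predictions.tsv", meta)
        for track, rep in eval_reports.items():
            (out / f"eval_{track}.json").write_text(
                json.dumps({**rep.to_dict(), **meta}, indent=1)
            )
        _write_tsv(per_gene, out / "per_gene_auc.tsv", meta)
        _write_tsv(fold_changes, out / "pooled_log2fc.tsv", meta)
        _write_tsv(consensus, out / "consensus_panel.tsv", meta)
        coords, var = pca_projection(log_tpm)
        _write_tsv(coords, out / "pca_coords.tsv",
                   {**meta, "variance_explained": var.tolist()})
        for gene, enr in result.gsea_results.items():
            _write_tsv(enr.to_frame(), out / f"gsea_{gene}.tsv", meta)
        if result.ddct_results is not None:
            _write_tsv(result.ddct_results.table, out / "ddct_results.tsv", meta)
        (out / "summary.txt").write_text(result.summary() + "\n")

    return result
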