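"""Per-candidate-gene set enrichment (weighted Kolmogorov–Smirnov ES/NES/FDR).

For one candidate gene, the rest of the transcriptome is ranked by Pearson
correlation with the candidate's expression across all samples. For each
gene set, the classic weighted-KS running sum is walked down that ranking:
a hit increments by |metric|^p normalized by the total over set hits, a
miss decrements by 1/(N - N_hits); the enrichment score (ES) is the
signed extremum of the running sum, and the leading edge the set members at
or before it (at or after, for negative ES).

Because the study design has too few samples for phenotype permutation, the
null is gene-set permutation: random same-size sets drawn from the ranked
list. NES = ES / mean(|null ES| of the same sign), and FDR uses the standard
tail-ratio estimate over the pooled null NES distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MetricError, ParameterError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GseaParams:
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    min_set_size: int = 5
    max_set_size: int = 500
    ranking_metric: str = "pearson_with_candidate"  # or "signal_to_noise"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ParameterError("weight_exponent must be >= 0")
        if self.min_set_size > self.max_set_size:
            raise ParameterError("min_set_size must not exceed max_set_size")
        if self.ranking_metric not in ("pearson_with_candidate", "signal_to_noise"):
            raise ParameterError(f"unknown ranking metric {self.ranking_metric!r}")


@dataclass
class EnrichmentResult:
    candidate_gene: str
    set_name: str
    size: int                      # set members found in the ranked list
    es: float
    running_sum: np.ndarray = field(repr=False)
    leading_edge: list[str] = field(default_factory=list)
    nes: float = np.nan
    fdr: float = np.nan


# -- GMT I/O -----------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: ``set_name<TAB>description<TAB>gene1<TAB>...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# -- ranking -----------------------------------------------------------------

def rank_for_candidate(
    m: ExpressionMatrix, candidate: str, params: GseaParams | None = None
) -> pd.Series:
    """Rank every other gene by association with the candidate's expression.

    Default metric: Pearson correlation across all samples. Returns the
    metric values sorted descending with deterministic gene-id tie-breaks.
    """
    params = params or GseaParams()
    if candidate not in m.gene_ids:
        raise KeyError(f"candidate {candidate!r} not in matrix")
    if m.n_samples < 3:
        raise MetricError("ranking needs at least 3 samples")
    V = m.values.to_numpy(dtype=float)
    c = m.values.loc[candidate].to_numpy(dtype=float)
    if params.ranking_metric == "pearson_with_candidate":
        c_cent = c - c.mean()
        c_norm = np.sqrt((c_cent**2).sum())
        if c_norm == 0:
            raise MetricError("candidate gene has zero variance")
        Vc = V - V.mean(axis=1, keepdims=True)
        norms = np.sqrt((Vc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            metric = (Vc @ c_cent) / (norms * c_norm)
        metric = np.where(norms == 0, 0.0, metric)
    else:  # signal_to_noise between conditions
        wh, f = m.condition_mask("WH"), m.condition_mask("F")
        num = V[:, f].mean(axis=1) - V[:, wh].mean(axis=1)
        den = V[:, f].std(axis=1, ddof=1) + V[:, wh].std(axis=1, ddof=1)
        metric = np.where(den == 0, 0.0, num / np.where(den == 0, 1.0, den))
    s = pd.Series(metric, index=m.gene_ids.astype(str))
    s = s.drop(candidate)
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


# -- enrichment score --------------------------------------------------------

def _running_sum(metric: np.ndarray, hit_mask: np.ndarray, p: float) -> np.ndarray:
    """Full running-sum curve over the ranked list."""
    n = len(metric)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise MetricError("gene set must hit a strict subset of the ranked list")
    w = np.abs(metric) ** p
    w_hit = np.where(hit_mask, w, 0.0)
    total = w_hit.sum()
    if total == 0:          # all hit metrics are zero: fall back to equal weights
        w_hit = hit_mask.astype(float)
        total = w_hit.sum()
    step = w_hit / total - (~hit_mask) / (n - n_hit)
    return np.cumsum(step)


def enrichment_score(
    ranked: pd.Series, gene_set, params: GseaParams | None = None,
    candidate: str = "", set_name: str = "",
) -> EnrichmentResult:
    """Weighted-KS enrichment of ``gene_set`` in the ranked list.

    ES is the running-sum excursion of largest magnitude (positive wins
    exact-magnitude ties); the curve ends at 0 by construction.
    """
    params = params or GseaParams()
    genes = ranked.index.to_numpy()
    members = set(map(str, gene_set))
    hit_mask = np.fromiter((g in members for g in genes), bool, len(genes))
    size = int(hit_mask.sum())
    if size < params.min_set_size or size > params.max_set_size:
        raise MetricError(
            f"set {set_name!r}: {size} members in ranked list, outside "
            f"[{params.min_set_size}, {params.max_set_size}]"
        )
    curve = _running_sum(ranked.to_numpy(dtype=float), hit_mask, params.weight_exponent)
    i_max, i_min = int(np.argmax(curve)), int(np.argmin(curve))
    es = float(curve[i_max]) if curve[i_max] >= -curve[i_min] else float(curve[i_min])
    if es >= 0:
        leading = [str(g) for g in genes[: i_max + 1][hit_mask[: i_max + 1]]]
    else:
        leading = [str(g) for g in genes[i_min:][hit_mask[i_min:]]]
    return EnrichmentResult(candidate, set_name, size, es, curve, leading)


def _null_es(metric: np.ndarray, size: int, n_perm: int, p: float,
             rng: np.random.Generator) -> np.ndarray:
    """ES for ``n_perm`` random same-size gene sets (positions), vectorized."""
    n = len(metric)
    w = np.abs(metric) ** p
    # random k hit positions per permutation, sorted along each row
    pos = np.argpartition(rng.random((n_perm, n)), size - 1, axis=1)[:, :size]
    pos.sort(axis=1)
    wh = w[pos]
    W = wh.sum(axis=1, keepdims=True)
    W = np.where(W == 0, 1.0, W)
    cum = np.cumsum(wh, axis=1) / W
    miss = 1.0 / (n - size)
    offs = (pos - np.arange(size)) * miss
    after = cum - offs                     # value right after each hit
    before = after - wh / W                # value right before each hit
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def nes_and_fdr(
    results: list[EnrichmentResult],
    ranked: pd.Series,
    params: GseaParams | None = None,
) -> list[EnrichmentResult]:
    """Attach NES and FDR (gene-set permutation null); return NES>0, FDR-sorted.

    Each set's null ES distribution comes from ``n_permutations`` random
    same-size sets; NES = ES / mean(|null ES| of the same sign). The pooled
    null NES values give the tail-ratio FDR for each observed NES.
    """
    params = params or GseaParams()
    if not results:
        raise ParameterError("no scored sets supplied")
    rng = np.random.default_rng(params.seed)
    metric = ranked.to_numpy(dtype=float)

    null_nes_pool: list[np.ndarray] = []
    for r in results:
        null = _null_es(metric, r.size, params.n_permutations,
                        params.weight_exponent, rng)
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        denom = pos_mean if r.es >= 0 else neg_mean
        if not np.isfinite(denom) or denom == 0:
            logger.warning("set %s: degenerate null, FDR set to 1", r.set_name)
            r.nes = 0.0
            r.fdr = 1.0
            null_nes_pool.append(np.zeros(0))
            continue
        r.nes = float(r.es / denom)
        nn = np.where(null >= 0,
                      null / (pos_mean if np.isfinite(pos_mean) else 1.0),
                      null / (neg_mean if np.isfinite(neg_mean) else 1.0))
        null_nes_pool.append(nn)

    pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.zeros(0)
    obs = np.array([r.nes for r in results])
    for r in results:
        if np.isfinite(r.fdr):   # degenerate null already assigned FDR 1
            continue
        if not np.isfinite(r.nes):
            r.fdr = 1.0
            continue
        if r.nes >= 0:
            null_tail = (pooled >= r.nes).mean() if pooled.size else 1.0
            obs_tail = (obs >= r.nes).mean()
        else:
            null_tail = (pooled <= r.nes).mean() if pooled.size else 1.0
            obs_tail = (obs <= r.nes).mean()
        r.fdr = float(min(1.0, null_tail / obs_tail)) if obs_tail > 0 else 1.0

    kept = [r for r in results if r.nes > 0]
    return sorted(kept, key=lambda r: (r.fdr, r.set_name))


# -- Model/Results wrapper ---------------------------------------------------

@dataclass
class EnrichmentResults:
    candidate: str
    ranked: pd.Series
    all_results: list[EnrichmentResult]
    positive: list[EnrichmentResult]      # NES > 0, sorted by FDR
    skipped: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set_name": r.set_name,
                    "size": r.size,
                    "es": r.es,
                    "nes": r.nes,
                    "fdr": r.fdr,
                    "leading_edge": ";".join(r.leading_edge),
                }
                for r in self.all_results
            ]
        ).set_index("set_name")

    def summary(self) -> str:
        lines = [
            f"Per-gene enrichment for candidate {self.candidate}",
            "=" * 48,
            f"sets scored: {len(self.all_results)}   skipped: {len(self.skipped)}",
            "positively enriched (NES > 0), by FDR:",
        ]
        for r in self.positive[:10]:
            lines.append(
                f"  {r.set_name:<28s} ES={r.es:+.3f} NES={r.nes:+.3f} FDR={r.fdr:.3f}"
            )
        return "\n".join(lines)


class GeneSetEnrichment:
    """Per-candidate GSEA model over a GMT collection.

    Parameters
    ----------
    m : ExpressionMatrix
        Log-scale expression over all samples.
    candidate : str
        The gene whose co-expression neighborhood is tested.
    gene_sets : dict[str, list[str]]
        Set name -> member gene ids (GMT content).
    """

    def __init__(self, m: ExpressionMatrix, candidate: str,
                 gene_sets: dict[str, list[str]], params: GseaParams | None = None):
        self.m = m
        self.candidate = candidate
        self.gene_sets = gene_sets
        self.params = params or GseaParams()

    def fit(self) -> EnrichmentResults:
        ranked = rank_for_candidate(self.m, self.candidate, self.params)
        scored: list[EnrichmentResult] = []
        skipped: list[str] = []
        for name, members in self.gene_sets.items():
            try:
                scored.append(
                    enrichment_score(ranked, members, self.params,
                                     candidate=self.candidate, set_name=name)
                )
            except MetricError as err:
                logger.info("skipping set %s: %s", name, err)
                skipped.append(name)
        positive = nes_and_fdr(scored, ranked, self.params) if scored else []
        return EnrichmentResults(self.candidate, ranked, scored, positive, skipped)
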