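import numpy as np
import pandas as pd
import pytest

import lenssig as ls


def make_matrix(values, conditions, days=None, unit="FPKM", genes=None, samples=None):
    """Small hand-built ExpressionMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    days = days or [1] * n_samples
    frame = pd.DataFrame(values, index=genes, columns=samples)
    return ls.ExpressionMatrix(
        values=frame,
        condition=pd.Series(list(conditions), index=samples),
        day=pd.Series(days, index=samples),
        unit=unit,
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """One strongly planted synthetic dataset shared by the slower tests.

    200 genes, a single fibrosis-up gene at log2 effect 4 — the regime where
    every selector should find the planted gene.
    """
    spec = ls.SimSpec(n_genes=200, n_planted_f=1, n_planted_wh=0, effect_size=4, seed=7)
    m, truth = ls.generate_expression(spec)
    tpm = ls.fpkm_to_tpm(m)
    log = ls.log_transform(tpm)
    train, holdout = ls.make_holdout_split(log, ls.SplitSpec(5, 7))
    screen = ls.screen_genes(tpm.subset_samples(train.sample_ids))
    train_screened = train.subset_genes(ls.kept_genes(screen))
    return {
        "spec": spec,
        "matrix": m,
        "truth": truth,
        "planted_gene": truth["gene_id"].iloc[0],
        "tpm": tpm,
        "log": log,
        "train": train,
        "holdout": holdout,
        "screen": screen,
        "train_screened": train_screened,
    }


@pytest.fixture(scope="session")
def default_sim():
    """Default-design dataset (2000 genes, 20 F-up / 10 WH-up planted, effect 3)."""
    spec = ls.SimSpec(seed=5)
    m, truth = ls.generate_expression(spec)
    return {"spec": spec, "matrix": m, "truth": truth}
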