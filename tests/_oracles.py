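"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths they check: AUC by explicit
enumeration of positive/negative pairs, Welch's statistic from the textbook
formulas, and the enrichment running sum by a literal step-by-step walk.
"""

import numpy as np


def auc_all_pairs(labels, scores) -> float:
    """AUC as the fraction of concordant (pos, neg) pairs, ties counted half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def welch_by_hand(x, y):
    """(t, df) straight from the Welch formulas with unbiased variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def es_brute_force(metric, hit_flags, weight_exponent=1.0):
    """Enrichment score by a literal walk down the ranked list.

    Returns (es, full running-sum list). Hits step up by |m|^p / total hit
    weight, misses step down by 1/(N - n_hit); ES is the value of largest
    magnitude along the walk (positive preferred on exact ties).
    """
    metric = np.asarray(metric, dtype=float)
    hit_flags = np.asarray(hit_flags, dtype=bool)
    n = len(metric)
    n_hit = int(hit_flags.sum())
    weights = np.abs(metric) ** weight_exponent
    total = weights[hit_flags].sum()
    if total == 0:
        weights = np.ones(n)
        total = float(n_hit)
    curve = []
    running = 0.0
    for i in range(n):
        if hit_flags[i]:
            running += weights[i] / total
        else:
            running -= 1.0 / (n - n_hit)
        curve.append(running)
    curve = np.array(curve)
    hi, lo = curve.max(), curve.min()
    es = hi if hi >= -lo else lo
    return float(es), curve
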