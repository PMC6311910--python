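"""Evaluation metrics: Kendall's W, ROC/AUC, BH-FDR, competitive enrichment.

Kendall's coefficient of concordance W measures agreement among m
rankings of n items (1 = identical rankings).  With tied observations
assigned midranks, the tie-corrected statistic is

    W = (12 * sum_i R_i^2 - 3 m^2 n (n+1)^2)
        / (m^2 n (n^2 - 1) - m * sum_r T_r)

where R_i is the rank sum of item i and T_r = sum(t^3 - t) over the tie
groups of rater r.

The ROC/AUC here is the rank-based (Mann–Whitney) area: the probability
that a positive item outscores a negative one, ties counted 1/2.  The
built-in competitive enrichment test is a two-sided rank-sum comparison
of member versus non-member gene statistics — a deliberately simple
stand-in for inter-gene-correlation-aware methods such as CAMERA, whose
p-values can also be supplied externally.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def rank_table(scores: np.ndarray) -> np.ndarray:
    """Convert an m × n score table into per-row ranks (midranks for ties)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return np.vstack([stats.rankdata(row) for row in scores])


def kendalls_w(ranks: np.ndarray) -> float:
    """Tie-corrected Kendall's coefficient of concordance, in [0, 1].

    ``ranks`` is an m raters × n items table of ranks (midranks allowed).
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim != 2:
        raise ValueError("rank table must be 2-dimensional")
    m, n = ranks.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 raters and 2 items")
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - m * (n + 1) / 2.0) ** 2).sum())
    tie_term = 0.0
    for row in ranks:
        counts = Counter(row)
        tie_term += sum(c**3 - c for c in counts.values())
    denom = m**2 * n * (n**2 - 1) - m * tie_term
    if denom <= 0:
        log.warning("degenerate rank table (all items tied); W set to 0")
        return 0.0
    return 12.0 * s / denom


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(score_pos > score_neg) with ties counted 1/2."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) != 2:
        raise ValueError("both label classes must be present")
    return float(roc_auc_score(labels, scores))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def competitive_enrichment(gene_stats, members) -> float:
    """Two-sided rank-sum p-value: gene-set members vs the rest.

    ``gene_stats`` maps gene → per-gene phenotype statistic (a dict or
    pandas Series); ``members`` is the gene set.  Members absent from
    ``gene_stats`` are ignored.
    """
    import pandas as pd

    series = pd.Series(gene_stats, dtype=float)
    member_set = {g for g in members if g in series.index}
    if not member_set:
        raise ValueError("gene set has no members with statistics")
    inside = series.loc[list(member_set)].to_numpy()
    outside = series.drop(list(member_set)).to_numpy()
    if outside.size == 0:
        raise ValueError("gene-set complement is empty")
    return float(stats.mannwhitneyu(inside, outside,
                                    alternative="two-sided").pvalue)
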