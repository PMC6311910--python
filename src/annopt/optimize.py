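"""Expression-driven consensus filtering of the annotation matrix.

Pipeline: z-score the expression matrix (per gene), optionally keep only
differentially expressed genes, partition genes with k-means into a
one-hot category matrix C, form the annotation statistic S = A·C with
rows normalised to proportions, and keep — per term — only the
annotations falling in the term's dominant cluster, scaled by that
cluster's share:

    a*_{i,j} = a_{i,j} · c_{j,kmax_i} · s_{i,kmax_i}

Averaging a* over a range of cluster counts k and again over bootstrap
resamples of the samples yields a consensus score per annotation;
annotations scoring below a final threshold (0.1 by default in the
pipeline) are dropped.  Genes whose expression consistently co-clusters
with a term's other members keep high scores; annotations inconsistent
with the expression structure are driven toward zero.

All randomness (k-means initialisation, argmax tie-breaking, bootstrap
column draws) derives from a single master seed via
``numpy.random.SeedSequence``, so a run is fully reproducible.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .diffusion import ProbabilisticAnnotationMatrix

log = logging.getLogger(__name__)

#: tolerance for treating annotation-statistic values as tied at argmax
TIE_TOL = 1e-12


def _values(a) -> np.ndarray:
    """Accept either an annotation-matrix object or a bare ndarray."""
    return np.asarray(getattr(a, "values", a), dtype=float)


def zscore(expr: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardise each gene row to mean 0, sd 1.

    ``ddof=0`` (population sd) is the default convention; pass ``ddof=1``
    for sample sd.  Constant rows are set to all zeros and logged.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    vals = expr.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        log.warning("%d constant gene rows set to zero", int(constant.sum()))
    sd = np.where(sd == 0, 1.0, sd)
    out = (vals - mean) / sd
    out[constant] = 0.0
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def de_filter(
    expr: pd.DataFrame,
    groups,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep genes differentially expressed between two sample groups.

    Uses a two-sample Welch (unequal-variance) t-test per gene and keeps
    genes with p < ``alpha``, preserving row order.  With ``alpha=1``
    every gene with a computable p-value is returned.
    """
    groups = np.asarray(groups)
    if len(groups) != expr.shape[1]:
        raise ValueError("group labels must match the number of samples")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {len(levels)}")
    a = expr.loc[:, groups == levels[0]].to_numpy(dtype=float)
    b = expr.loc[:, groups == levels[1]].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    pvals = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    computable = np.isfinite(pvals)
    keep = computable if alpha >= 1 else computable & (pvals < alpha)
    log.info("DE filter kept %d / %d genes at alpha=%g", int(keep.sum()),
             len(keep), alpha)
    return expr.loc[keep]


def cluster_partition(expr: pd.DataFrame, k: int, seed: int) -> np.ndarray:
    """One-hot n × k gene-cluster matrix from k-means on gene rows.

    Deterministic for a fixed seed.
    """
    n = expr.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        return np.ones((n, 1), dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    labels = km.fit_predict(expr.to_numpy(dtype=float))
    c = np.zeros((n, k), dtype=float)
    c[np.arange(n), labels] = 1.0
    return c


def annotation_statistic(a, c: np.ndarray) -> np.ndarray:
    """Row-normalised annotation statistic S.

    ``S = A·C``; each nonzero row is divided by its sum so rows read as
    per-cluster annotation proportions.  All-zero rows (terms annotating
    nothing) stay zero and are logged.
    """
    av = _values(a)
    c = np.asarray(c, dtype=float)
    if av.shape[1] != c.shape[0]:
        raise ValueError(
            f"annotation matrix has {av.shape[1]} genes but category matrix "
            f"has {c.shape[0]} rows"
        )
    s = av @ c
    row_sums = s.sum(axis=1, keepdims=True)
    zero = row_sums[:, 0] == 0
    if zero.any():
        log.debug("%d terms annotate nothing; statistic rows left zero",
                  int(zero.sum()))
    return np.where(row_sums > 0, s / np.where(row_sums == 0, 1, row_sums), 0.0)


def optimize_step(
    a,
    c: np.ndarray,
    s: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-partition optimisation: keep each term's dominant cluster.

    For term i, ``kmax_i`` is the argmax of row i of S (ties within
    ``TIE_TOL`` broken uniformly at random with ``rng``); the output is
    ``a_{i,j} · c_{j,kmax_i} · s_{i,kmax_i}``.
    """
    av = _values(a)
    t, k = s.shape
    kmax = np.empty(t, dtype=int)
    row_max = s.max(axis=1)
    for i in range(t):
        tied = np.flatnonzero(s[i] >= row_max[i] - TIE_TOL)
        kmax[i] = tied[0] if tied.size == 1 else rng.choice(tied)
    scale = s[np.arange(t), kmax]
    membership = c[:, kmax].T  # (t, n): c_{j, kmax_i}
    return av * membership * scale[:, None]


def _child_seed(seed: int, *key: int) -> np.random.SeedSequence:
    """Stable per-(k or bootstrap) seed stream: depends on the master
    seed and the key only, not on the surrounding loop ranges."""
    return np.random.SeedSequence(int(seed), spawn_key=tuple(key))


def _int_seed(ss: np.random.SeedSequence, index: int = 0) -> int:
    return int(ss.generate_state(index + 1)[index] % (2**31))


def optimize_over_k(
    a,
    expr: pd.DataFrame,
    k_min: int = 3,
    k_max: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Average the per-partition optimisation over k = k_min .. k_max.

    Each k is clustered independently with a seed derived from the master
    seed.
    """
    if k_min < 2:
        raise ValueError("k_min must be at least 2")
    if k_max < k_min:
        raise ValueError("empty cluster-count range")
    if k_max > expr.shape[0]:
        raise ValueError("k_max exceeds the number of genes")
    av = _values(a)
    if av.shape[1] != expr.shape[0]:
        raise ValueError("annotation genes and expression rows differ")
    acc = np.zeros_like(av)
    ks = range(k_min, k_max + 1)
    for k in ks:
        ss = _child_seed(seed, k)
        c = cluster_partition(expr, k, _int_seed(ss, 0))
        s = annotation_statistic(av, c)
        rng = np.random.default_rng(ss)
        acc += optimize_step(av, c, s, rng)
    return acc / len(ks)


def bootstrap_optimize(
    a,
    expr: pd.DataFrame,
    k_min: int = 3,
    k_max: int = 15,
    n_boot: int = 50,
    seed: int = 0,
    ddof: int = 0,
) -> np.ndarray:
    """Consensus annotation scores over bootstrap resamples of samples.

    Each resample draws samples (columns) with replacement, re-z-scores
    the replicate (resampling changes column statistics), runs
    :func:`optimize_over_k` and the ``n_boot`` results are averaged.
    Deterministic for a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    av = _values(a)
    m = expr.shape[1]
    acc = np.zeros_like(av)
    for b in range(n_boot):
        ss = _child_seed(seed, 0, b)  # key level 0 = bootstrap stream
        rng = np.random.default_rng(ss)
        cols = rng.integers(0, m, size=m)
        boot = zscore(expr.iloc[:, cols], ddof=ddof)
        acc += optimize_over_k(a, boot, k_min, k_max, seed=_int_seed(ss, 1))
    return acc / n_boot


def apply_threshold(
    a_final,
    tau: float = 0.1,
    binarize: bool = False,
) -> np.ndarray:
    """Zero out entries strictly below ``tau``.

    With ``binarize=True`` the surviving entries become 1.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    av = _values(a_final)
    out = np.where(av < tau, 0.0, av)
    if binarize:
        out = (out > 0).astype(float) if tau > 0 else (av >= tau).astype(float)
    return out


def filter_scores(
    a0: ProbabilisticAnnotationMatrix,
    a_final: np.ndarray,
) -> pd.Series:
    """Per-gene fraction of curated annotations removed by the optimizer.

    The score (in [0, 1]) is the fraction of the gene's curated (binary)
    annotations whose final optimised value is 0.  Genes with no curated
    annotation get NaN.
    """
    curated = a0.curated
    removed = curated & (np.asarray(a_final) == 0)
    n_curated = curated.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = removed.sum(axis=0) / n_curated
    score[n_curated == 0] = np.nan
    return pd.Series(score, index=list(a0.genes), name="filter_score")
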