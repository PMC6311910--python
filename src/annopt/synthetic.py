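"""Synthetic ontologies, annotations and expression data with known truth.

The generator plants the structure the optimizer is supposed to recover:

* a rooted term tree (optionally with extra cross-edges, making it a
  proper DAG) standing in for a GO namespace;
* gene clusters — each leaf term has a *home* cluster and its consistent
  annotations go to genes of that cluster; a chosen fraction of leaf
  annotations instead point at genes of a *different* cluster and are
  flagged as planted inconsistencies (flagging at leaves only, so the
  true-path closure does not blur the ground truth);
* an expression matrix in which samples fall into per-cluster blocks and
  genes of cluster c are shifted upward in block c, with Gaussian noise.
  The ``effect`` parameter is the per-sample center separation in units
  of ``noise_sd``; effect 0 makes the clusters indistinguishable.

Everything is deterministic per seed.  The generator writes/round-trips
the same OBO / annotation / GMT / TSV formats the real pipeline reads.
It deliberately omits real microarray artefacts (batch effects,
heteroscedastic noise, correlated genes), so results on it bound what
the method can do under clean, well-separated conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import BinaryAnnotationMatrix, OntologyDag, true_path_closure


def gene_names(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


@dataclass
class SyntheticTruth:
    """Ground truth bundle for end-to-end tests."""

    dag: OntologyDag
    annotations: BinaryAnnotationMatrix
    cluster_labels: np.ndarray  # per-gene cluster id, 0 .. k_true-1
    inconsistent_mask: np.ndarray  # (t, n) bool, planted inconsistent leaf pairs
    leaf_annotation_mask: np.ndarray  # (t, n) bool, all planted leaf pairs
    params: dict = field(default_factory=dict)

    @property
    def genes(self) -> tuple[str, ...]:
        return self.annotations.genes


def generate_dag(
    levels: int,
    branching: int,
    seed: int = 0,
    cross_edge_prob: float = 0.0,
) -> OntologyDag:
    """Rooted term tree of given depth and branching factor.

    ``levels`` counts the root level, so the tree has
    ``sum(branching**l for l in range(levels))`` terms.  With
    ``cross_edge_prob`` > 0, each non-root term independently gains one
    extra parent chosen among strictly shallower terms, keeping the graph
    acyclic and single-rooted.
    """
    if levels < 1 or branching < 1:
        raise ValueError("levels and branching must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    terms: list[str] = []
    depth_of: list[int] = []
    edges: set[tuple[str, str]] = set()
    # breadth-first construction
    prev_level: list[int] = []
    counter = 0
    for level in range(levels):
        this_level = []
        n_new = branching ** level
        if level == 0:
            parents = [None]
        else:
            parents = prev_level
        for p in parents:
            for _ in range(branching if level > 0 else 1):
                tid = f"S:{counter:07d}"
                terms.append(tid)
                depth_of.append(level)
                if p is not None:
                    edges.add((terms[p], tid))
                this_level.append(counter)
                counter += 1
        assert len(this_level) == n_new
        prev_level = this_level

    if cross_edge_prob > 0:
        for i, tid in enumerate(terms):
            d = depth_of[i]
            if d == 0 or rng.random() >= cross_edge_prob:
                continue
            shallower = [j for j in range(len(terms)) if depth_of[j] < d]
            existing = {p for p, c in edges if c == tid}
            candidates = [terms[j] for j in shallower if terms[j] not in existing]
            if candidates:
                edges.add((str(rng.choice(candidates)), tid))
    return OntologyDag(terms, edges)


def generate_truth(
    dag: OntologyDag,
    n_genes: int,
    k_true: int = 3,
    p_inconsistent: float = 0.2,
    seed: int = 0,
    genes_per_leaf: int | None = None,
) -> SyntheticTruth:
    """Plant clustered annotations with a flagged inconsistent fraction.

    Genes are split evenly (randomly) into ``k_true`` clusters.  Each
    leaf term gets a home cluster (round-robin over leaves) and
    ``genes_per_leaf`` annotations: a Binomial(genes_per_leaf,
    p_inconsistent) number of them point at genes *outside* the home
    cluster and are recorded in ``inconsistent_mask``; the rest point at
    home-cluster genes.  Annotations are then true-path closed.
    """
    if not 0.0 <= p_inconsistent < 1.0:
        raise ValueError("p_inconsistent must be in [0, 1)")
    if k_true < 2:
        raise ValueError("k_true must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    genes = gene_names(n_genes)
    cluster_labels = rng.permutation(np.arange(n_genes) % k_true)
    by_cluster = [np.flatnonzero(cluster_labels == c) for c in range(k_true)]
    leaves = dag.leaves
    if genes_per_leaf is None:
        genes_per_leaf = max(3, round(n_genes / len(leaves)))

    pairs: list[tuple[str, str]] = []
    t, n = len(dag), n_genes
    inconsistent = np.zeros((t, n), dtype=bool)
    leaf_mask = np.zeros((t, n), dtype=bool)
    for li, leaf in enumerate(leaves):
        home = li % k_true
        home_genes = by_cluster[home]
        away_genes = np.concatenate(
            [by_cluster[c] for c in range(k_true) if c != home]
        )
        n_away = rng.binomial(genes_per_leaf, p_inconsistent)
        n_home = genes_per_leaf - n_away
        n_home = min(n_home, len(home_genes))
        n_away = min(n_away, len(away_genes))
        chosen_home = rng.choice(home_genes, size=n_home, replace=False)
        chosen_away = rng.choice(away_genes, size=n_away, replace=False)
        row = dag.index[leaf]
        for j in chosen_home:
            pairs.append((genes[j], leaf))
            leaf_mask[row, j] = True
        for j in chosen_away:
            pairs.append((genes[j], leaf))
            leaf_mask[row, j] = True
            inconsistent[row, j] = True

    annotations = true_path_closure(pairs, dag, genes=genes)
    return SyntheticTruth(
        dag=dag,
        annotations=annotations,
        cluster_labels=cluster_labels,
        inconsistent_mask=inconsistent,
        leaf_annotation_mask=leaf_mask,
        params=dict(
            n_genes=n_genes,
            k_true=k_true,
            p_inconsistent=p_inconsistent,
            seed=int(seed),
            genes_per_leaf=genes_per_leaf,
        ),
    )


def generate_expression(
    cluster_labels: np.ndarray,
    n_samples: int = 40,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression matrix (genes × samples) with block-structured clusters.

    Samples are assigned round-robin to ``k_true`` blocks; the center of
    cluster c is ``effect * noise_sd`` in block c and 0 elsewhere, and
    i.i.d. Gaussian noise of sd ``noise_sd`` is added.  Two cluster
    centers therefore differ by ``effect * noise_sd`` per sample in two
    blocks of samples.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    cluster_labels = np.asarray(cluster_labels)
    k = int(cluster_labels.max()) + 1
    n = len(cluster_labels)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    sample_block = np.arange(n_samples) % k
    centers = np.zeros((k, n_samples))
    for c in range(k):
        centers[c, sample_block == c] = effect * noise_sd
    x = centers[cluster_labels] + rng.normal(0.0, noise_sd, size=(n, n_samples))
    return pd.DataFrame(
        x,
        index=gene_names(n),
        columns=[f"sample{s:03d}" for s in range(n_samples)],
    )


def sample_groups(n_samples: int, k_true: int) -> np.ndarray:
    """Two-level phenotype labels aligned with the expression blocks:
    block 0 versus the rest.  Useful as input to the DE filter and to
    enrichment statistics on synthetic data."""
    block = np.arange(n_samples) % k_true
    return np.where(block == 0, "case", "control")


def leaf_gene_sets(truth: SyntheticTruth) -> dict[str, list[str]]:
    """Gene sets derived from the planted leaf annotations (one set per
    leaf term), usable as a synthetic GMT collection."""
    sets: dict[str, list[str]] = {}
    genes = truth.genes
    for leaf in truth.dag.leaves:
        row = truth.leaf_annotation_mask[truth.dag.index[leaf]]
        members = [genes[j] for j in np.flatnonzero(row)]
        if members:
            sets[leaf.replace(":", "_")] = members
    return sets
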