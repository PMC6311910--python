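"""Information content and Lin semantic similarity between ontology terms.

The information content (IC) of a term is the negative natural log of its
annotation frequency in a corpus: ``IC(i) = -ln(n_i / n_root)`` where
``n_i`` counts genes annotated by term i.  Because the annotation matrix
is closed under the true-path rule the counts are descendant-inclusive,
so IC never decreases from ancestor to descendant and ``IC(root) = 0``.

Lin similarity between two terms a, b is

    sim(a, b) = 2 * IC(MICA) / (IC(a) + IC(b))

where MICA is the common ancestor of a and b (inclusive of a and b
themselves) with maximal IC.  The measure lies in [0, 1]; any pair whose
only common ancestor is the root scores 0, and sim(a, a) = 1 whenever
IC(a) > 0.  Terms annotating no gene have infinite IC and are excluded
from the similarity matrix (their rows/columns are zero).
"""

from __future__ import annotations

import logging

import numpy as np

from .ontology import BinaryAnnotationMatrix, OntologyDag

log = logging.getLogger(__name__)


def information_content(
    annotations: BinaryAnnotationMatrix, dag: OntologyDag
) -> np.ndarray:
    """Per-term corpus IC; ``+inf`` sentinel for zero-frequency terms.

    Requires the annotation matrix to be true-path closed and at least
    one gene annotated at the root.
    """
    if annotations.terms != dag.terms:
        raise ValueError("annotation matrix and DAG term orders differ")
    counts = annotations.values.sum(axis=1).astype(float)
    root_count = counts[dag.index[dag.root]]
    if root_count == 0:
        raise ValueError("no gene annotated at the root; IC undefined")
    with np.errstate(divide="ignore"):
        ic = -np.log(counts / root_count)
    ic[counts == 0] = np.inf
    return ic


def lin_similarity(
    ic: np.ndarray, dag: OntologyDag, a: str, b: str
) -> float:
    """Lin similarity of a single term pair (see module docstring)."""
    ia, ib = dag.index[a], dag.index[b]
    if not (np.isfinite(ic[ia]) and np.isfinite(ic[ib])):
        raise ValueError("Lin similarity requires finite IC for both terms")
    anc = dag.ancestor_matrix
    common = anc[ia] & anc[ib]
    finite = np.isfinite(ic)
    mica_ic = float(np.max(ic[common & finite], initial=0.0))
    denom = float(ic[ia] + ic[ib])
    if denom == 0.0:
        return 0.0
    return 2.0 * mica_ic / denom


def similarity_matrix(ic: np.ndarray, dag: OntologyDag) -> np.ndarray:
    """Full symmetric t × t Lin similarity matrix.

    Infinite-IC terms (zero annotation frequency) get zero rows and
    columns.  The diagonal is 1 for every term with positive finite IC
    and 0 for the root.
    """
    t = len(dag)
    anc = dag.ancestor_matrix
    finite = np.isfinite(ic)
    ic_masked = np.where(finite, ic, -np.inf)  # never selected as MICA
    sim = np.zeros((t, t), dtype=float)
    for i in range(t):
        if not finite[i]:
            continue
        common = anc & anc[i]  # (t, t): common[j, m] — m common anc of (i, j)
        mica = np.max(np.where(common, ic_masked, -np.inf), axis=1)
        mica = np.maximum(mica, 0.0)  # root is always common, IC(root)=0
        denom = ic[i] + ic
        with np.errstate(invalid="ignore"):
            row = np.where(denom > 0, 2.0 * mica / denom, 0.0)
        row[~finite] = 0.0
        sim[i] = row
    return sim
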