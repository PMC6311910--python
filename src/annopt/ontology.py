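"""Gene Ontology DAG handling.

The ontology is modelled as a rooted directed acyclic graph of terms
connected by ``is_a`` (and optionally ``part_of``) relations, with edges
oriented parent → child.  A fixed term order is shared by every matrix
built downstream (adjacency, similarity, transition, annotation), so the
:class:`OntologyDag` is the single source of truth for term indexing.

Annotations follow the *true-path rule*: a gene annotated with a term is
implicitly annotated with every ancestor of that term, up to the root.
:func:`true_path_closure` materialises that rule into a binary
term × gene matrix.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import obonet

log = logging.getLogger(__name__)

#: identifier used when a parsed ontology has several namespace roots and a
#: single artificial root must be synthesised above them
VIRTUAL_ROOT = "VIRTUAL:ROOT"


class CyclicOntologyError(ValueError):
    """Raised when the term graph contains a cycle (names one cycle edge)."""


class OntologyDag:
    """Rooted DAG of ontology terms.

    Parameters
    ----------
    terms:
        Term identifiers in the canonical order shared by all matrices.
    parent_edges:
        ``(parent, child)`` pairs over is_a (and optionally part_of)
        relations.
    root:
        The unique root term.  If omitted it is inferred; construction
        fails if the graph does not have exactly one parentless term.
    """

    def __init__(
        self,
        terms: Sequence[str],
        parent_edges: Iterable[tuple[str, str]],
        root: str | None = None,
    ):
        self.terms: tuple[str, ...] = tuple(terms)
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate term identifiers")
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.terms)}
        self.parent_edges: frozenset[tuple[str, str]] = frozenset(parent_edges)

        self._parents: dict[str, set[str]] = {t: set() for t in self.terms}
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        for p, c in self.parent_edges:
            if p not in self.index or c not in self.index:
                raise ValueError(f"edge ({p}, {c}) references unknown term")
            self._parents[c].add(p)
            self._children[p].add(c)

        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.parent_edges)
        if not nx.is_directed_acyclic_graph(g):
            edge = nx.find_cycle(g)[0]
            raise CyclicOntologyError(
                f"term graph is cyclic; cycle includes edge {edge[0]} -> {edge[1]}"
            )

        roots = [t for t in self.terms if not self._parents[t]]
        if root is None:
            if len(roots) != 1:
                raise ValueError(
                    f"expected exactly one root, found {len(roots)}: {roots[:5]}"
                )
            root = roots[0]
        elif root not in self.index:
            raise ValueError(f"root {root!r} is not a term")
        self.root = root

        reachable = {self.root} | nx.descendants(g, self.root)
        orphans = set(self.terms) - reachable
        if orphans:
            raise ValueError(
                f"{len(orphans)} terms unreachable from root {self.root!r}, "
                f"e.g. {sorted(orphans)[:5]}"
            )
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self._parents[term])

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._children[term])

    @cached_property
    def leaves(self) -> tuple[str, ...]:
        """Terms without children, in canonical order."""
        return tuple(t for t in self.terms if not self._children[t])

    def ancestors(self, term: str) -> frozenset[str]:
        """All proper ancestors of ``term`` (the term itself excluded)."""
        if term not in self.index:
            raise KeyError(f"unknown term {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        seen: set[str] = set()
        stack = list(self._parents[term])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self._parents[t])
        result = frozenset(seen)
        self._ancestor_cache[term] = result
        return result

    def depth(self, term: str) -> int:
        """Length of the shortest parent path from the root to ``term``."""
        if term == self.root:
            return 0
        d, frontier = 0, {term}
        while frontier:
            if self.root in frontier:
                return d
            d += 1
            frontier = {p for t in frontier for p in self._parents[t]}
        raise ValueError(f"{term!r} not connected to root")

    @cached_property
    def ancestor_matrix(self) -> np.ndarray:
        """Boolean t × t matrix; entry (i, j) is True iff term j is an
        ancestor of term i or j == i (inclusive closure)."""
        t = len(self)
        anc = np.eye(t, dtype=bool)
        for term in self.terms:
            i = self.index[term]
            for a in self.ancestors(term):
                anc[i, self.index[a]] = True
        return anc

    def adjacency_matrix(self) -> np.ndarray:
        """Binary t × t matrix with entry (p, q) = 1 iff q is a direct
        child of p."""
        x = np.zeros((len(self), len(self)), dtype=np.uint8)
        for p, c in self.parent_edges:
            x[self.index[p], self.index[c]] = 1
        return x


def parse_obo(
    document,
    namespace: str | None = "biological_process",
    include_part_of: bool = False,
) -> OntologyDag:
    """Parse an OBO 1.2/1.4 document into an :class:`OntologyDag`.

    Terms are restricted to one namespace (terms carrying no namespace
    information are kept, which makes small hand-written test ontologies
    work without boilerplate).  Obsolete terms are dropped.  Only ``is_a``
    edges are used unless ``include_part_of`` is set.  If several roots
    survive filtering, a virtual root is synthesised above them and
    logged.
    """
    handle = io.StringIO(document) if isinstance(document, str) else document
    graph = obonet.read_obo(handle)  # drops obsolete terms by default

    default_ns = graph.graph.get("default-namespace", [None])[0]
    keep: list[str] = []
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace", default_ns)
        if namespace is None or ns is None or ns == namespace:
            keep.append(node)
    if not keep:
        raise ValueError(f"no terms in namespace {namespace!r}")
    keep_set = set(keep)

    relations = {"is_a"} | ({"part_of"} if include_part_of else set())
    edges: set[tuple[str, str]] = set()
    for child, parent, rel in graph.edges(keys=True):
        if rel in relations and child in keep_set and parent in keep_set:
            edges.add((parent, child))  # obonet orients child -> parent

    has_parent = {c for _, c in edges}
    roots = [t for t in keep if t not in has_parent]
    if len(roots) > 1:
        log.warning(
            "%d roots after namespace filtering; adding virtual root %s",
            len(roots), VIRTUAL_ROOT,
        )
        keep.insert(0, VIRTUAL_ROOT)
        edges |= {(VIRTUAL_ROOT, r) for r in roots}
    elif not roots:
        # every term has a parent: the graph must be cyclic; let the
        # OntologyDag constructor raise the informative error
        pass
    return OntologyDag(keep, edges)


@dataclass
class BinaryAnnotationMatrix:
    """t terms × n genes binary annotation matrix, closed under the
    true-path rule: if gene j is annotated with term i, every ancestor of
    i is also set for gene j."""

    values: np.ndarray  # (t, n) of {0, 1}
    terms: tuple[str, ...]
    genes: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.terms), len(self.genes)):
            raise ValueError("matrix shape does not match term/gene labels")

    @cached_property
    def term_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    @cached_property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def annotated_terms(self, gene: str) -> frozenset[str]:
        """χ_j — the set of terms annotating ``gene``."""
        col = self.values[:, self.gene_index[gene]]
        return frozenset(self.terms[i] for i in np.flatnonzero(col))

    def to_pairs(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.values)
        return [(self.genes[j], self.terms[i]) for i, j in zip(rows, cols)]


def true_path_closure(
    raw_annotations: Iterable[tuple[str, str]],
    dag: OntologyDag,
    genes: Sequence[str] | None = None,
    strict: bool = False,
    drop_unannotated: bool = False,
) -> BinaryAnnotationMatrix:
    """Close raw (gene, term) annotations under the true-path rule.

    Parameters
    ----------
    raw_annotations:
        Iterable of ``(gene, term)`` pairs.
    genes:
        Optional explicit gene universe/order (columns).  Defaults to
        order of first appearance in ``raw_annotations``.  Genes with no
        surviving annotation are kept as all-zero columns unless
        ``drop_unannotated`` is set.
    strict:
        If True an unknown term is a hard error; otherwise it is logged
        and skipped.
    """
    pairs = list(raw_annotations)
    if genes is None:
        seen: dict[str, None] = {}
        for g, _ in pairs:
            seen.setdefault(g)
        gene_order = list(seen)
    else:
        gene_order = list(genes)
    gene_idx = {g: j for j, g in enumerate(gene_order)}

    values = np.zeros((len(dag), len(gene_order)), dtype=np.uint8)
    skipped = 0
    for gene, term in pairs:
        if term not in dag:
            if strict:
                raise KeyError(f"unknown term {term!r} for gene {gene!r}")
            skipped += 1
            log.warning("skipping annotation (%s, %s): unknown term", gene, term)
            continue
        if gene not in gene_idx:
            if genes is not None:
                log.debug("gene %s outside universe, skipped", gene)
                continue
            raise AssertionError("unreachable")
        j = gene_idx[gene]
        values[dag.index[term], j] = 1
        for anc in dag.ancestors(term):
            values[dag.index[anc], j] = 1
    if skipped:
        log.warning("skipped %d annotations with unknown terms", skipped)

    if drop_unannotated:
        keep = np.flatnonzero(values.sum(axis=0) > 0)
        values = values[:, keep]
        gene_order = [gene_order[j] for j in keep]
    return BinaryAnnotationMatrix(values, dag.terms, tuple(gene_order))


def read_gaf(
    handle,
    exclude_evidence: Iterable[str] = (),
) -> list[tuple[str, str]]:
    """Read (gene, term) pairs from a GAF 2.x file.

    ``exclude_evidence`` drops annotations carrying any of the given
    evidence codes (e.g. ``{"IEA"}``).  The gene identifier used is the
    DB Object Symbol.
    """
    from Bio.UniProt import GOA

    excluded = set(exclude_evidence)
    pairs: list[tuple[str, str]] = []
    for rec in GOA.gafiterator(handle):
        if rec["Evidence"] in excluded:
            continue
        if "NOT" in rec.get("Qualifier", []):
            continue
        pairs.append((rec["DB_Object_Symbol"], rec["GO_ID"]))
    return pairs
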