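"""Readers and writers for the pipeline's file formats.

Formats handled: OBO (ontology), GAF 2.x or two-column TSV (annotations),
GMT (gene sets), TSV matrices (expression, annotation/similarity
matrices), one-column TSV (sample group labels) and the JSON run
manifest.  Every writer is the exact inverse of the corresponding reader
so objects round-trip losslessly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ontology import OntologyDag

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


# ----------------------------------------------------------------- GMT
def read_gmt(document: str) -> dict[str, list[str]]:
    """Parse GMT text into an ordered mapping set-name → gene list.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.
    Duplicate genes within a set are dropped (first occurrence kept) with
    a warning.  Malformed lines raise with their line number.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(document.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"GMT line {lineno}: expected >=3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            log.warning(
                "GMT set %s: removed %d duplicate genes",
                name, len(genes) - len(deduped),
            )
        sets[name] = deduped
    return sets


def write_gmt(sets: dict[str, list[str]], descriptions: dict[str, str] | None = None) -> str:
    descriptions = descriptions or {}
    lines = [
        "\t".join([name, descriptions.get(name, "na"), *genes])
        for name, genes in sets.items()
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def filter_gene_sets(
    sets: dict[str, list[str]],
    min_size: int = 15,
    max_size: int = 200,
    universe: set[str] | None = None,
) -> dict[str, list[str]]:
    """Keep sets whose size is within [min_size, max_size] inclusive.

    If a ``universe`` (e.g. the measured genes) is given, sizes are
    counted after intersecting each set with it, and the intersected sets
    are returned.
    """
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    out: dict[str, list[str]] = {}
    for name, genes in sets.items():
        members = [g for g in genes if universe is None or g in universe]
        if min_size <= len(members) <= max_size:
            out[name] = members
    return out


# ----------------------------------------------------------------- OBO
def write_obo(dag: OntologyDag, namespace: str = "biological_process") -> str:
    """Serialise a DAG as a minimal OBO 1.2 document (is_a edges only)."""
    parents: dict[str, list[str]] = {t: [] for t in dag.terms}
    for p, c in sorted(dag.parent_edges):
        parents[c].append(p)
    chunks = ["format-version: 1.2", f"default-namespace: {namespace}", ""]
    for term in dag.terms:
        chunks.append("[Term]")
        chunks.append(f"id: {term}")
        chunks.append(f"name: {term}")
        for p in sorted(parents[term]):
            chunks.append(f"is_a: {p}")
        chunks.append("")
    return "\n".join(chunks)


# ------------------------------------------------------- TSV matrices
def write_matrix_tsv(
    values: np.ndarray,
    rows: list[str],
    cols: list[str],
) -> str:
    df = pd.DataFrame(np.asarray(values), index=list(rows), columns=list(cols))
    return df.to_csv(sep="\t", float_format=FLOAT_FMT)


def read_matrix_tsv(document: str) -> pd.DataFrame:
    import io as _io

    return pd.read_csv(_io.StringIO(document), sep="\t", index_col=0)


def read_expression_tsv(path_or_text) -> pd.DataFrame:
    """Expression TSV: genes as rows (index), header row of sample IDs."""
    p = Path(path_or_text) if "\n" not in str(path_or_text) else None
    if p is not None:
        return pd.read_csv(p, sep="\t", index_col=0)
    return read_matrix_tsv(str(path_or_text))


def read_annotation_pairs_tsv(document: str) -> list[tuple[str, str]]:
    """Two-column TSV of gene<TAB>term annotation pairs (no header)."""
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(document.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"annotation TSV line {lineno}: need 2 columns")
        pairs.append((fields[0], fields[1]))
    return pairs


def write_annotation_pairs_tsv(pairs: list[tuple[str, str]]) -> str:
    return "\n".join(f"{g}\t{t}" for g, t in pairs) + ("\n" if pairs else "")


def read_groups_tsv(document: str) -> pd.Series:
    """Sample group labels: ``sample<TAB>group`` per line (no header)."""
    samples, groups = [], []
    for line in document.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        s, g = line.rstrip("\n").split("\t")[:2]
        samples.append(s)
        groups.append(g)
    return pd.Series(groups, index=samples, name="group")


def write_groups_tsv(groups: pd.Series) -> str:
    return "\n".join(f"{s}\t{g}" for s, g in groups.items()) + "\n"


# ----------------------------------------------------------- RunConfig
@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run plus input/output paths.

    Serialises to/from the JSON run manifest; a manifest is sufficient to
    reproduce a run bit-for-bit.
    """

    # random walk
    beta: float = 0.5
    eps: float = 1e-6
    max_iter: int = 100
    theta_mode: str = "row"
    # clustering / consensus
    k_min: int = 3
    k_max: int = 15
    n_boot: int = 50
    tau: float = 0.1
    # preprocessing
    alpha_de: float = 0.05
    zscore_ddof: int = 0
    # ontology / annotations
    namespace: str = "biological_process"
    include_part_of: bool = False
    exclude_evidence: tuple[str, ...] = ()
    case_fold_genes: bool = False
    # gene sets
    min_set_size: int = 15
    max_set_size: int = 200
    retain_fraction: float = 0.5
    # reproducibility
    seed: int = 0
    # paths (all optional so the config can drive partial stages)
    obo_path: str | None = None
    annotations_path: str | None = None
    expression_path: str | None = None
    groups_path: str | None = None
    gene_sets_path: str | None = None
    out_dir: str = "annopt_out"

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")
        self.exclude_evidence = tuple(self.exclude_evidence)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, document: str) -> "RunConfig":
        return cls(**json.loads(document))
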