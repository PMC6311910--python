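"""End-to-end annotation-optimization pipeline.

Stage order: z-score → optional DE filter → true-path closure → IC /
Lin similarity → transition matrix → steady-state walk → probabilistic
extension → bootstrap consensus optimisation → final threshold →
reports.  Each stage failure aborts with the stage name; a JSON manifest
recording every effective parameter (including the master seed) is
written alongside the output matrices, and re-running with the same
manifest reproduces the outputs byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffusion, optimize, semsim
from .io import (
    RunConfig,
    filter_gene_sets,
    read_annotation_pairs_tsv,
    read_expression_tsv,
    read_gmt,
    read_groups_tsv,
    write_gmt,
    write_matrix_tsv,
)
from .ontology import (
    BinaryAnnotationMatrix,
    OntologyDag,
    parse_obo,
    read_gaf,
    true_path_closure,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Wraps a pipeline-stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run."""

    dag: OntologyDag
    annotations: BinaryAnnotationMatrix
    probabilistic: diffusion.ProbabilisticAnnotationMatrix
    optimized: np.ndarray  # final thresholded t × n matrix
    expression: pd.DataFrame  # normalised (and DE-filtered) expression
    filter_scores: pd.Series
    iterations_used: int


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrapped with context
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def optimize_annotations(
    annotations: BinaryAnnotationMatrix,
    expression: pd.DataFrame,
    dag: OntologyDag,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the computational core on in-memory inputs.

    ``expression`` rows must be the same genes (same order) as the
    annotation matrix columns; it is assumed already normalised.
    """
    config = config or RunConfig()
    if tuple(expression.index) != annotations.genes:
        raise ValueError("expression rows and annotation genes differ")

    ic = semsim.information_content(annotations, dag)
    ssm = semsim.similarity_matrix(ic, dag)
    T = diffusion.transition_matrix(ssm, dag.adjacency_matrix())
    rstar = diffusion.steady_state(
        T, beta=config.beta, eps=config.eps, max_iter=config.max_iter
    )
    prob = diffusion.extend_annotations(
        annotations, rstar, theta_mode=config.theta_mode
    )
    consensus = optimize.bootstrap_optimize(
        prob,
        expression,
        k_min=config.k_min,
        k_max=config.k_max,
        n_boot=config.n_boot,
        seed=config.seed,
        ddof=config.zscore_ddof,
    )
    final = optimize.apply_threshold(consensus, tau=config.tau)
    scores = optimize.filter_scores(prob, final)
    return PipelineResult(
        dag=dag,
        annotations=annotations,
        probabilistic=prob,
        optimized=final,
        expression=expression,
        filter_scores=scores,
        iterations_used=rstar.iterations_used,
    )


@_stage("read_inputs")
def _read_inputs(config: RunConfig):
    for name in ("obo_path", "annotations_path", "expression_path"):
        value = getattr(config, name)
        if value is None:
            raise FileNotFoundError(f"config.{name} is required")
        if not Path(value).exists():
            raise FileNotFoundError(f"config.{name}: no such file: {value}")
    dag = parse_obo(
        Path(config.obo_path).read_text(),
        namespace=config.namespace,
        include_part_of=config.include_part_of,
    )
    ann_path = Path(config.annotations_path)
    if ann_path.suffix.lower() == ".gaf":
        with ann_path.open() as handle:
            pairs = read_gaf(handle, exclude_evidence=config.exclude_evidence)
    else:
        pairs = read_annotation_pairs_tsv(ann_path.read_text())
    expr = read_expression_tsv(Path(config.expression_path))
    groups = None
    if config.groups_path:
        groups = read_groups_tsv(Path(config.groups_path).read_text())
        groups = groups.reindex(expr.columns)
        if groups.isna().any():
            raise ValueError("group labels missing for some samples")
    gene_sets = None
    if config.gene_sets_path:
        gene_sets = read_gmt(Path(config.gene_sets_path).read_text())
    if config.case_fold_genes:
        pairs = [(g.upper(), t) for g, t in pairs]
        expr.index = expr.index.str.upper()
        if gene_sets:
            gene_sets = {
                name: [g.upper() for g in genes]
                for name, genes in gene_sets.items()
            }
    return dag, pairs, expr, groups, gene_sets


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Full file-to-file run; returns the in-memory results as well."""
    dag, pairs, expr, groups, gene_sets = _read_inputs(config)

    @_stage("normalize")
    def _normalize():
        return optimize.zscore(expr, ddof=config.zscore_ddof)

    expr_z = _normalize()

    if groups is not None:
        @_stage("de_filter")
        def _de():
            return optimize.de_filter(expr_z, groups.to_numpy(),
                                      alpha=config.alpha_de)

        expr_z = _de()

    @_stage("closure")
    def _closure():
        return true_path_closure(pairs, dag, genes=list(expr_z.index))

    annotations = _closure()

    @_stage("optimize")
    def _core():
        return optimize_annotations(annotations, expr_z, dag, config)

    result = _core()

    @_stage("write_outputs")
    def _write():
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        terms, genes = list(dag.terms), list(annotations.genes)
        (out / "probabilistic_annotations.tsv").write_text(
            write_matrix_tsv(result.probabilistic.values, terms, genes)
        )
        (out / "curated_mask.tsv").write_text(
            write_matrix_tsv(
                result.probabilistic.curated.astype(int), terms, genes
            )
        )
        (out / "optimized_annotations.tsv").write_text(
            write_matrix_tsv(result.optimized, terms, genes)
        )
        (out / "filter_scores.tsv").write_text(
            result.filter_scores.to_csv(sep="\t", float_format="%.10g")
        )
        if gene_sets is not None:
            universe = set(genes)
            kept = filter_gene_sets(
                gene_sets,
                min_size=config.min_set_size,
                max_size=config.max_set_size,
                universe=universe,
            )
            def _keep(g: str) -> bool:
                score = result.filter_scores.get(g)
                if score is None or np.isnan(score):
                    return True  # never annotated -> nothing to filter on
                return 1.0 - score >= config.retain_fraction

            filtered = {
                name: [g for g in members if _keep(g)]
                for name, members in kept.items()
            }
            (out / "filtered_gene_sets.gmt").write_text(write_gmt(filtered))
        manifest = dict(
            config=config.to_json(),
            iterations_used=result.iterations_used,
            n_terms=len(terms),
            n_genes=len(genes),
            n_samples=int(result.expression.shape[1]),
        )
        import json

        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )

    _write()
    return result
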