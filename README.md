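# annopt

Gene-set annotation optimization combining Gene Ontology structure and
gene-expression data.

Curated GO annotations are incomplete and often too general, and some
annotations are simply inconsistent with what a given expression dataset
shows. `annopt` addresses both problems in one pipeline:

1. **Extension** — the binary term × gene annotation matrix *A* is
   extended into a probabilistic one by a *downward random walk with
   restart* over the ontology DAG. Edge weights are Lin semantic
   similarities `sim(p, q) = 2·IC(MICA) / (IC(p) + IC(q))` computed from
   the annotation corpus itself; per child q the weights are normalised
   over its ancestors into a transition matrix *T*, and the walk

   ```
   R_{k+1} = β·R_k·T + (1 − β)·I
   ```

   is iterated to its steady state *R\**. An unannotated pair
   (term *i*, gene *j*) receives the score
   `Σ_{e ∈ χ_j} R*(e, i)` over the gene's annotated terms χ_j, keeping
   only contributions above the per-row mean of *R\** and clamping at 1;
   curated annotations stay exactly 1.

2. **Optimization** — genes are partitioned by k-means on their
   (z-scored, optionally DE-filtered) expression profiles into a one-hot
   category matrix *C*; the annotation statistic `S = A·C`, row-normalised
   to proportions, identifies each term's dominant expression cluster, and

   ```
   a*_{i,j} = a_{i,j} · c_{j,kmax_i} · s_{i,kmax_i}
   ```

   keeps only annotations in that cluster (argmax ties broken at
   random). Averaging *A\** over a range of cluster counts (default
   k = 3..15) and over bootstrap resamples of the samples (default 50)
   yields a consensus score per annotation; entries below τ = 0.1 are
   set to zero.

3. **Evaluation** — tie-corrected Kendall's coefficient of concordance
   W over bootstrap enrichment rankings (replication), rank-based
   ROC/AUC against core/non-core gene labels (filtering accuracy),
   Benjamini–Hochberg FDR of competitive enrichment p-values
   (enrichment power).

A synthetic-data module generates ontologies, true-path-closed
annotations with a planted fraction of wrong-cluster annotations, and
block-structured expression matrices, so the whole pipeline is testable
without any download.

## Worked example

`examples/02_optimize_synthetic.py` plants 3 expression clusters across
200 genes and corrupts ~20% of the leaf annotations to point at genes
from the wrong cluster, then runs the full method (β = 0.5, k = 3..8,
20 bootstrap resamples):

```
planted leaf annotations : 198 (39 inconsistent)
ranking AUC (inconsistent scored lowest): 1.000
inconsistent removed at tau=0.1 : 100.0%
consistent retained at tau=0.1  : 100.0%
```

The AUC of 1.0 means the consensus score ranks every planted
inconsistent annotation below every consistent one under these
well-separated conditions; at the final 0.1 threshold all planted
errors are removed and no genuine annotation is lost. The other
examples show the diffusion step on a five-term ontology
(`01_extend_annotations.py`) and the evaluation metrics on a toy
enrichment study (`03_evaluate_metrics.py`).

The `annopt` command wraps the same library: `annopt simulate` writes a
synthetic OBO/annotations/expression/GMT bundle, `annopt run --config
cfg.json` executes the file-to-file pipeline (all parameters and the
master seed live in the JSON config, echoed to a run manifest that
reproduces the run byte-for-byte), and `annopt evaluate` computes the
metrics from TSV inputs.

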