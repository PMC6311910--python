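# Methods

## Model

The method treats gene annotation as a two-source inference problem: the
ontology DAG says which functions are *structurally plausible* for a
gene (descendants of what is already curated), and the expression matrix
says which functions are *empirically consistent* (shared by genes that
co-express). The pipeline composes the two: a structure-driven extension
step that can only add candidate annotations, followed by an
expression-driven filtering step that can only remove or down-weight
them.

### Annotation matrix and extension

Annotations form a t × n matrix over terms × genes, closed under the
true-path rule (an annotation to a term implies annotations to all its
ancestors). Extension scores unannotated (term, gene) pairs with a
downward random walk with restart:

* **Edge weights.** Each parent → child edge (p, q) carries
  `trans(p, q) = sim(p, q)`, the Lin similarity
  `2·IC(MICA)/(IC(p)+IC(q))`, where IC is the corpus information
  content `−ln(n_term / n_root)` computed from the input annotation
  matrix itself (the corpus choice is deliberate: it requires no
  external annotation release and adapts the walk to the experiment's
  own gene universe). The MICA search includes the two query terms, so
  self-similarity is 1. Terms annotating no gene have infinite IC and
  are excluded (zero similarity rows/columns).
* **Normalisation.** Per child q the incoming weights are divided by
  the total weight from q's ancestors. Since weights live only on
  direct parent edges and parents are ancestors, this is the column
  sum; non-degenerate columns of T sum to exactly 1.
* **A structural zero worth knowing.** IC(root) = 0 makes Lin
  similarity 0 on every root → child edge, so depth-1 terms whose only
  parent is the root get all-zero (degenerate) transition columns: the
  walk cannot descend from the root directly. This follows from the
  formulas as stated; the implementation logs each degenerate column
  rather than patching the weights.
* **Walk.** `R_{k+1} = β R_k T + (1−β) I` from `R_0 = I`, stopping when
  the summed absolute change drops below ε. On a DAG, T is nilpotent
  (strictly downward), so the iteration terminates *exactly* after
  about depth + 2 steps — observed iteration counts of 3–8 on toy
  ontologies, comfortably under the walk's `max_iter`, and the fixed
  point equals the closed form `(1−β)(I−βT)^{-1}` to machine precision
  (this is asserted in the tests against the matrix-inverse oracle).
* **Scores.** For gene j with annotated set χ_j, the candidate score of
  term i is `Σ_{e∈χ_j} R*(e, i)`, keeping only contributions strictly
  above θ_e. θ is per-row by default: the arithmetic mean of row e of
  R* over all t entries, zeros and diagonal included (alternatives —
  one global mean, or the mean over nonzero entries — are config
  options). Sums above 1 are clamped and logged so entries read as
  probabilities; curated entries are exactly 1.

### Consensus filtering

Given the probabilistic matrix A and a normalised expression matrix:

1. k-means on gene rows yields a one-hot n × k category matrix C
   (`n_init=10`, seeded).
2. `S = A·C` with nonzero rows normalised to sum 1 gives each term's
   distribution of annotation mass over clusters.
3. Per term the dominant cluster kmax (argmax of the S row, ties within
   1e-12 broken uniformly at random) is kept:
   `a* = a_{i,j}·c_{j,kmax}·s_{i,kmax}`.
4. Step 1–3 are averaged over k = k_min..k_max (defaults 3 and 15, the
   range used in the reference experiments) and over n_boot bootstrap
   resamples (default 50) of *samples* (columns, with replacement) —
   genes keep their identity so the annotation alignment is stable.
   Each replicate is re-z-scored because resampling changes column
   statistics.
5. Entries of the final average below τ = 0.1 are set to 0.

The filter is sound by construction: `support(A*_final) ⊆ support(A)`
and no entry ever exceeds its input value (s ≤ 1, c ∈ {0,1}, and
averaging is convex).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| β | 0.5 | restart balance of the walk; larger values push more mass to deeper descendants. Exposed because no canonical value exists. |
| ε | 1e-6 | L1 convergence tolerance of the walk; nilpotency makes the result insensitive to it. |
| max_iter | 100 | safety bound; non-convergence is a hard error carrying the last residual. |
| θ mode | per-row mean | removes the walk's many near-zero transition probabilities before summing. |
| k_min..k_max | 3..15 | cluster-count consensus range. |
| n_boot | 50 | bootstrap resamples of samples. |
| τ | 0.1 | final threshold on the consensus score. |
| α (DE filter) | 0.05 | Welch t-test threshold for keeping differentially expressed genes; Welch because group variances are not assumed equal. |
| z-score ddof | 0 | population-sd convention; ddof=1 available. |

All randomness (k-means init, tie-breaks, bootstrap draws) derives from
one master seed through `SeedSequence(seed, spawn_key=...)` streams keyed
by cluster count and bootstrap index, so runs are byte-reproducible and
a single-k run reproduces the corresponding component of a range run.

## Evaluation metrics

* **Kendall's W** with midrank tie correction,
  `W = 12·S / (m²n(n²−1) − m·ΣT)`; a degenerate table (all items tied)
  returns 0 with a warning.
* **ROC/AUC** is the rank-based area (ties ½). The per-gene filter
  score used against core/non-core labels is the fraction of the gene's
  curated annotations removed — a continuous score, so a full curve can
  be drawn rather than a single hard call.
* **BH-FDR** via the standard step-up adjustment.
* **Competitive enrichment** is a two-sided rank-sum test of member vs
  non-member gene statistics. It is a simple stand-in: it ignores
  inter-gene correlation, so its p-values are optimistic on correlated
  real data; externally computed enrichment p-values (e.g. from
  CAMERA/limma) can be supplied instead wherever a p-value table is
  accepted.

## Synthetic data

The generator produces a rooted term tree (optional cross-edges at a
stated probability make it a non-tree DAG while preserving the single
root), balanced random gene clusters, per-leaf annotations of which a
Binomial(genes_per_leaf, p_inconsistent) share point at wrong-cluster
genes (flagged at leaf level only, so closure does not blur the ground
truth), and an expression matrix with block-structured cluster centers:
samples fall round-robin into one block per cluster and cluster c is
up-shifted by `effect·noise_sd` in block c — a condition-specific
expression pattern. `effect = 0` makes clusters indistinguishable;
`effect ≥ 5` makes k-means recovery exact.

What passing tests on this substrate do **not** show: robustness to
batch effects, heteroscedastic noise, correlated genes, mismatched gene
identifiers, or annotation corpora whose IC distribution differs
substantially from the experiment's genes. The synthetic conditions
(200 genes, 40 samples, 2-sd effects, 20% planted inconsistency) are
clean and well separated; real microarray data sit far from them, so
synthetic recovery rates are upper bounds, not forecasts.

## Numerical and design notes

* Degenerate transition columns and all-zero statistic rows are left
  zero and logged, never renormalised silently.
* The consensus average is implemented as the mean over bootstrap
  averages (each itself a mean over k), the natural reading of the
  procedure; the final averaging step is convex so values stay in [0,1].
* Argmax ties are detected with a 1e-12 tolerance before the random
  tie-break, so floating-point noise does not masquerade as a tie.
* Constant expression rows z-score to 0 (logged); a DE filter with
  α = 1 keeps every gene with a computable p-value.
* Gene identifiers are matched as exact strings across
  OBO/annotations/expression/GMT inputs; an optional case-fold flag
  upper-cases everything first. No symbol mapping is attempted.
* The gene-set size filter (default 15..200, inclusive) is applied
  after intersecting each set with the measured genes, because set
  sizes are data-dependent.
* Problem sizes in the test suite and the reproduction script (toy
  DAGs ≤ 200 terms, ≤ 200 genes, 20–50 bootstraps) were chosen as the
  smallest sizes at which the planted structure is unambiguous and
  every invariant is exercised.

## Limitations

* The walk only adds descendants of already-annotated terms; functions
  outside the curated neighbourhood are unreachable by design.
* Filtering assumes one dominant expression cluster per term;
  genuinely multi-cluster functions (housekeeping, pleiotropic terms)
  are penalised.
* The IC corpus defaults to the input annotations; very small gene
  universes give coarse IC estimates and hence coarse similarities.
* k-means with Euclidean distance on z-scored profiles is the only
  built-in clusterer; the category-matrix interface accepts any one-hot
  matrix if another clustering is preferred.
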