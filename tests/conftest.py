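import numpy as np
import pytest

from annopt import (
    OntologyDag,
    RunConfig,
    generate_dag,
    generate_expression,
    generate_truth,
    optimize_annotations,
    true_path_closure,
    zscore,
)

CHAIN_OBO = """format-version: 1.2

[Term]
id: r
name: root

[Term]
id: a
name: mid
is_a: r

[Term]
id: b
name: leaf
is_a: a
"""


@pytest.fixture(scope="session")
def chain_dag():
    """Three-term chain r -> a -> b."""
    return OntologyDag(["r", "a", "b"], {("r", "a"), ("a", "b")})


@pytest.fixture(scope="session")
def diamond_dag():
    """Diamond: r -> a -> c, r -> b -> c."""
    return OntologyDag(
        ["r", "a", "b", "c"],
        {("r", "a"), ("r", "b"), ("a", "c"), ("b", "c")},
    )


@pytest.fixture(scope="session")
def chain_corpus(chain_dag):
    """Closed annotations with term gene counts r:3, a:2, b:1."""
    return true_path_closure(
        [("g1", "b"), ("g2", "a"), ("g3", "r")], chain_dag
    )


@pytest.fixture(scope="session")
def fan_dag():
    """Five-term DAG r -> a, a -> {b, c, d} used for hand-computed
    diffusion values."""
    return OntologyDag(
        ["r", "a", "b", "c", "d"],
        {("r", "a"), ("a", "b"), ("a", "c"), ("a", "d")},
    )


@pytest.fixture(scope="session")
def small_truth():
    """Small planted-structure bundle shared by optimizer tests."""
    dag = generate_dag(3, 3, seed=11)
    truth = generate_truth(dag, n_genes=60, k_true=3, p_inconsistent=0.2,
                           seed=12)
    expr = generate_expression(truth.cluster_labels, n_samples=24,
                               effect=4.0, noise_sd=1.0, seed=13)
    return truth, zscore(expr)


@pytest.fixture(scope="session")
def small_run(small_truth):
    """A completed small pipeline run (consensus + threshold)."""
    truth, expr = small_truth
    config = RunConfig(k_min=3, k_max=5, n_boot=5, seed=21)
    result = optimize_annotations(truth.annotations, expr, truth.dag, config)
    return truth, expr, config, result


def random_ssm(t: int, seed: int) -> np.ndarray:
    """Random symmetric similarity-like matrix in [0, 1], unit diagonal."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.05, 1.0, size=(t, t))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m
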