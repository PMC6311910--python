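"""Downward random walk with restart over the ontology DAG.

The walk runs from each term toward its descendants on edges weighted by
semantic similarity.  Edge weights ``trans(p, q) = SSM(p, q) * X(p, q)``
(similarity times adjacency) are normalised per child q by the total
weight flowing in from its ancestors, giving the transition matrix T.
Since ``trans`` is nonzero only on direct parent edges and every parent
is an ancestor, the ancestor-sum denominator equals the column sum.

The walk with restart iterates

    R_{k+1} = beta * R_k * T + (1 - beta) * I,      R_0 = I

until the elementwise L1 change drops below ``eps``.  On a DAG, T is
nilpotent (T^d = 0 at depth d), so the iteration converges *exactly*
after about depth + 1 steps, and the fixed point equals the closed form
``(1 - beta) * (I - beta T)^{-1}``.

The steady state extends a binary annotation matrix into a probabilistic
one: for an unannotated pair (term i, gene j) the score is the sum of
R*(e, i) over the gene's annotated terms e ∈ χ_j, keeping only
contributions exceeding the per-row mean threshold θ_e, and clamped to 1
so the result reads as a probability.  Curated annotations stay exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .ontology import BinaryAnnotationMatrix

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Random-walk iteration failed to reach the tolerance."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"steady state not reached after {max_iter} iterations "
            f"(last residual {residual:.3e})"
        )
        self.residual = residual
        self.max_iter = max_iter


@dataclass
class SteadyState:
    """Converged restart-walk matrix R* with its parameters."""

    values: np.ndarray  # (t, t)
    beta: float
    iterations_used: int


@dataclass
class ProbabilisticAnnotationMatrix:
    """t × n annotation matrix with curated 1s and diffused probabilities.

    ``curated`` marks the entries that were 1 in the input binary matrix;
    those are exactly 1 in ``values``.  All other entries are diffusion
    scores in [0, 1].
    """

    values: np.ndarray  # (t, n) in [0, 1]
    curated: np.ndarray  # (t, n) bool
    terms: tuple[str, ...]
    genes: tuple[str, ...]

    @cached_property
    def term_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    @cached_property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def transition_matrix(ssm: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """Ancestor-normalised transition matrix T(p, q).

    Columns whose incoming weight is all zero (e.g. similarity 0 on every
    parent edge) are left all-zero and logged as degenerate.
    """
    ssm = np.asarray(ssm, dtype=float)
    adj = np.asarray(adj)
    if ssm.shape != adj.shape or ssm.shape[0] != ssm.shape[1]:
        raise ValueError(f"shape mismatch: ssm {ssm.shape} vs adj {adj.shape}")
    trans = ssm * adj
    col_sums = trans.sum(axis=0)
    degenerate = (col_sums == 0) & (adj.sum(axis=0) > 0)
    if degenerate.any():
        log.warning(
            "%d child columns have zero incoming weight; left degenerate",
            int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(col_sums > 0, trans / col_sums, 0.0)
    return T


def steady_state(
    T: np.ndarray,
    beta: float = 0.5,
    eps: float = 1e-6,
    max_iter: int = 100,
) -> SteadyState:
    """Iterate the restart walk to its steady state R*.

    Raises :class:`ConvergenceError` (carrying the last residual) if the
    L1 change has not dropped below ``eps`` within ``max_iter`` steps.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    T = np.asarray(T, dtype=float)
    t = T.shape[0]
    identity = np.eye(t)
    restart = (1.0 - beta) * identity
    R = identity.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        R_next = beta * (R @ T) + restart
        residual = float(np.abs(R_next - R).sum())
        R = R_next
        if residual < eps:
            log.debug("steady state after %d iterations (residual %.2e)", it, residual)
            return SteadyState(R, beta, it)
    raise ConvergenceError(residual, max_iter)


def extend_annotations(
    a0: BinaryAnnotationMatrix,
    rstar: SteadyState,
    theta_mode: str = "row",
) -> ProbabilisticAnnotationMatrix:
    """Extend binary annotations into diffusion probabilities.

    ``theta_mode`` selects the small-value threshold θ applied to R*
    contributions before summing:

    - ``"row"`` (default): θ_e is the arithmetic mean of row e of R*
      over all t entries (zeros and diagonal included);
    - ``"global"``: one θ, the grand mean of R*;
    - ``"row_nonzero"``: per-row mean over nonzero entries only.

    Contributions must exceed θ strictly.  Sums above 1 are clamped (and
    counted in the log) so every entry reads as a probability.
    """
    R = rstar.values
    if R.shape[0] != len(a0.terms):
        raise ValueError("R* and annotation matrix term orders differ")
    if theta_mode == "row":
        theta = R.mean(axis=1)[:, None]
    elif theta_mode == "global":
        theta = np.full((R.shape[0], 1), R.mean())
    elif theta_mode == "row_nonzero":
        nz = (R != 0).sum(axis=1)
        theta = np.where(nz > 0, R.sum(axis=1) / np.maximum(nz, 1), 0.0)[:, None]
    else:
        raise ValueError(f"unknown theta_mode {theta_mode!r}")

    filtered = np.where(R > theta, R, 0.0)
    # A(i, j) = sum_{e in chi_j} R*(e, i) over surviving contributions
    diffused = filtered.T @ a0.values.astype(float)
    clamped = int((diffused > 1.0).sum())
    if clamped:
        log.info("clamped %d diffused scores above 1 to 1", clamped)
    curated = a0.values.astype(bool)
    values = np.where(curated, 1.0, np.clip(diffused, 0.0, 1.0))
    return ProbabilisticAnnotationMatrix(values, curated, a0.terms, a0.genes)
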