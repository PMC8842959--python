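"""Selection-index (pseudo-BLUP) engine.

Combines information sources by solving for the optimal linear index:
``weights = P^-1 c`` where ``P`` is the covariance matrix among sources and
``c`` the vector of covariances between each source and the breeding goal.
The index reliability is ``c' P^-1 c / var(goal)``.

This is an independent derivation route: the two-predictor problems built
here reproduce the closed-form merge formulas of
:mod:`gebvrel.info_combining` from first principles (covariance structure),
rather than by algebraic simplification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .info_combining import FULL_GENETIC, MARKER_CAPTURED

__all__ = ["IndexProblem", "solve_index", "build_two_predictor_problem"]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class IndexProblem:
    """A selection-index specification on the unit phenotypic-variance scale.

    Attributes
    ----------
    source_cov
        Symmetric positive-definite covariance matrix among sources.
    target_cov
        Covariances between each source and the breeding goal.
    target_var
        Variance of the breeding goal (equals the heritability here).
    """

    source_cov: np.ndarray
    target_cov: np.ndarray
    target_var: float

    def __post_init__(self) -> None:
        P = np.atleast_2d(np.asarray(self.source_cov, dtype=float))
        c = np.atleast_1d(np.asarray(self.target_cov, dtype=float))
        object.__setattr__(self, "source_cov", P)
        object.__setattr__(self, "target_cov", c)
        if P.shape[0] != P.shape[1]:
            raise ValueError(f"source_cov must be square, got shape {P.shape}")
        if not np.allclose(P, P.T):
            raise ValueError("source_cov must be symmetric")
        if c.shape[0] != P.shape[0]:
            raise ValueError(
                f"target_cov length {c.shape[0]} does not match source_cov dimension {P.shape[0]}"
            )
        if self.target_var <= 0.0:
            raise ValueError(f"target_var must be positive, got {self.target_var}")


def solve_index(problem: IndexProblem) -> tuple[np.ndarray, float]:
    """Optimal index weights and the resulting reliability.

    Returns ``(weights, reliability)`` with ``weights = P^-1 c`` and
    ``reliability = c' P^-1 c / target_var``.  Near-singular source
    covariance (condition number above 1e12) indicates a redundant source
    and raises ``np.linalg.LinAlgError``.
    """
    P, c = problem.source_cov, problem.target_cov
    # SPD contract: factorize rather than invert; catches non-PD input too.
    try:
        L = np.linalg.cholesky(P)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "source covariance is not positive definite (redundant or inconsistent source)"
        ) from err
    if np.linalg.cond(P) > _COND_LIMIT:
        corr = P / np.sqrt(np.outer(np.diag(P), np.diag(P)))
        i, j = divmod(int(np.abs(corr - np.eye(len(P))).argmax()), len(P))
        raise np.linalg.LinAlgError(
            f"source covariance is near-singular; sources {i} and {j} are nearly redundant"
        )
    z = np.linalg.solve(L, c)
    weights = np.linalg.solve(L.T, z)
    reliability = float(z @ z) / problem.target_var
    return weights, reliability


def build_two_predictor_problem(
    r1_sq: float,
    r2_sq: float,
    q2: float,
    heritability: float,
    shared_component: str = FULL_GENETIC,
) -> IndexProblem:
    """Index problem for two unbiased EBV with independent sampling errors.

    Each source ``i`` has variance and goal-covariance ``r_i^2 * h2`` (BLUP
    property: var(EBV) = cov(EBV, goal)).  The cross-source covariance
    comes from the true component both predict:

    * ``marker_captured`` (two subpopulation GEBV): both regress on the
      same marker component of variance ``q2*h2``, giving
      ``cov = r1^2 * r2^2 * h2 / q2``;
    * ``full_genetic`` (pedigree + genomic-deviation EBV): both regress on
      the full genetic effect, giving ``cov = r1^2 * r2^2 * h2``.
    """
    if shared_component not in (MARKER_CAPTURED, FULL_GENETIC):
        raise ValueError(f"unknown shared_component {shared_component!r}")
    if not 0.0 < q2 <= 1.0:
        raise ValueError(f"q2 must be in (0, 1], got {q2}")
    if not 0.0 <= heritability <= 1.0:
        raise ValueError(f"heritability must be in [0, 1], got {heritability}")
    limit = q2 if shared_component == MARKER_CAPTURED else 1.0
    for name, val in (("r1_sq", r1_sq), ("r2_sq", r2_sq)):
        if not 0.0 <= val <= limit:
            raise ValueError(f"{name} must be in [0, {limit}], got {val}")

    h2 = heritability
    cross = r1_sq * r2_sq * h2
    if shared_component == MARKER_CAPTURED:
        cross /= q2
    P = np.array([[r1_sq * h2, cross], [cross, r2_sq * h2]])
    c = np.array([r1_sq * h2, r2_sq * h2])

    # drop uninformative sources so P stays positive definite
    keep = np.array([r1_sq > 0.0, r2_sq > 0.0])
    if not keep.any():
        # degenerate: no information at all; keep one zero source and let
        # the caller read reliability 0 from a 1x1 problem
        P = np.array([[1.0]])
        c = np.array([0.0])
    else:
        P = P[np.ix_(keep, keep)]
        c = c[keep]
    return IndexProblem(P, c, h2)
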