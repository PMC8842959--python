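"""Deterministic single-population reliability equations.

All expressions treat the squared accuracy (reliability) of a genomic
estimated breeding value as a proportion of variance explained.  The
phenotypic variance is normalized to 1 throughout, so the additive genetic
variance equals the heritability ``h2``.

Three nested levels of approximation are provided:

* ``reliability_single_segment`` — the R-squared due to a single effective
  chromosome segment, ignoring that all segments are fitted jointly
  (exact and large-``m_effective`` approximate forms);
* ``reliability_joint_fit`` — accounts for the reduction in residual
  variance from fitting all segments simultaneously, which turns the
  fixed-point relation into a quadratic in the reliability;
* ``reliability_dekkers_variant`` — an earlier published closed form that
  differs in how the residual-variance reduction is scaled, retained for
  comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "PopulationParams",
    "ReliabilityResult",
    "ResidualVariance",
    "progeny_test_reliability",
    "theta_marker",
    "reliability_single_segment",
    "residual_variance_joint",
    "reliability_joint_fit",
    "reliability_dekkers_variant",
]

# Fixed-point solver settings; the update map is a contraction on [0, 1]
# for admissible parameters, so non-convergence signals an internal error.
_FP_TOL = 1e-12
_FP_MAX_ITER = 10_000


@dataclass(frozen=True)
class PopulationParams:
    """Design scalars of a genomic reference population.

    Parameters
    ----------
    n_reference
        Number of genotyped and phenotyped individuals (``N``).
    heritability
        Fraction of phenotypic variance that is additive genetic (``h2``);
        the phenotypic variance is normalized to 1.
    q2
        Fraction of the additive genetic variance captured by the markers.
    m_effective
        Number of effective chromosome segments (``Me``): independent,
        equal-variance segments that jointly explain all additive variance.
    """

    n_reference: int
    heritability: float
    q2: float
    m_effective: int

    def __post_init__(self) -> None:
        if self.n_reference < 0 or self.n_reference != int(self.n_reference):
            raise ValueError(f"n_reference must be a non-negative integer, got {self.n_reference}")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError(f"heritability must be in [0, 1], got {self.heritability}")
        if not 0.0 <= self.q2 <= 1.0:
            raise ValueError(f"q2 must be in [0, 1], got {self.q2}")
        if self.m_effective < 1 or self.m_effective != int(self.m_effective):
            raise ValueError(f"m_effective must be a positive integer, got {self.m_effective}")

    @property
    def segment_variance(self) -> float:
        """Phenotypic variance explained by one marker-captured segment."""
        return self.q2 * self.heritability / self.m_effective


@dataclass(frozen=True)
class ReliabilityResult:
    """A reliability value with provenance.

    ``route`` names the closed form that produced the value; the
    ``residual_assumption`` records how the residual variance of the
    underlying regression was treated:

    * ``segment_only`` — only the focal segment removed from the residual;
    * ``fixed_reference_r2`` — residual reduced by a frozen, externally
      supplied reliability;
    * ``joint_fit`` — residual reduced self-consistently by the output
      reliability itself.
    """

    r2: float
    route: str
    residual_assumption: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"reliability must lie in [0, 1], got {self.r2}")


class ResidualVariance(NamedTuple):
    exact: float
    approx: float


def progeny_test_reliability(n_progeny: int, heritability: float) -> float:
    """Reliability of a sire EBV from a progeny test with unrelated dams.

    The progeny-mean R-squared due to the sire:
    ``r2 = n*h2 / (n*h2 + 4 - h2)``, equivalently
    ``sigma_s2 / (sigma_s2 + (1 - sigma_s2)/n)`` with
    ``sigma_s2 = h2/4`` on the unit phenotypic-variance scale.
    """
    if n_progeny < 0:
        raise ValueError(f"n_progeny must be non-negative, got {n_progeny}")
    if not 0.0 <= heritability <= 1.0:
        raise ValueError(f"heritability must be in [0, 1], got {heritability}")
    if n_progeny == 0:
        return 0.0
    return n_progeny * heritability / (n_progeny * heritability + 4.0 - heritability)


def theta_marker(params: PopulationParams) -> float:
    """Fisher information for the marker-captured genetic component.

    ``theta = N * q2 * h2 / Me``: the proportion of phenotypic variance
    explained by one segment, times the number of reference records.
    """
    return params.n_reference * params.q2 * params.heritability / params.m_effective


def reliability_single_segment(
    params: PopulationParams, approximate: bool = False
) -> ReliabilityResult:
    """Reliability from the R-squared of a single segment, times ``q2``.

    Exact form: ``r2 = q2 * theta / (theta + 1 - q2*h2/Me)``.  The
    approximate form drops the ``q2*h2/Me`` term (negligible single-segment
    variance).  With ``q2 = 1`` both reduce to the classical
    ``N*h2/Me``-based expressions.
    """
    theta = theta_marker(params)
    if theta == 0.0:
        return ReliabilityResult(0.0, "eq2c" if approximate else "eq2a", "segment_only")
    if approximate:
        r2 = params.q2 * theta / (theta + 1.0)
        route = "eq2c"
    else:
        r2 = params.q2 * theta / (theta + 1.0 - params.segment_variance)
        route = "eq2a"
    return ReliabilityResult(r2, route, "segment_only")


def residual_variance_joint(params: PopulationParams, r2: float) -> ResidualVariance:
    """Residual variance when all segments are fitted simultaneously.

    Exact: ``1 - q2*h2/Me - (Me - 1)*r2*h2/Me``, i.e. the phenotypic
    variance minus the focal segment's true variance minus the variance
    explained by the estimated effects of the other ``Me - 1`` segments.
    Approximation (``h2*(q2 - r2)/Me << 1``): ``1 - r2*h2``.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must be in [0, 1], got {r2}")
    h2, q2, me = params.heritability, params.q2, params.m_effective
    exact = 1.0 - q2 * h2 / me - (me - 1) * r2 * h2 / me
    return ResidualVariance(exact=exact, approx=1.0 - r2 * h2)


def _joint_fit_roots(theta: float, heritability: float, q2: float) -> tuple[float, float]:
    """Both roots of the joint-fit quadratic ``h2*r2**2 - (1+theta)*r2 + q2*theta = 0``."""
    disc = (1.0 + theta) ** 2 - 4.0 * heritability * q2 * theta
    if disc < 0.0:  # impossible for theta >= 0, h2, q2 in [0, 1]
        raise ArithmeticError(f"negative discriminant {disc} for theta={theta}")
    sq = math.sqrt(disc)
    # conjugate form of the minus root avoids cancellation for small h2*q2
    lo = 2.0 * q2 * theta / (1.0 + theta + sq)
    hi = (1.0 + theta + sq) / (2.0 * heritability)
    return lo, hi


def reliability_joint_fit(
    theta: float,
    heritability: float,
    q2: float = 1.0,
    method: str = "closed_form",
) -> ReliabilityResult:
    """Reliability accounting for the joint fit of all segments.

    Solves the self-consistent relation
    ``r2 = q2 * theta / (theta + 1 - r2*h2)``.  The quadratic has two
    roots; the larger one exceeds 1 and is discarded.

    ``method='closed_form'`` evaluates the minus-sign root directly;
    ``method='fixed_point'`` iterates the relation from ``r2 = 0``.
    ``theta`` may be supplied directly or computed with :func:`theta_marker`.
    """
    if theta < 0.0:
        raise ValueError(f"theta must be non-negative, got {theta}")
    if not 0.0 <= heritability <= 1.0:
        raise ValueError(f"heritability must be in [0, 1], got {heritability}")
    if not 0.0 <= q2 <= 1.0:
        raise ValueError(f"q2 must be in [0, 1], got {q2}")
    if theta == 0.0 or q2 == 0.0:
        return ReliabilityResult(0.0, "eq3b", "joint_fit")
    if heritability == 0.0:
        # limit of the quadratic as h2 -> 0: the residual term vanishes
        return ReliabilityResult(q2 * theta / (theta + 1.0), "eq3b", "joint_fit")

    if method == "closed_form":
        r2, _ = _joint_fit_roots(theta, heritability, q2)
        route = "eq3b"
    elif method == "fixed_point":
        r2 = 0.0
        for _ in range(_FP_MAX_ITER):
            nxt = q2 * theta / (theta + 1.0 - r2 * heritability)
            if abs(nxt - r2) <= _FP_TOL * max(1.0, abs(nxt)):
                r2 = nxt
                break
            r2 = nxt
        else:
            raise ArithmeticError("fixed-point iteration did not converge")
        route = "eq3a_fixed_point"
    else:
        raise ValueError(f"unknown method {method!r}")
    return ReliabilityResult(min(r2, 1.0), route, "joint_fit")


def reliability_dekkers_variant(theta: float, heritability: float, q2: float) -> ReliabilityResult:
    """Earlier published closed form for the joint-fit reliability.

    ``r2 = [1 + theta - sqrt((1+theta)^2 - 4*h2*q2^2*theta)] / (2*q2*h2)``.
    It arises from scaling the residual reduction by ``r2*q2*h2`` rather
    than ``r2*h2`` and coincides with :func:`reliability_joint_fit` at
    ``q2 = 1``.
    """
    if q2 <= 0.0:
        raise ValueError("the variant form divides by q2; q2 must be positive")
    if theta < 0.0:
        raise ValueError(f"theta must be non-negative, got {theta}")
    if theta == 0.0:
        return ReliabilityResult(0.0, "dekkers_variant", "joint_fit")
    if heritability == 0.0:
        return ReliabilityResult(q2 * theta / (theta + 1.0), "dekkers_variant", "joint_fit")
    disc = (1.0 + theta) ** 2 - 4.0 * heritability * q2 ** 2 * theta
    # conjugate form of [1 + theta - sqrt(disc)] / (2*q2*h2)
    r2 = 2.0 * q2 * theta / (1.0 + theta + math.sqrt(disc))
    return ReliabilityResult(r2, "dekkers_variant", "joint_fit")
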