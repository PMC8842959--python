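"""Fisher-information (FI) algebra for combining reliabilities.

A reliability and an information amount are interchangeable descriptions of
the same evidence, via ``r2 = theta / (theta + 1 - r2_ref * h2)`` where the
residual-reference reliability ``r2_ref`` is either frozen at a pre-merge
value or solved self-consistently.  Crucially, an information amount is tied
to a genetic component: the part captured by markers (``marker_captured``)
or the full additive effect (``full_genetic``).  Information amounts may be
summed only when their sampling errors are independent AND they refer to
the same component; mixing components is the classical mistake this module
refuses to make.

The closed-form merge formulas of selection-index theory (SIT) are provided
alongside, and the test suite asserts route-by-route equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .predict_core import PopulationParams, ReliabilityResult, reliability_joint_fit

__all__ = [
    "InfoSource",
    "MARKER_CAPTURED",
    "FULL_GENETIC",
    "r2_from_theta",
    "r2_from_theta_selfconsistent",
    "theta_from_r2_marker",
    "theta_from_r2_marker_selfconsistent",
    "theta_from_r2_full",
    "sum_information",
    "merge_subpops_sit",
    "merge_pedigree_genomic_sit",
    "merge_subpops_fi",
]

MARKER_CAPTURED = "marker_captured"
FULL_GENETIC = "full_genetic"
_TARGETS = (MARKER_CAPTURED, FULL_GENETIC)


@dataclass(frozen=True)
class InfoSource:
    """A Fisher-information amount tagged with the component it targets."""

    theta: float
    target: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.theta < 0.0:
            raise ValueError(f"theta must be non-negative, got {self.theta}")
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}, got {self.target!r}")


def r2_from_theta(theta: float, heritability: float, r2_residual_ref: float) -> float:
    """Reliability from information with an explicit residual reference.

    ``r2 = theta / (theta + 1 - r2_residual_ref * h2)``.  Passing the
    output's own value back in corresponds to the self-consistent solution
    (see :func:`r2_from_theta_selfconsistent`); passing a frozen pre-merge
    reliability reproduces the route that ignores the additional
    residual-variance reduction from merging.
    """
    if theta < 0.0:
        raise ValueError(f"theta must be non-negative, got {theta}")
    if not 0.0 <= r2_residual_ref <= 1.0:
        raise ValueError(f"r2_residual_ref must be in [0, 1], got {r2_residual_ref}")
    denom = theta + 1.0 - r2_residual_ref * heritability
    if denom <= 0.0:
        raise ValueError(f"non-positive denominator {denom}")
    return theta / denom


def r2_from_theta_selfconsistent(theta: float, heritability: float) -> float:
    """Self-consistent reliability from full-genetic information.

    Solves ``r2 = theta / (theta + 1 - r2*h2)`` for ``r2``:
    ``r2 = [1 + theta - sqrt((1+theta)^2 - 4*h2*theta)] / (2*h2)``,
    with the ``h2 = 0`` limit ``theta/(theta + 1)``.
    """
    return reliability_joint_fit(theta, heritability, q2=1.0).r2


def theta_from_r2_marker(r2: float, params: PopulationParams) -> InfoSource:
    """Marker-component information implied by a single-population reliability.

    Inverts ``r2 = q2 * theta / (theta + 1 - q2*h2/Me)`` (frozen,
    segment-only residual):
    ``theta = r2 * (1 - q2*h2/Me) / (q2 - r2)``.
    A marker-based reliability can never reach ``q2``.
    """
    if not 0.0 <= r2 < params.q2:
        raise ValueError(
            f"marker-based reliability must satisfy 0 <= r2 < q2={params.q2}, got {r2}"
        )
    theta = r2 * (1.0 - params.segment_variance) / (params.q2 - r2)
    return InfoSource(theta, MARKER_CAPTURED)


def theta_from_r2_marker_selfconsistent(r2: float, params: PopulationParams) -> InfoSource:
    """Marker-component information implied by a joint-fit reliability.

    Inverts the self-consistent relation
    ``r2 = q2 * theta / (theta + 1 - r2*h2)``:
    ``theta = r2 * (1 - r2*h2) / (q2 - r2)``.
    Use this inversion when the input reliabilities came from the joint-fit
    closed form, so that the design information (``N*q2*h2/Me``) is
    recovered exactly.
    """
    if not 0.0 <= r2 < params.q2:
        raise ValueError(
            f"marker-based reliability must satisfy 0 <= r2 < q2={params.q2}, got {r2}"
        )
    theta = r2 * (1.0 - r2 * params.heritability) / (params.q2 - r2)
    return InfoSource(theta, MARKER_CAPTURED)


def theta_from_r2_full(r2: float, heritability: float) -> InfoSource:
    """Full-genetic information implied by a reliability of any source.

    Inverts the self-consistent relation for the full genetic effect:
    ``theta = r2 * (1 - r2*h2) / (1 - r2)``.  Not limited to marker
    information — any unbiased predictor of the full genetic effect with
    independent sampling error qualifies (e.g. a pedigree EBV).
    """
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    theta = r2 * (1.0 - r2 * heritability) / (1.0 - r2)
    return InfoSource(theta, FULL_GENETIC)


def sum_information(sources: Iterable[InfoSource]) -> InfoSource:
    """Sum information amounts from sources with independent sampling errors.

    Refuses to sum sources targeting different genetic components: an
    information amount about the marker-captured part cannot be added to
    one about the full genetic effect.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("no information sources to sum")
    targets = {s.target for s in sources}
    if len(targets) > 1:
        labels = ", ".join(f"{s.label or 'unnamed'}->{s.target}" for s in sources)
        raise ValueError(
            f"cannot sum information targeting different genetic components: {labels}"
        )
    return InfoSource(
        sum(s.theta for s in sources),
        sources[0].target,
        "+".join(s.label for s in sources if s.label),
    )


def merge_subpops_sit(r1_sq: float, r2_sq: float, q2: float) -> float:
    """SIT closed form for merging two subpopulation GEBV reliabilities.

    ``r2 = (r1 + r2 - 2*r1*r2/q2) / (1 - r1*r2/q2^2)`` with the arguments
    already squared.  Both GEBV predict the same marker-captured component
    with independent sampling errors; reduces to
    :func:`merge_pedigree_genomic_sit` at ``q2 = 1``.
    """
    if not 0.0 < q2 <= 1.0:
        raise ValueError(f"q2 must be in (0, 1], got {q2}")
    for name, val in (("r1_sq", r1_sq), ("r2_sq", r2_sq)):
        if not 0.0 <= val <= q2:
            raise ValueError(f"{name} must be in [0, q2={q2}], got {val}")
    denom = 1.0 - r1_sq * r2_sq / q2 ** 2
    if denom <= 0.0:
        raise ValueError(f"degenerate denominator: r1_sq*r2_sq = q2^2 ({denom})")
    return (r1_sq + r2_sq - 2.0 * r1_sq * r2_sq / q2) / denom


def merge_pedigree_genomic_sit(rA_sq: float, rD_sq: float) -> float:
    """SIT closed form for merging pedigree and genomic-deviation EBV.

    ``rG2 = (rA2 + rD2 - 2*rA2*rD2) / (1 - rA2*rD2)``; both sources are
    unbiased predictors of the full genetic effect with independent
    sampling errors.  Ignores any residual-variance reduction from the
    merger.
    """
    for name, val in (("rA_sq", rA_sq), ("rD_sq", rD_sq)):
        if not 0.0 <= val < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {val}")
    denom = 1.0 - rA_sq * rD_sq
    return (rA_sq + rD_sq - 2.0 * rA_sq * rD_sq) / denom


def merge_subpops_fi(
    r_sq_list: Sequence[float],
    params: PopulationParams,
    account_residual_reduction: bool = False,
) -> ReliabilityResult:
    """Merge subpopulation reliabilities through the FI route.

    Each reliability is translated to marker-component information, the
    amounts are summed, and the sum is translated back:

    * ``account_residual_reduction=False`` — inversion and back-conversion
      both use the frozen segment-only residual, which is algebraically
      identical to the SIT closed form :func:`merge_subpops_sit`;
    * ``account_residual_reduction=True`` — inversion uses the
      self-consistent (joint-fit) relation and the summed information goes
      through the joint-fit closed form, capturing the full residual
      reduction from enlarging the reference population.
    """
    if len(r_sq_list) == 0:
        raise ValueError("need at least one subpopulation reliability")
    q2, h2 = params.q2, params.heritability
    if account_residual_reduction:
        sources = [theta_from_r2_marker_selfconsistent(r, params) for r in r_sq_list]
        theta = sum_information(sources).theta
        res = reliability_joint_fit(theta, h2, q2)
        return ReliabilityResult(res.r2, "fi_joint_fit", "joint_fit")
    sources = [theta_from_r2_marker(r, params) for r in r_sq_list]
    theta = sum_information(sources).theta
    r2 = q2 * theta / (theta + 1.0 - params.segment_variance)
    return ReliabilityResult(r2, "fi_frozen", "fixed_reference_r2")
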