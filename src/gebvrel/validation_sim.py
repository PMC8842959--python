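"""Monte-Carlo validation of the deterministic reliability predictions.

Simulates the effective-chromosome-segments model: segments are
independent, have equal variance, and jointly explain the marker-captured
share ``q2*h2`` of a unit phenotypic variance; a residual polygenic part
carries the remaining ``(1-q2)*h2``.  Segment effects are fitted by
ridge/BLUP on a reference population and the realized reliability is the
squared out-of-sample correlation between GEBV and the true total genetic
value in a fresh validation set.

Random-stream discipline: one root seed; replicate ``k`` uses the
substream ``(seed, k)``, so its data are invariant to the total number of
replicates requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .predict_core import PopulationParams, reliability_joint_fit, theta_marker

__all__ = [
    "SimConfig",
    "SimReplicate",
    "EmpiricalReliability",
    "simulate_replicate",
    "fit_segment_blup",
    "empirical_reliability",
    "simulate_two_predictor_merge",
]


@dataclass(frozen=True)
class SimConfig:
    params: PopulationParams
    n_validation: int = 2000
    n_replicates: int = 30
    seed: int = 0
    shrinkage: float | None = None  # override of the ridge parameter

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.n_validation < 1:
            raise ValueError(f"n_validation must be >= 1, got {self.n_validation}")
        if self.n_validation < 100:
            warnings.warn(
                f"n_validation={self.n_validation} < 100 gives unstable correlation "
                "estimates",
                stacklevel=2,
            )


@dataclass
class SimReplicate:
    """One simulated reference + validation dataset.

    ``scores_ref``/``scores_val`` are standardized segment genotype
    matrices; ``g_m`` is the marker-captured genetic value, ``g_total``
    includes the non-captured residual part; ``phenotypes`` exist for the
    reference individuals only (validation is unphenotyped).
    """

    scores_ref: np.ndarray
    scores_val: np.ndarray
    true_effects: np.ndarray
    g_m_ref: np.ndarray
    g_m_val: np.ndarray
    g_total_ref: np.ndarray
    g_total_val: np.ndarray
    phenotypes: np.ndarray
    gebv_val: np.ndarray | None = field(default=None)


class EmpiricalReliability(NamedTuple):
    mean_r2: float
    mc_se: float
    per_replicate: np.ndarray
    predicted_r2: float


def _standardize(scores: np.ndarray) -> np.ndarray:
    """Center and scale each segment column to mean 0, variance 1."""
    mu = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0
    return (scores - mu) / sd


def simulate_replicate(config: SimConfig, replicate_index: int = 0) -> SimReplicate:
    """Draw one reference + validation dataset under the segments model.

    Segment scores are iid standard normal, standardized per column; true
    segment effects have variance ``q2*h2/Me`` each; the non-captured
    genetic residual has variance ``(1-q2)*h2``; environmental noise has
    variance ``1 - h2``.  Deterministic given ``(config.seed,
    replicate_index)``.
    """
    p = config.params
    rng = np.random.default_rng([config.seed, replicate_index])
    n_ref, n_val, me = p.n_reference, config.n_validation, p.m_effective

    scores = _standardize(rng.standard_normal((n_ref + n_val, me)))
    effects = rng.normal(0.0, np.sqrt(p.segment_variance), size=me)
    g_m = scores @ effects
    g_res = rng.normal(0.0, np.sqrt((1.0 - p.q2) * p.heritability), size=n_ref + n_val)
    g_total = g_m + g_res
    noise = rng.normal(0.0, np.sqrt(1.0 - p.heritability), size=n_ref)
    phenotypes = g_total[:n_ref] + noise

    return SimReplicate(
        scores_ref=scores[:n_ref],
        scores_val=scores[n_ref:],
        true_effects=effects,
        g_m_ref=g_m[:n_ref],
        g_m_val=g_m[n_ref:],
        g_total_ref=g_total[:n_ref],
        g_total_val=g_total[n_ref:],
        phenotypes=phenotypes,
    )


def default_shrinkage(params: PopulationParams) -> float:
    """Ridge parameter from the model's own variances.

    Residual variance of the marker model is ``1 - q2*h2`` (environmental
    noise plus the non-captured genetic part); the per-segment effect
    variance is ``q2*h2/Me``.
    """
    num = 1.0 - params.q2 * params.heritability
    if params.segment_variance == 0.0:
        return np.inf
    return num / params.segment_variance


def fit_segment_blup(
    replicate: SimReplicate, params: PopulationParams, shrinkage: float | None = None
) -> np.ndarray:
    """Ridge/BLUP fit of all segment effects; returns validation GEBV.

    Solves ``(Z'Z + lambda*I) u = Z'y`` on centered phenotypes, then
    ``GEBV = Z_val @ u``.  The fitted GEBV are also stored on the
    replicate.
    """
    lam = default_shrinkage(params) if shrinkage is None else shrinkage
    if not np.isfinite(lam):
        gebv = np.zeros(replicate.scores_val.shape[0])
        replicate.gebv_val = gebv
        return gebv
    Z = replicate.scores_ref
    y = replicate.phenotypes - replicate.phenotypes.mean()
    me = Z.shape[1]
    lhs = Z.T @ Z + lam * np.eye(me)
    u_hat = np.linalg.solve(lhs, Z.T @ y)
    gebv = replicate.scores_val @ u_hat
    replicate.gebv_val = gebv
    return gebv


def empirical_reliability(config: SimConfig) -> EmpiricalReliability:
    """Mean realized reliability over replicates, with Monte-Carlo SE.

    Reliability per replicate is the squared correlation between
    validation GEBV and the true total genetic value.  Replicates with
    zero-variance GEBV or genetic values are excluded with a warning.
    The deterministic joint-fit prediction at the configuration's own
    information amount is reported alongside.
    """
    p = config.params
    r2s = []
    for k in range(config.n_replicates):
        rep = simulate_replicate(config, k)
        gebv = fit_segment_blup(rep, p, config.shrinkage)
        if gebv.std() == 0.0 or rep.g_total_val.std() == 0.0:
            warnings.warn(f"replicate {k}: zero-variance GEBV, excluded", stacklevel=2)
            continue
        r2s.append(np.corrcoef(gebv, rep.g_total_val)[0, 1] ** 2)
    r2s = np.asarray(r2s)
    if r2s.size == 0:
        return EmpiricalReliability(0.0, 0.0, r2s, 0.0)
    mc_se = float(r2s.std(ddof=1) / np.sqrt(r2s.size)) if r2s.size > 1 else float("nan")
    predicted = reliability_joint_fit(theta_marker(p), p.heritability, p.q2).r2
    return EmpiricalReliability(float(r2s.mean()), mc_se, r2s, predicted)


def simulate_two_predictor_merge(
    r1_sq: float,
    r2_sq: float,
    heritability: float,
    n_individuals: int = 200_000,
    seed: int = 0,
) -> float:
    """Empirical combined reliability of two unbiased predictors.

    Draws true genetic values with variance ``h2`` and two predictors with
    the stated reliabilities and independent errors; returns the squared
    multiple correlation of the genetic value on both predictors
    (in-sample OLS R-squared, which converges to the index reliability).
    """
    for name, val in (("r1_sq", r1_sq), ("r2_sq", r2_sq)):
        if not 0.0 <= val < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {val}")
    rng = np.random.default_rng(seed)
    h2 = heritability
    g = rng.normal(0.0, np.sqrt(h2), size=n_individuals)

    def predictor(r_sq: float) -> np.ndarray:
        if r_sq == 0.0:
            return rng.standard_normal(n_individuals)
        err_var = h2 * (1.0 - r_sq) / r_sq
        return g + rng.normal(0.0, np.sqrt(err_var), size=n_individuals)

    X = np.column_stack([np.ones(n_individuals), predictor(r1_sq), predictor(r2_sq)])
    beta, *_ = np.linalg.lstsq(X, g, rcond=None)
    resid = g - X @ beta
    return float(1.0 - resid.var() / g.var())
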