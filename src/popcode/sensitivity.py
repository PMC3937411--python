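"""Condition-number bounds for the information measures.

The condition number of a measure with respect to a perturbation target is
the ratio of the relative change of the measure to the relative (2-norm) size
of the perturbation.  Locally:

* perturbing the noise covariance:  kappa <= lambda_max / lambda_min of the
  relevant covariance (``C^n`` for Fisher, ``C^n + C_mu`` for OLE, which
  stays bounded even when ``C^n`` itself is singular);
* perturbing the tuning (f' for Fisher, L for OLE):
  kappa <= 2 sqrt(K) lambda_max / lambda_min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import assert_pd, min_max_eig
from .measures import NoiseCov, PopulationStats, info

__all__ = ["SensitivityReport", "condition_bound", "empirical_kappa"]


@dataclass(frozen=True)
class SensitivityReport:
    empirical_kappa: float
    bound: float
    perturb_target: str  # "noise_cov" | "cross_cov"
    perturb_norm: float
    measure: str


def _relevant_cov(stats: PopulationStats, noise: NoiseCov, measure: str) -> np.ndarray:
    if measure == "fisher":
        return noise.cov
    if measure == "ole":
        return noise.cov + stats.mean_resp_cov
    raise ValueError("condition bounds are provided for 'fisher' and 'ole' only")


def condition_bound(
    stats: PopulationStats, noise: NoiseCov, target: str = "noise_cov", measure: str = "fisher"
) -> float:
    """Upper bound on the local condition number for the given target."""
    cov = _relevant_cov(stats, noise, measure)
    assert_pd(cov, "covariance")
    lo, hi = min_max_eig(cov)
    ratio = hi / lo
    if target == "noise_cov":
        return float(ratio)
    if target == "cross_cov":
        tuning = stats.sensitivities if measure == "fisher" else stats.cross_cov
        if np.any(np.linalg.norm(tuning, axis=0) == 0):
            raise ValueError("zero column in the tuning matrix: bound undefined")
        k = stats.stim_dim
        return float(2.0 * np.sqrt(k) * ratio)
    raise ValueError("target must be 'noise_cov' or 'cross_cov'")


def empirical_kappa(
    stats: PopulationStats,
    noise: NoiseCov,
    perturbation: np.ndarray,
    measure: str = "fisher",
    target: str = "noise_cov",
) -> SensitivityReport:
    """Empirical condition ratio for a concrete (small) perturbation.

    ``(|dI| / I) / (||d|| / ||.||)`` with 2-norms; the perturbed matrices
    must remain admissible.
    """
    delta = np.asarray(perturbation, dtype=float)
    base = info(stats, noise, measure)
    if base <= 0:
        raise ValueError("baseline information must be positive")
    if target == "noise_cov":
        ref = noise.cov
        if delta.shape != ref.shape:
            raise ValueError("perturbation shape mismatch")
        delta = 0.5 * (delta + delta.T)
        perturbed = NoiseCov(noise.cov + delta)
        new = info(stats, perturbed, measure)
    elif target == "cross_cov":
        tuning = stats.sensitivities if measure == "fisher" else stats.cross_cov
        ref = tuning
        if delta.shape != ref.shape:
            raise ValueError("perturbation shape mismatch")
        if measure == "fisher":
            new_stats = PopulationStats(
                sensitivities=stats.sensitivities + delta,
                cross_cov=stats.cross_cov,
                mean_resp_cov=stats.mean_resp_cov,
                noise_vars=stats.noise_vars,
                stim_cov=stats.stim_cov,
            )
        else:
            new_stats = PopulationStats(
                sensitivities=stats.sensitivities,
                cross_cov=stats.cross_cov + delta,
                mean_resp_cov=stats.mean_resp_cov,
                noise_vars=stats.noise_vars,
                stim_cov=stats.stim_cov,
            )
        new = info(new_stats, noise, measure)
    else:
        raise ValueError("target must be 'noise_cov' or 'cross_cov'")

    delta_norm = float(np.linalg.norm(delta, 2))
    ref_norm = float(np.linalg.norm(ref, 2))
    rel_pert = delta_norm / ref_norm
    rel_change = abs(new - base) / base
    ratio = 0.0 if delta_norm == 0 else rel_change / rel_pert
    return SensitivityReport(
        empirical_kappa=float(ratio),
        bound=condition_bound(stats, noise, target, measure),
        perturb_target=target,
        perturb_norm=delta_norm,
        measure=measure,
    )
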