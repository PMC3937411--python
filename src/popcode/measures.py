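"""Information measures for a population code and their correlation structure.

Three measures of coding fidelity are computed from the sufficient statistics
of the problem (tuning sensitivities, stimulus/response covariances, noise
variances) and a choice of pairwise noise correlations:

* linear Fisher information ``f'^T (C^n)^{-1} f'`` (local discrimination),
* OLE information ``L^T (C^n + C_mu)^{-1} L`` (global linear decoding; the
  quantity subtracted from the stimulus variance to give the OLE's mean
  squared error),
* Gaussian mutual information for jointly Gaussian stimulus and response.

Also provided: signal correlations and the per-measure sensitivity vectors
they are built from, analytic gradients of each measure with respect to the
off-diagonal noise correlations, the noise-free upper bound on OLE
information, and the Euclidean strength of a correlation pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._linalg import (
    InconsistentJointCovarianceError,
    NotPositiveDefiniteError,
    assert_pd,
    eig_scale,
    matrix_to_pairs,
    min_max_eig,
    n_from_pairs,
    n_pairs,
    pair_indices,
    pairs_to_matrix,
    pd_solve,
)

MEASURES = ("fisher", "ole", "mutual")

__all__ = [
    "MEASURES",
    "PopulationStats",
    "NoiseCov",
    "PairVector",
    "noise_cov_from",
    "independent_noise",
    "linear_fisher",
    "ole_solution",
    "ole_info",
    "ole_mse",
    "mutual_info_gaussian",
    "info",
    "sensitivity_vectors",
    "signal_correlations",
    "info_gradient_at_independent",
    "info_gradient",
    "noise_free_bound",
    "correlation_strength",
    "rescaling_weights",
]


@dataclass(frozen=True)
class PopulationStats:
    """Sufficient statistics of a population-coding problem.

    Parameters
    ----------
    sensitivities : (N, K) array
        Stimulus sensitivity of each neuron's mean response (rows = neurons).
    cross_cov : (N, K) array
        Cross-covariance ``L`` between responses and stimulus.
    mean_resp_cov : (N, N) array
        Covariance ``C_mu`` of the mean (tuned) response over stimuli.
    noise_vars : (N,) array
        Trial-to-trial noise variance of each neuron (fixed diagonal of C^n).
    stim_cov : (K, K) array or scalar
        Stimulus covariance ``C_s``; a scalar is accepted when K = 1.
    """

    sensitivities: np.ndarray
    cross_cov: np.ndarray
    mean_resp_cov: np.ndarray
    noise_vars: np.ndarray
    stim_cov: np.ndarray

    def __post_init__(self):
        f = np.atleast_2d(np.asarray(self.sensitivities, dtype=float))
        if f.shape[0] == 1 and np.asarray(self.noise_vars).size > 1:
            f = f.T
        l = np.atleast_2d(np.asarray(self.cross_cov, dtype=float))
        if l.shape[0] == 1 and np.asarray(self.noise_vars).size > 1:
            l = l.T
        cmu = np.asarray(self.mean_resp_cov, dtype=float)
        nv = np.asarray(self.noise_vars, dtype=float).ravel()
        cs = np.atleast_2d(np.asarray(self.stim_cov, dtype=float))
        object.__setattr__(self, "sensitivities", f)
        object.__setattr__(self, "cross_cov", l)
        object.__setattr__(self, "mean_resp_cov", cmu)
        object.__setattr__(self, "noise_vars", nv)
        object.__setattr__(self, "stim_cov", cs)
        n, k = f.shape
        if l.shape != (n, k):
            raise ValueError(f"cross_cov shape {l.shape} != sensitivities shape {(n, k)}")
        if cmu.shape != (n, n):
            raise ValueError(f"mean_resp_cov must be {n}x{n}, got {cmu.shape}")
        if nv.shape != (n,):
            raise ValueError(f"noise_vars must have length {n}")
        if cs.shape != (k, k):
            raise ValueError(f"stim_cov must be {k}x{k}, got {cs.shape}")
        if np.any(nv <= 0):
            raise ValueError("noise variances must be strictly positive")
        if not np.allclose(cmu, cmu.T, atol=1e-10 * eig_scale(cmu)):
            raise ValueError("mean_resp_cov must be symmetric")
        lo, _ = min_max_eig(cmu)
        if lo < -1e-9 * eig_scale(cmu):
            raise ValueError(f"mean_resp_cov must be PSD (min eigenvalue {lo:.3e})")
        assert_pd(cs, "stim_cov")

    @property
    def n_neurons(self) -> int:
        return self.sensitivities.shape[0]

    @property
    def stim_dim(self) -> int:
        return self.sensitivities.shape[1]

    @property
    def noise_sds(self) -> np.ndarray:
        return np.sqrt(self.noise_vars)


@dataclass(frozen=True)
class NoiseCov:
    """Noise covariance matrix plus its unit-diagonal correlation form."""

    cov: np.ndarray
    corr: np.ndarray = field(init=False)

    def __post_init__(self):
        cov = 0.5 * (np.asarray(self.cov, dtype=float) + np.asarray(self.cov, dtype=float).T)
        d = np.sqrt(np.diag(cov))
        if np.any(d <= 0):
            raise ValueError("noise variances (diagonal of cov) must be positive")
        corr = cov / np.outer(d, d)
        corr[np.diag_indices(cov.shape[0])] = 1.0
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "corr", corr)

    @property
    def n_neurons(self) -> int:
        return self.cov.shape[0]

    @property
    def noise_vars(self) -> np.ndarray:
        return np.diag(self.cov).copy()

    def corr_pairs(self) -> "PairVector":
        return PairVector(matrix_to_pairs(self.corr), label="noise_corr")


PAIR_LABELS = ("noise_corr", "signal_corr", "gradient", "direction")


@dataclass(frozen=True)
class PairVector:
    """A point in the M = N(N-1)/2 space of pairwise quantities.

    Entries follow the lexicographic (i < j) pair order of
    ``numpy.triu_indices``.
    """

    values: np.ndarray
    label: str = "direction"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        n_from_pairs(v.size)  # validates length
        if self.label not in PAIR_LABELS:
            raise ValueError(f"label must be one of {PAIR_LABELS}")
        if self.label == "noise_corr" and np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("noise correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_neurons(self) -> int:
        return n_from_pairs(self.values.size)

    def matrix(self, diag: np.ndarray | float = 1.0) -> np.ndarray:
        return pairs_to_matrix(self.values, diag)

    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


def noise_cov_from(noise_vars: np.ndarray, corr: PairVector | np.ndarray) -> NoiseCov:
    """Noise covariance from variances and pairwise correlations.

    ``C^n_ij = rho_ij * sqrt(var_i * var_j)``.  Positive semidefiniteness is
    deliberately *not* enforced here; admissibility is the spectrahedron
    module's concern.
    """
    nv = np.asarray(noise_vars, dtype=float).ravel()
    vals = corr.values if isinstance(corr, PairVector) else np.asarray(corr, dtype=float).ravel()
    if n_from_pairs(vals.size) != nv.size:
        raise ValueError("correlation vector length inconsistent with noise_vars")
    if np.any(np.abs(vals) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(nv <= 0):
        raise ValueError("noise variances must be strictly positive")
    sd = np.sqrt(nv)
    cov = pairs_to_matrix(vals, 1.0) * np.outer(sd, sd)
    return NoiseCov(cov)


def independent_noise(noise_vars: np.ndarray) -> NoiseCov:
    nv = np.asarray(noise_vars, dtype=float).ravel()
    return NoiseCov(np.diag(nv))


# ---------------------------------------------------------------------------
# information measures
# ---------------------------------------------------------------------------

def linear_fisher(stats: PopulationStats, noise: NoiseCov) -> tuple[np.ndarray, float]:
    """Linear Fisher information ``f'^T (C^n)^{-1} f'``.

    Returns the K x K information matrix and its trace.  ``C^n`` must be
    positive definite; a singular matrix raises NotPositiveDefiniteError.
    """
    f = stats.sensitivities
    x = pd_solve(noise.cov, f, "noise covariance")
    mat = f.T @ x
    mat = 0.5 * (mat + mat.T)
    return mat, float(np.trace(mat))


def ole_solution(stats: PopulationStats, noise: NoiseCov | None) -> np.ndarray:
    """Optimal-linear-estimator readout ``A = (C^n + C_mu)^{-1} L``.

    ``noise=None`` (or a zero covariance) yields the noise-free readout
    ``(C_mu)^{-1} L``.
    """
    total = stats.mean_resp_cov if noise is None else noise.cov + stats.mean_resp_cov
    return pd_solve(total, stats.cross_cov, "total covariance")


def ole_info(stats: PopulationStats, noise: NoiseCov | None) -> tuple[np.ndarray, float]:
    """OLE information ``L^T (C^n + C_mu)^{-1} L`` (K x K matrix and trace)."""
    a = ole_solution(stats, noise)
    mat = stats.cross_cov.T @ a
    mat = 0.5 * (mat + mat.T)
    return mat, float(np.trace(mat))


def ole_mse(stats: PopulationStats, noise: NoiseCov | None) -> float:
    """Mean squared error of the OLE: ``trace(C_s) - trace(ole_info)``."""
    _, scalar = ole_info(stats, noise)
    return max(float(np.trace(stats.stim_cov)) - scalar, 0.0)


def _joint_consistency_gap(stats: PopulationStats, noise: NoiseCov) -> np.ndarray:
    """Schur complement C^n + C_mu - L (C_s)^{-1} L^T of the joint covariance."""
    total = noise.cov + stats.mean_resp_cov
    ls = pd_solve(stats.stim_cov, stats.cross_cov.T, "stim_cov")
    return total - stats.cross_cov @ ls


def mutual_info_gaussian(stats: PopulationStats, noise: NoiseCov) -> float:
    """Mutual information (nats) for jointly Gaussian stimulus and response.

    ``I = (1/2) [ln det C_s - ln det(C_s - L^T (C^n + C_mu)^{-1} L)]``.
    Raises InconsistentJointCovarianceError when the implied joint covariance
    is not PSD; returns ``+inf`` (with a warning) at the singular boundary.
    """
    gap = _joint_consistency_gap(stats, noise)
    lo, _ = min_max_eig(gap)
    scale = eig_scale(noise.cov + stats.mean_resp_cov)
    if lo < -1e-8 * scale:
        raise InconsistentJointCovarianceError(
            f"inconsistent joint covariance (Schur complement eigenvalue {lo:.3e})"
        )
    total = noise.cov + stats.mean_resp_cov
    assert_pd(total, "total covariance")
    resid = stats.stim_cov - stats.cross_cov.T @ np.linalg.solve(total, stats.cross_cov)
    resid = 0.5 * (resid + resid.T)
    lo_r, _ = min_max_eig(resid)
    if lo_r <= 1e-300 or lo_r < 1e-15 * eig_scale(stats.stim_cov):
        warnings.warn("mutual information diverges: residual stimulus covariance is singular")
        return float("inf")
    sign_s, logdet_s = np.linalg.slogdet(stats.stim_cov)
    sign_r, logdet_r = np.linalg.slogdet(resid)
    if sign_s <= 0 or sign_r <= 0:
        raise InconsistentJointCovarianceError("non-positive determinant in mutual information")
    return max(0.5 * (logdet_s - logdet_r), 0.0)


def info(stats: PopulationStats, noise: NoiseCov, measure: str) -> float:
    """Scalar value of the requested measure (trace for matrix-valued ones)."""
    if measure == "fisher":
        return linear_fisher(stats, noise)[1]
    if measure == "ole":
        return ole_info(stats, noise)[1]
    if measure == "mutual":
        return mutual_info_gaussian(stats, noise)
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def noise_free_bound(stats: PopulationStats) -> float:
    """Upper bound ``trace(L^T (C_mu)^{-1} L)`` on OLE information.

    Attained exactly when the noise covariance annihilates the noise-free
    readout; see the cancel module.
    """
    assert_pd(stats.mean_resp_cov, "mean_resp_cov")
    a = np.linalg.solve(stats.mean_resp_cov, stats.cross_cov)
    return float(np.trace(stats.cross_cov.T @ a))


# ---------------------------------------------------------------------------
# signal correlations, gradients, rescaling weights
# ---------------------------------------------------------------------------

def sensitivity_vectors(stats: PopulationStats, measure: str) -> np.ndarray:
    """Per-neuron tuning sensitivity vectors entering the signal correlations.

    fisher : rows of f'
    ole    : rows of (D + C_mu)^{-1} L                  (D = diag noise vars)
    mutual : rows of (D + C_mu)^{-1} L M^{-1/2}, with
             M = C_s - L^T (D + C_mu)^{-1} L.
    """
    if measure == "fisher":
        return stats.sensitivities.copy()
    d = np.diag(stats.noise_vars)
    total = d + stats.mean_resp_cov
    a0 = pd_solve(total, stats.cross_cov, "total covariance at independence")
    if measure == "ole":
        return a0
    if measure == "mutual":
        m = stats.stim_cov - stats.cross_cov.T @ a0
        m = 0.5 * (m + m.T)
        assert_pd(m, "residual stimulus covariance")
        w, v = np.linalg.eigh(m)
        m_inv_sqrt = (v / np.sqrt(w)) @ v.T
        return a0 @ m_inv_sqrt
    raise ValueError(f"unknown measure {measure!r}")


def signal_correlations(stats: PopulationStats, measure: str = "fisher") -> PairVector:
    """Pairwise signal correlations: cosines between sensitivity vectors.

    For the Fisher measure with a scalar stimulus this reduces to
    ``sign(f'_i f'_j)``.  Pairs involving a zero-norm sensitivity vector are
    undefined and returned as NaN with a warning (never silently zero).
    """
    vecs = sensitivity_vectors(stats, measure)
    norms = np.linalg.norm(vecs, axis=1)
    iu, ju = pair_indices(stats.n_neurons)
    dots = (vecs @ vecs.T)[iu, ju]
    denom = norms[iu] * norms[ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        xi = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), np.nan)
    if np.any(denom == 0):
        warnings.warn("zero-norm sensitivity vector: signal correlation undefined for some pairs")
    xi = np.clip(xi, -1.0, 1.0)
    return PairVector(xi, label="signal_corr")


def info_gradient(stats: PopulationStats, noise: NoiseCov, measure: str) -> PairVector:
    """Analytic gradient of the measure w.r.t. the pairwise noise correlations.

    Derivative of the scalar measure with respect to each ``rho_ij`` at the
    supplied noise covariance (chain rule through ``C^n_ij = rho_ij s_i s_j``):

    fisher : -2 s_i s_j (W W^T)_ij,        W = (C^n)^{-1} f'
    ole    : -2 s_i s_j (W W^T)_ij,        W = (C^n + C_mu)^{-1} L
    mutual : -  s_i s_j (W M^{-1} W^T)_ij, M = C_s - L^T (C^n + C_mu)^{-1} L
    """
    sd = np.sqrt(noise.noise_vars)
    iu, ju = pair_indices(stats.n_neurons)
    if measure == "fisher":
        w = pd_solve(noise.cov, stats.sensitivities, "noise covariance")
        outer = -2.0 * (w @ w.T)
    elif measure == "ole":
        w = pd_solve(noise.cov + stats.mean_resp_cov, stats.cross_cov, "total covariance")
        outer = -2.0 * (w @ w.T)
    elif measure == "mutual":
        total = noise.cov + stats.mean_resp_cov
        w = pd_solve(total, stats.cross_cov, "total covariance")
        m = stats.stim_cov - stats.cross_cov.T @ w
        m = 0.5 * (m + m.T)
        assert_pd(m, "residual stimulus covariance")
        outer = -1.0 * (w @ np.linalg.solve(m, w.T))
    else:
        raise ValueError(f"unknown measure {measure!r}")
    grad = outer[iu, ju] * sd[iu] * sd[ju]
    return PairVector(grad, label="gradient")


def info_gradient_at_independent(stats: PopulationStats, measure: str) -> PairVector:
    """Gradient at the independent-noise point ``C^n = diag(noise_vars)``.

    Each entry has sign opposite to the corresponding signal correlation:
    moving opposite to signal correlations is the steepest uphill direction.
    """
    return info_gradient(stats, independent_noise(stats.noise_vars), measure)


def correlation_strength(corr: PairVector | np.ndarray) -> float:
    """Euclidean norm of the pair vector: the strength of correlations."""
    vals = corr.values if isinstance(corr, PairVector) else np.asarray(corr, dtype=float)
    return float(np.linalg.norm(vals))


def rescaling_weights(stats: PopulationStats, measure: str) -> np.ndarray:
    """Positive weights ``w`` with ``w * xi = gradient`` entrywise.

    Multiplying each signal correlation by its weight recovers the gradient at
    independence, revealing the linear signal/noise-correlation alignment in
    the weak-correlation regime.  Pairs with ``xi = 0`` but nonzero gradient
    have no defined weight and are returned as NaN with a warning.
    """
    xi = signal_correlations(stats, measure).values
    grad = info_gradient_at_independent(stats, measure).values
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(xi != 0, -grad / np.where(xi != 0, xi, 1.0), np.nan)
    undefined = (xi == 0) & (np.abs(grad) > 1e-12)
    if np.any(undefined):
        warnings.warn("zero signal correlation with nonzero gradient: weight undefined")
    w = np.where((xi == 0) & ~undefined, np.nan, w)
    return w
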