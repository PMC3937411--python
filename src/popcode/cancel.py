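"""Noise-canceling correlation structures.

A noise covariance attains the noise-free OLE bound exactly when it
annihilates the noise-free readout: ``C^n A = 0`` with ``A = (C_mu)^{-1} L``.
Whether any admissible correlation matrix does so depends only on the
nonnegative quantities ``q_i = sigma_i |A_i|`` (scalar stimulus): canceling
correlations exist iff ``2 max(q) <= sum(q)`` — the closed-polygon condition.

The constructive route builds N vectors of prescribed lengths q_i that sum to
zero (a closing polygon); the Gram matrix of their unit directions, with signs
restored from the readout, is a canceling correlation matrix.  The set of all
canceling correlations is convex, flat, and generically high-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from ._linalg import (
    InfeasibleError,
    assert_pd,
    eig_scale,
    matrix_to_pairs,
    min_max_eig,
    n_pairs,
    nearest_correlation,
    pair_indices,
    pairs_to_matrix,
)
from .measures import (
    NoiseCov,
    PairVector,
    PopulationStats,
    noise_free_bound,
    ole_info,
    ole_solution,
)

__all__ = [
    "QVector",
    "CancelSolution",
    "FlatObjectiveError",
    "q_values",
    "feasibility",
    "closing_polygon",
    "construct_canceling",
    "canceling_set_dimension",
    "canceling_basis",
    "find_canceling_numeric",
    "feasibility_probability",
]

CANCEL_RTOL = 1e-8


class FlatObjectiveError(ValueError):
    """The readout is identically zero (L = 0): trivially flat objective."""


@dataclass(frozen=True)
class QVector:
    """Per-neuron cancellation weights ``q_i = sigma_i |A_i|`` and signs."""

    q: np.ndarray
    signs: np.ndarray
    n_zero: int


def q_values(stats: PopulationStats) -> QVector:
    """Cancellation weights from the noise-free readout (scalar stimulus)."""
    if stats.stim_dim != 1:
        raise ValueError("q_values requires a scalar stimulus (K = 1)")
    assert_pd(stats.mean_resp_cov, "mean_resp_cov")
    a = ole_solution(stats, None).ravel()
    scale = max(np.max(np.abs(a)), 1e-300)
    a_clean = np.where(np.abs(a) < 1e-12 * scale, 0.0, a)
    q = stats.noise_sds * np.abs(a_clean)
    signs = np.sign(a_clean).astype(int)
    return QVector(q=q, signs=signs, n_zero=int(np.sum(q == 0)))


def feasibility(q: QVector | np.ndarray, rtol: float = 1e-9) -> str:
    """Polygon test: 'strict' if 2 max(q) < sum(q), 'equality', or 'infeasible'."""
    qv = q.q if isinstance(q, QVector) else np.asarray(q, dtype=float).ravel()
    if np.any(qv < 0):
        raise ValueError("q values must be nonnegative")
    total = float(np.sum(qv))
    if total == 0.0:
        raise FlatObjectiveError("all q are zero: trivially flat objective (L = 0)")
    top = 2.0 * float(np.max(qv))
    if top < total * (1.0 - rtol):
        return "strict"
    if top <= total * (1.0 + rtol):
        return "equality"
    return "infeasible"


def closing_polygon(q: np.ndarray) -> list[np.ndarray]:
    """N vectors in R^{N-1} with prescribed norms q_i summing to zero.

    Requires all q_i > 0, N >= 3, and the strict polygon inequality.  The
    construction is the inductive one: peel off the two largest lengths into a
    triangle whose third side closes the remaining polygon.  Free choices are
    fixed deterministically (sort descending, midpoint of the feasible
    interval for the recursion scalar, fresh coordinate axes).
    """
    q = np.asarray(q, dtype=float).ravel()
    n = q.size
    if n < 3:
        raise ValueError("need at least 3 lengths")
    if np.any(q <= 0):
        raise ValueError("all lengths must be positive")
    if feasibility(q) != "strict":
        raise ValueError("strict polygon inequality 2*max(q) < sum(q) required")
    order = np.argsort(-q, kind="stable")
    sorted_vecs = _polygon_sorted(q[order])
    out: list[np.ndarray] = [np.empty(0)] * n
    for pos, idx in enumerate(order):
        v = np.zeros(n - 1)
        v[: sorted_vecs[pos].size] = sorted_vecs[pos]
        out[idx] = v
    return out


def _triangle(a: float, b: float, c: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planar vectors of norms a, b, c with v1 + v2 + v3 = 0."""
    cos_t = (c * c - a * a - b * b) / (2.0 * a * b)
    cos_t = float(np.clip(cos_t, -1.0, 1.0))
    sin_t = float(np.sqrt(max(1.0 - cos_t * cos_t, 0.0)))
    v1 = np.array([a, 0.0])
    v2 = np.array([b * cos_t, b * sin_t])
    v3 = -(v1 + v2)
    return v1, v2, v3


def _split_edge(w: np.ndarray, a: float, b: float, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split w into v1 + v2 with norms a, b, using a fresh orthogonal axis."""
    t = float(np.linalg.norm(w))
    u = w / t
    cos_a = (a * a + t * t - b * b) / (2.0 * a * t)
    cos_a = float(np.clip(cos_a, -1.0, 1.0))
    sin_a = float(np.sqrt(max(1.0 - cos_a * cos_a, 0.0)))
    v1 = a * (cos_a * u + sin_a * axis)
    v2 = w - v1
    return v1, v2


def _polygon_sorted(q: np.ndarray) -> list[np.ndarray]:
    """Closing polygon for q sorted descending; vectors of growing dimension."""
    n = q.size
    if n == 3:
        v1, v2, v3 = _triangle(q[0], q[1], q[2])
        return [v1, v2, v3]
    rest = q[2:]
    rest_sum = float(np.sum(rest))
    rest_max = float(np.max(rest))
    lo = max(q[0] - q[1], 2.0 * rest_max - rest_sum, 0.0)
    hi = min(q[0] + q[1], rest_sum)
    if lo > hi + 1e-12:
        raise ValueError("polygon inequality violated during recursion")
    t = 0.5 * (lo + hi)
    if t <= 0:
        raise ValueError("degenerate recursion scalar")
    sub = np.concatenate(([t], rest))
    sub_order = np.argsort(-sub, kind="stable")
    sub_vecs_sorted = _polygon_sorted(sub[sub_order])
    sub_vecs = [np.empty(0)] * sub.size
    for pos, idx in enumerate(sub_order):
        sub_vecs[idx] = sub_vecs_sorted[pos]
    dim = max(v.size for v in sub_vecs) + 1
    padded = []
    for v in sub_vecs:
        p = np.zeros(dim)
        p[: v.size] = v
        padded.append(p)
    w_t = padded[0]
    axis = np.zeros(dim)
    axis[dim - 1] = 1.0
    v1, v2 = _split_edge(w_t, q[0], q[1], axis)
    return [v1, v2] + padded[1:]


@dataclass(frozen=True)
class CancelSolution:
    corr: np.ndarray
    dimension: int
    basis: list
    case: str  # "strict" | "equality"
    q: QVector

    def pair_vector(self) -> PairVector:
        return PairVector(matrix_to_pairs(self.corr), label="noise_corr")

    def noise_cov(self, noise_vars: np.ndarray) -> NoiseCov:
        sd = np.sqrt(np.asarray(noise_vars, dtype=float))
        return NoiseCov(self.corr * np.outer(sd, sd))


def _constraint_system(stats: PopulationStats) -> tuple[np.ndarray, np.ndarray]:
    """Linear system T x = r on off-diagonal correlations for C^n A = 0.

    Unknowns are rho_ij (lexicographic pairs); equation (i, k):
    sum_j rho_ij sigma_i sigma_j A_jk = -sigma_i^2 A_ik.
    """
    a = ole_solution(stats, None)
    sd = stats.noise_sds
    n, k = a.shape
    m = n_pairs(n)
    iu, ju = pair_indices(n)
    t = np.zeros((n * k, m))
    r = np.zeros(n * k)
    for row_i in range(n):
        for col_k in range(k):
            row = row_i * k + col_k
            r[row] = -sd[row_i] ** 2 * a[row_i, col_k]
            for p, (i, j) in enumerate(zip(iu, ju)):
                if i == row_i:
                    t[row, p] = sd[i] * sd[j] * a[j, col_k]
                elif j == row_i:
                    t[row, p] = sd[i] * sd[j] * a[i, col_k]
    return t, r


def construct_canceling(stats: PopulationStats) -> CancelSolution:
    """A noise-canceling correlation matrix via the closing-polygon route.

    Strict case: Gram matrix of the polygon's unit directions (sign-restored),
    extended by an identity block for zero-q neurons.  Equality case: the
    unique collinear solution on the nonzero block.  Raises InfeasibleError
    when the polygon condition fails.
    """
    qv = q_values(stats)
    case = feasibility(qv)
    if case == "infeasible":
        raise InfeasibleError(
            "no noise-canceling correlations exist: 2*max(q) > sum(q)"
        )
    n = stats.n_neurons
    nz = np.flatnonzero(qv.q > 0)
    gamma = np.eye(n)
    if case == "strict":
        vecs = closing_polygon(qv.q[nz])
        units = np.stack([v / np.linalg.norm(v) for v in vecs])
        gram = units @ units.T
        gamma[np.ix_(nz, nz)] = gram
    else:  # equality: collinear vectors, the largest opposed to the rest
        s = np.ones(nz.size)
        s[int(np.argmax(qv.q[nz]))] = -1.0
        gamma[np.ix_(nz, nz)] = np.outer(s, s)
    signs = np.where(qv.signs == 0, 1, qv.signs).astype(float)
    corr = gamma * np.outer(signs, signs)
    corr[np.diag_indices(n)] = 1.0
    corr = 0.5 * (corr + corr.T)

    # verify the defining properties
    a = ole_solution(stats, None)
    sd = stats.noise_sds
    cn = corr * np.outer(sd, sd)
    resid = np.linalg.norm(cn @ a)
    scale = eig_scale(cn) * max(np.linalg.norm(a), 1e-300)
    if resid > CANCEL_RTOL * scale * 10:
        raise RuntimeError(f"construction failed: ||C^n A|| = {resid:.3e}")
    lo, _ = min_max_eig(corr)
    if lo < -1e-9 * eig_scale(corr):
        raise RuntimeError(f"construction failed: min eigenvalue {lo:.3e}")

    dim = canceling_set_dimension(stats)
    basis = canceling_basis(stats) if case == "strict" else []
    return CancelSolution(corr=corr, dimension=dim, basis=basis, case=case, q=qv)


def canceling_basis(stats: PopulationStats) -> list[PairVector]:
    """Directions spanning the homogeneous solutions of ``C^n A = 0``."""
    t, _ = _constraint_system(stats)
    ns = null_space(t, rcond=1e-10)
    return [PairVector(ns[:, k], label="direction") for k in range(ns.shape[1])]


def canceling_set_dimension(stats: PopulationStats) -> int:
    """Dimension of the convex set of canceling correlation matrices.

    Strict case: number of off-diagonal unknowns minus the rank of the linear
    constraint system (the generic solution admits two-sided perturbations in
    every homogeneous direction).  With all q nonzero this is
    ``N(N-1)/2 - N``.  Equality case: 0 when all q are nonzero (the solution
    is unique); with N0 zeros a free PSD block of dimension N0(N0+1)/2
    survives.
    """
    qv = q_values(stats)
    case = feasibility(qv)
    if case == "infeasible":
        raise InfeasibleError("no noise-canceling correlations exist")
    if case == "equality":
        return 0 if qv.n_zero == 0 else qv.n_zero * (qv.n_zero + 1) // 2
    t, _ = _constraint_system(stats)
    rank = int(np.linalg.matrix_rank(t, tol=1e-10 * max(np.linalg.norm(t), 1.0)))
    return n_pairs(stats.n_neurons) - rank


def find_canceling_numeric(
    stats: PopulationStats, max_iter: int = 500, rtol: float = 1e-9
) -> np.ndarray | None:
    """Numeric canceling correlations by alternating convex projections.

    Works for any stimulus dimension: alternates projection onto the affine
    set ``{rho : C^n(rho) A = 0}`` and onto the correlation spectrahedron.
    Returns the pair vector on success, None if no intersection is found.
    This is an oracle independent of the polygon construction.
    """
    t, r = _constraint_system(stats)
    if np.allclose(t, 0.0):
        return None if not np.allclose(r, 0.0) else np.zeros(n_pairs(stats.n_neurons))
    t_pinv = np.linalg.pinv(t, rcond=1e-12)
    x = np.zeros(n_pairs(stats.n_neurons))
    scale = max(np.linalg.norm(r), 1.0)
    for _ in range(max_iter):
        x = x - t_pinv @ (t @ x - r)  # affine projection
        mat = nearest_correlation(pairs_to_matrix(np.clip(x, -1.0, 1.0), 1.0))
        x_new = matrix_to_pairs(mat)
        if np.linalg.norm(t @ x_new - r) < rtol * scale:
            return x_new
        x = x_new
    return None


def _wilson_interval(successes: int, n: int, z: float = 2.5758293035489004) -> tuple[float, float]:
    """Wilson score interval (default 99% confidence)."""
    if n <= 0:
        raise ValueError("n must be positive")
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


def feasibility_probability(
    dist, n_neurons: int, reps: int = 10000, rng: np.random.Generator | None = None,
    confidence_z: float = 2.5758293035489004,
) -> dict:
    """Monte-Carlo probability that i.i.d. q values satisfy 2 max(q) <= sum(q).

    ``dist`` is either the string 'uniform' or a callable
    ``dist(rng, (reps, n_neurons)) -> array``.  Returns the estimate with a
    Wilson interval; deterministic under a fixed generator.
    """
    if reps < 1000:
        raise ValueError("reps must be at least 1000")
    if rng is None:
        rng = np.random.default_rng()
    if dist == "uniform":
        samples = rng.uniform(0.0, 1.0, size=(reps, n_neurons))
    elif callable(dist):
        samples = np.asarray(dist(rng, (reps, n_neurons)), dtype=float)
    else:
        raise ValueError("dist must be 'uniform' or a callable")
    feasible = 2.0 * samples.max(axis=1) <= samples.sum(axis=1)
    k = int(np.sum(feasible))
    lo, hi = _wilson_interval(k, reps, confidence_z)
    return {
        "probability": k / reps,
        "ci_low": lo,
        "ci_high": hi,
        "reps": reps,
        "n_neurons": n_neurons,
    }
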