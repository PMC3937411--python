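"""Maximization of information over admissible noise correlations.

Each information measure is a convex function of the pairwise correlations,
so its maximum over the (convex, bounded) spectrahedron sits on the boundary.
Maximizing a convex function is a nonconvex problem; the solver is a
multi-start projected gradient ascent with analytic gradients, projecting
onto the spectrahedron (nearest-correlation style) and, optionally, onto a
Euclidean norm cap on the correlation strength.

A penalty sweep ``max info - lambda * sum(rho^2)`` traces the optimal
(strength, information) frontier: by the Lagrange argument each penalty
solution is optimal among all points with strength up to its achieved norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._linalg import eig_scale, min_max_eig, n_pairs, nearest_correlation, pairs_to_matrix
from . import measures as msr
from .measures import NoiseCov, PairVector, PopulationStats, noise_cov_from
from .spectrahedron import classify, max_step, random_admissible

__all__ = ["OptimizationResult", "maximize_info", "penalty_sweep", "sr_curve", "targeted_penalty"]

# Below this floor (relative min eigenvalue) a fisher/mutual evaluation is
# regularized and the optimum flagged as divergent.
PD_FLOOR = 1e-9


@dataclass
class OptimizationResult:
    best_corr: PairVector
    best_info: float
    boundary_flag: bool
    active_constraint: str  # "psd" | "norm_cap" | "none"
    n_restarts: int
    trace: list = field(default_factory=list)
    divergent: bool = False
    degenerate_flat: bool = False
    independent_info: float = 0.0


def _safe_noise(stats: PopulationStats, rho: np.ndarray, measure: str) -> tuple[NoiseCov, bool]:
    """Noise covariance for a correlation vector, floored to PD when the
    measure requires an invertible C^n (fisher) or joint consistency (mutual)."""
    mat = pairs_to_matrix(np.clip(rho, -1.0, 1.0), 1.0)
    clipped = False
    if measure in ("fisher", "mutual"):
        lo, _ = min_max_eig(mat)
        scale = eig_scale(mat)
        floor = 10 * PD_FLOOR * scale
        if lo < floor:
            w, v = np.linalg.eigh(mat)
            mat = (v * np.maximum(w, floor)) @ v.T
            d = np.sqrt(np.diag(mat))
            mat = mat / np.outer(d, d)
            clipped = True
    sd = np.sqrt(stats.noise_vars)
    return NoiseCov(mat * np.outer(sd, sd)), clipped


def _objective(stats: PopulationStats, rho: np.ndarray, measure: str, lam: float = 0.0) -> float:
    noise, _ = _safe_noise(stats, rho, measure)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = msr.info(stats, noise, measure)
    except msr.InconsistentJointCovarianceError:
        return -np.inf
    if not np.isfinite(val):
        val = 1e300
    return val - lam * float(rho @ rho)


def _gradient(stats: PopulationStats, rho: np.ndarray, measure: str, lam: float = 0.0) -> np.ndarray:
    noise, _ = _safe_noise(stats, rho, measure)
    g = msr.info_gradient(stats, noise, measure).values
    return g - 2.0 * lam * rho


def _project(rho: np.ndarray, norm_cap: float | None, iters: int = 40) -> np.ndarray:
    """Approximate projection onto spectrahedron (and norm ball, if capped)."""
    from ._linalg import matrix_to_pairs

    x = rho.copy()
    for _ in range(iters):
        moved = False
        mat = pairs_to_matrix(np.clip(x, -1.0, 1.0), 1.0)
        lo, _ = min_max_eig(mat)
        if lo < -1e-12 * eig_scale(mat) or np.any(np.abs(x) > 1.0):
            x = matrix_to_pairs(nearest_correlation(mat))
            moved = True
        if norm_cap is not None:
            nrm = np.linalg.norm(x)
            if nrm > norm_cap + 1e-12:
                x = x * (norm_cap / nrm)
                moved = True
        if not moved:
            break
    return np.clip(x, -1.0, 1.0)


def _ascend(
    stats: PopulationStats,
    x0: np.ndarray,
    measure: str,
    lam: float,
    norm_cap: float | None,
    tol: float,
    max_iter: int = 300,
) -> tuple[np.ndarray, float, list]:
    x = _project(x0, norm_cap)
    f = _objective(stats, x, measure, lam)
    eta = 0.05
    trace = [(0, f)]
    for it in range(1, max_iter + 1):
        g = _gradient(stats, x, measure, lam)
        gn = np.linalg.norm(g)
        if gn < tol:
            break
        step = g / max(gn, 1e-300)
        improved = False
        for _ in range(30):
            x_new = _project(x + eta * step, norm_cap)
            f_new = _objective(stats, x_new, measure, lam)
            if f_new > f + 1e-14 * max(abs(f), 1.0):
                x, f = x_new, f_new
                eta = min(eta * 1.5, 1.0)
                improved = True
                break
            eta *= 0.5
            if eta < 1e-12:
                break
        trace.append((it, f))
        if not improved:
            break
    return x, f, trace


def maximize_info(
    stats: PopulationStats,
    measure: str = "ole",
    norm_cap: float | None = None,
    restarts: int = 20,
    seed: int | None = 0,
    tol: float = 1e-9,
    penalty: float = 0.0,
    extra_starts: list | None = None,
    canceling_start: str | np.ndarray | None = "auto",
) -> OptimizationResult:
    """Maximize an information measure over admissible noise correlations.

    Multi-start projected gradient ascent.  Candidate starts: independence,
    the scaled sign-rule gradient direction, random admissible points, and a
    noise-canceling solution when one exists (OLE, scalar stimulus).  The
    returned point is admissible, respects the norm cap, and its information
    is at least the independent-noise value.
    """
    rng = np.random.default_rng(seed)
    n = stats.n_neurons
    m = n_pairs(n)
    zero = np.zeros(m)
    baseline = _objective(stats, zero, measure, 0.0)

    starts = [zero]
    g0 = _gradient(stats, zero, measure, 0.0)
    if np.linalg.norm(g0) > 1e-12:
        direction = g0 / np.linalg.norm(g0)
        t_max = max_step(zero, direction)
        t_use = t_max if norm_cap is None else min(t_max, norm_cap)
        starts.append(0.999 * t_use * direction)
    if isinstance(canceling_start, np.ndarray):
        starts.append(np.asarray(canceling_start, dtype=float))
    elif canceling_start == "auto" and measure == "ole":
        try:
            from .cancel import find_canceling_numeric

            cand = find_canceling_numeric(stats)
            if cand is not None:
                starts.append(cand)
        except Exception:
            pass
    if extra_starts:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    while len(starts) < restarts:
        d = n if rng.uniform() < 0.5 else int(rng.integers(1, n + 1))
        starts.append(random_admissible(n, d, rng).corr.values)

    best_x, best_f, best_trace = None, -np.inf, []
    for x0 in starts:
        x, f, trace = _ascend(stats, x0, measure, penalty, norm_cap, tol)
        if f > best_f:
            best_x, best_f, best_trace = x, f, trace

    best_info = _objective(stats, best_x, measure, 0.0)
    noise, clipped = _safe_noise(stats, best_x, measure)
    point = classify(best_x)
    degenerate = bool(np.allclose(stats.cross_cov, 0.0)) and measure == "ole"
    if degenerate:
        warnings.warn("OLE information is identically zero (L = 0): flat objective")
    cap_active = norm_cap is not None and np.linalg.norm(best_x) >= norm_cap - 1e-6
    if point.on_boundary or clipped:
        active = "psd"
    elif cap_active:
        active = "norm_cap"
    else:
        active = "none"
    divergent = clipped and measure in ("fisher", "mutual")
    return OptimizationResult(
        best_corr=PairVector(best_x, label="noise_corr"),
        best_info=float(best_info),
        boundary_flag=point.on_boundary or clipped,
        active_constraint=active,
        n_restarts=len(starts),
        trace=best_trace,
        divergent=divergent,
        degenerate_flat=degenerate,
        independent_info=float(baseline),
    )


def targeted_penalty(stats: PopulationStats, measure: str, target_strength: float) -> float:
    """Penalty prefactor forcing the optimum toward a given strength.

    Near independence the objective gradient is ~ G, so with the penalty
    ``(||G|| / (2 c)) * sum(rho^2)`` the stationarity condition puts the
    solution at ``rho = c G / ||G||`` — strength ``c``.
    """
    g = msr.info_gradient_at_independent(stats, measure).values
    if target_strength <= 0:
        raise ValueError("target strength must be positive")
    return float(np.linalg.norm(g) / (2.0 * target_strength))


def penalty_sweep(
    stats: PopulationStats,
    measure: str = "ole",
    lambdas: list | np.ndarray | None = None,
    restarts: int = 8,
    seed: int | None = 0,
    tol: float = 1e-9,
) -> list[dict]:
    """Sweep the penalty ``info - lambda * sum(rho^2)`` over lambda values.

    ``lambdas`` must be nonnegative; they are sorted descending so each
    solution warm-starts the next (larger penalties shrink toward
    independence).  Returns one record per lambda with the achieved strength
    and information.
    """
    if lambdas is None:
        g0 = msr.info_gradient_at_independent(stats, measure).values
        scale = np.linalg.norm(g0)
        lambdas = np.geomspace(10.0 * scale, 1e-3 * scale, 12)
        lambdas = np.append(lambdas, 0.0)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    if np.any(lambdas < 0):
        raise ValueError("lambdas must be nonnegative")
    cancel_cand: np.ndarray | None = None
    if measure == "ole":
        try:
            from .cancel import find_canceling_numeric

            cancel_cand = find_canceling_numeric(stats)
        except Exception:
            cancel_cand = None
    results = []
    warm: np.ndarray | None = None
    for lam in lambdas:
        extra = [warm] if warm is not None else None
        res = maximize_info(
            stats, measure, norm_cap=None, restarts=restarts, seed=seed, tol=tol,
            penalty=float(lam), extra_starts=extra,
            canceling_start=cancel_cand if cancel_cand is not None else None,
        )
        warm = res.best_corr.values
        results.append(
            {
                "lambda": float(lam),
                "achieved_norm": float(np.linalg.norm(res.best_corr.values)),
                "best_corr": res.best_corr,
                "best_info": float(res.best_info),
            }
        )
    return results


def sr_curve(
    stats: PopulationStats, measure: str = "ole", strengths: list | np.ndarray = (),
) -> list[dict]:
    """Information along the sign-rule (gradient) direction at given strengths.

    Entries beyond the maximal feasible step are reported as infeasible.
    """
    strengths = np.asarray(strengths, dtype=float)
    if np.any(strengths < 0):
        raise ValueError("strengths must be nonnegative")
    m = n_pairs(stats.n_neurons)
    g0 = msr.info_gradient_at_independent(stats, measure).values
    gn = np.linalg.norm(g0)
    if gn < 1e-300:
        direction = np.zeros(m)
        t_max = 0.0
    else:
        direction = g0 / gn
        t_max = max_step(np.zeros(m), direction)
    out = []
    for s in strengths:
        if s > t_max + 1e-12:
            out.append({"strength": float(s), "feasible": False, "info": None})
            continue
        rho = min(s, t_max) * direction
        val = _objective(stats, rho, measure, 0.0)
        out.append({"strength": float(s), "feasible": True, "info": float(val)})
    return out
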