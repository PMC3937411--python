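"""Geometry of admissible pairwise correlations with unit diagonal.

The set of N x N correlation matrices (symmetric PSD, diagonal fixed at 1)
is a bounded convex spectrahedron in the M = N(N-1)/2 dimensional space of
off-diagonal entries.  This module classifies points, computes the maximal
feasible step along a ray, and samples admissible points with controlled
rank (rank < N lands on the boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import (
    BOUNDARY_RTOL,
    eig_scale,
    matrix_to_pairs,
    min_max_eig,
    pairs_to_matrix,
)
from .measures import PairVector

__all__ = ["CorrelationPoint", "classify", "max_step", "random_admissible"]


@dataclass(frozen=True)
class CorrelationPoint:
    """A pairwise-correlation vector with its PSD admissibility status."""

    corr: PairVector
    min_eig: float
    admissible: bool
    on_boundary: bool

    def matrix(self) -> np.ndarray:
        return self.corr.matrix(1.0)


def classify(
    corr: PairVector | np.ndarray,
    noise_vars: np.ndarray | None = None,
    tol: float = BOUNDARY_RTOL,
) -> CorrelationPoint:
    """Eigenvalue classification of a correlation point.

    admissible  iff min_eig >= -tol * lambda_max
    on_boundary iff admissible and min_eig <= tol * lambda_max

    ``noise_vars`` is accepted for interface symmetry but does not influence
    admissibility: ``C^n = S R S`` (S = diag of noise SDs) is PSD exactly when
    the correlation matrix ``R`` is.
    """
    del noise_vars
    vals = corr.values if isinstance(corr, PairVector) else np.asarray(corr, dtype=float)
    if np.any(np.abs(vals) > 1 + 1e-12):
        # entrywise violation: certainly inadmissible, report anyway
        vals = np.asarray(vals, dtype=float)
    mat = pairs_to_matrix(np.clip(vals, -1.0, 1.0), 1.0)
    lo, _ = min_max_eig(mat)
    scale = eig_scale(mat)
    admissible = bool(lo >= -tol * scale) and bool(np.all(np.abs(vals) <= 1 + 1e-12))
    on_boundary = admissible and bool(lo <= tol * scale)
    pv = PairVector(np.clip(vals, -1.0, 1.0), label="noise_corr")
    return CorrelationPoint(corr=pv, min_eig=lo, admissible=admissible, on_boundary=on_boundary)


def max_step(
    corr0: PairVector | np.ndarray,
    direction: PairVector | np.ndarray,
    noise_vars: np.ndarray | None = None,
    tol: float = 1e-10,
) -> float:
    """Largest t >= 0 such that ``corr0 + t * direction`` stays admissible.

    For an interior starting point the critical step solves a symmetric
    eigenvalue problem: with ``R(t) = R0 + t B`` and ``R0 = R0^{1/2} R0^{1/2}``
    positive definite, ``R(t) >= 0`` iff ``1 + t * lambda >= 0`` for every
    eigenvalue ``lambda`` of ``R0^{-1/2} B R0^{-1/2}``.  A boundary start
    falls back to bisection.
    """
    del noise_vars  # admissibility is invariant under the diagonal rescaling
    x0 = corr0.values if isinstance(corr0, PairVector) else np.asarray(corr0, dtype=float)
    b = direction.values if isinstance(direction, PairVector) else np.asarray(direction, dtype=float)
    if np.allclose(b, 0.0):
        raise ValueError("direction must be nonzero (every ray exits the bounded set)")
    point = classify(x0)
    if not point.admissible:
        raise ValueError("corr0 must be admissible")
    r0 = pairs_to_matrix(x0, 1.0)
    bmat = pairs_to_matrix(b, 0.0)
    lo0, _ = min_max_eig(r0)
    if lo0 > 1e-8 * eig_scale(r0):
        w, v = np.linalg.eigh(r0)
        inv_sqrt = (v / np.sqrt(w)) @ v.T
        s = inv_sqrt @ bmat @ inv_sqrt
        lam_min = float(np.linalg.eigvalsh(0.5 * (s + s.T))[0])
        if lam_min >= -1e-14:
            # PSD never violated along the ray; entrywise bounds still apply
            t_psd = np.inf
        else:
            t_psd = 1.0 / (-lam_min)
    else:
        t_psd = _bisect_step(x0, b)
    # entrywise |rho| <= 1 along the ray
    t_box = np.inf
    for xi, bi in zip(x0, b):
        if bi > 0:
            t_box = min(t_box, (1.0 - xi) / bi)
        elif bi < 0:
            t_box = min(t_box, (-1.0 - xi) / bi)
    t = min(t_psd, t_box)
    if not np.isfinite(t):
        raise ValueError("ray never exits the admissible set; inconsistent inputs")
    return max(float(t), 0.0)


def _bisect_step(x0: np.ndarray, b: np.ndarray, hi_start: float = 4.0, iters: int = 80) -> float:
    def ok(t: float) -> bool:
        x = x0 + t * b
        if np.any(np.abs(x) > 1 + 1e-12):
            return False
        mat = pairs_to_matrix(np.clip(x, -1.0, 1.0), 1.0)
        lo, _ = min_max_eig(mat)
        return lo >= -1e-12 * eig_scale(mat)

    lo, hi = 0.0, hi_start
    while ok(hi):
        hi *= 2.0
        if hi > 1e6:
            return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def random_admissible(
    n_neurons: int, rank: int | None = None, rng: np.random.Generator | None = None
) -> CorrelationPoint:
    """Random admissible point: Gram matrix of N random unit vectors in R^rank.

    ``rank < N`` yields boundary points; ``rank = N`` is generically interior.
    Deterministic under a fixed generator.
    """
    if rng is None:
        rng = np.random.default_rng()
    d = n_neurons if rank is None else int(rank)
    if d < 1 or d > n_neurons:
        raise ValueError(f"rank must be in [1, {n_neurons}], got {d}")
    vecs = rng.standard_normal((n_neurons, d))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    gram = vecs @ vecs.T
    return classify(PairVector(matrix_to_pairs(gram), label="noise_corr"))
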