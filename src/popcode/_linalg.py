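"""Shared linear-algebra helpers: pair indexing, PSD tolerances, safe inverses.

Pairwise quantities (correlations, gradients, directions) over ``N`` neurons
live in a vector of length ``M = N * (N - 1) / 2`` ordered lexicographically
over pairs ``(i, j)`` with ``i < j`` (the order of ``numpy.triu_indices``).
"""

from __future__ import annotations

import numpy as np

# Relative eigenvalue cutoffs.  A symmetric matrix is accepted as PSD when its
# smallest eigenvalue is >= -PSD_RTOL * lambda_max, and treated as singular
# (non-invertible) when the smallest eigenvalue is < SINGULAR_RTOL * lambda_max.
PSD_RTOL = 1e-9
SINGULAR_RTOL = 1e-12
# Boundary-of-spectrahedron tolerance (relative to lambda_max).
BOUNDARY_RTOL = 1e-8


class NotPositiveDefiniteError(ValueError):
    """A matrix required to be positive definite is singular or indefinite."""

    def __init__(self, message: str, min_eigenvalue: float | None = None):
        super().__init__(message)
        self.min_eigenvalue = min_eigenvalue


class InconsistentJointCovarianceError(ValueError):
    """The joint stimulus/response covariance is not positive semidefinite."""


class InfeasibleError(ValueError):
    """No noise-canceling correlations exist for the supplied statistics."""


def n_pairs(n_neurons: int) -> int:
    return n_neurons * (n_neurons - 1) // 2

def pair_indices(n_neurons: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the upper triangle, lexicographic in (i, j)."""
    return np.triu_indices(n_neurons, k=1)


def n_from_pairs(m: int) -> int:
    """Invert M = N(N-1)/2; raises if m is not a triangular number."""
    n = int(round((1.0 + np.sqrt(1.0 + 8.0 * m)) / 2.0))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"length {m} is not N*(N-1)/2 for any integer N")
    return n


def pairs_to_matrix(values: np.ndarray, diag: np.ndarray | float = 1.0) -> np.ndarray:
    """Symmetric matrix with the given upper-triangle values and diagonal."""
    values = np.asarray(values, dtype=float)
    n = n_from_pairs(values.size)
    out = np.zeros((n, n))
    iu, ju = pair_indices(n)
    out[iu, ju] = values
    out[ju, iu] = values
    out[np.diag_indices(n)] = diag
    return out


def matrix_to_pairs(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    iu, ju = pair_indices(mat.shape[0])
    return mat[iu, ju].copy()


def sym_eigvals(mat: np.ndarray) -> np.ndarray:
    return np.linalg.eigvalsh(0.5 * (mat + mat.T))


def min_max_eig(mat: np.ndarray) -> tuple[float, float]:
    w = sym_eigvals(mat)
    return float(w[0]), float(w[-1])


def eig_scale(mat: np.ndarray) -> float:
    """Scale for relative eigenvalue tolerances: max(|lambda|), floored at 1."""
    w = sym_eigvals(mat)
    return max(float(np.max(np.abs(w))), 1.0)


def is_psd(mat: np.ndarray, rtol: float = PSD_RTOL) -> bool:
    lo, _ = min_max_eig(mat)
    return lo >= -rtol * eig_scale(mat)


def assert_pd(mat: np.ndarray, name: str = "matrix") -> None:
    """Raise NotPositiveDefiniteError unless mat is PD at tolerance."""
    lo, _ = min_max_eig(mat)
    if lo < SINGULAR_RTOL * eig_scale(mat):
        raise NotPositiveDefiniteError(
            f"{name} is not positive definite (min eigenvalue {lo:.3e})",
            min_eigenvalue=lo,
        )


def pd_solve(mat: np.ndarray, rhs: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Solve mat @ x = rhs for a symmetric PD matrix, with an explicit check."""
    assert_pd(mat, name)
    return np.linalg.solve(0.5 * (mat + mat.T), rhs)


def random_pd(rng: np.random.Generator, n: int, cond_spread: float = 1.0) -> np.ndarray:
    """Random symmetric positive-definite matrix with O(1) eigenvalues."""
    w = np.linalg.qr(rng.standard_normal((n, n)))[0]
    eigs = np.exp(cond_spread * rng.standard_normal(n) * 0.5)
    return (w * eigs) @ w.T


def project_psd(mat: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Nearest (Frobenius) symmetric matrix with eigenvalues >= floor."""
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    return (v * np.maximum(w, floor)) @ v.T


def nearest_correlation(mat: np.ndarray, tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projections.

    Alternates projection onto the PSD cone (with Dykstra correction) and onto
    the unit-diagonal affine set.
    """
    y = 0.5 * (np.asarray(mat, dtype=float) + np.asarray(mat, dtype=float).T)
    n = y.shape[0]
    ds = np.zeros_like(y)
    x = y.copy()
    for _ in range(max_iter):
        r = x - ds
        x_psd = project_psd(r)
        ds = x_psd - r
        x_new = x_psd.copy()
        x_new[np.diag_indices(n)] = 1.0
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    # final clean-up: guarantee PSD up to tolerance and exact unit diagonal
    x = project_psd(x)
    d = np.sqrt(np.clip(np.diag(x), 1e-300, None))
    x = x / np.outer(d, d)
    x[np.diag_indices(n)] = 1.0
    return 0.5 * (x + x.T)
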