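"""Sampling moments of vectorized covariance and correlation matrices.

The joint-coefficient covariance correction needs ``V_R`` — the asymptotic
covariance of ``sqrt(n) * vec(R_hat - R)`` for a sample correlation matrix
``R_hat`` estimated from ``n`` rows.  ``V_R`` is obtained by the delta method
from the covariance ``V_Sigma`` of the vectorized sample *covariance* matrix:

    V_R = J @ V_Sigma @ J.T,   J = d vec(R) / d vec(Sigma).

``V_Sigma`` itself is estimated either under a Gaussian assumption, via the
closed form ``2 * Ms * (Sigma ⊗ Sigma)`` with ``Ms`` the symmetrizer
``(I + K_p) / 2``, or distribution-free from the per-row outer products.

All ``p² × p²`` operators use column-major (Fortran) vectorization, so that
``vec(A)[j*p + i] == A[i, j]``.  Storage is dense; sizes above ``p_max``
(default 150) are refused because the memory and time cost grows as ``p⁴``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "OperatorMatrix",
    "MomentEstimates",
    "commutation_matrix",
    "symmetrizer",
    "vcov_vec_cov_gaussian",
    "vcov_vec_cov_empirical",
    "corr_jacobian",
    "vcov_vec_corr",
]

P_MAX_DEFAULT = 150

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class OperatorMatrix:
    """A dense p²×p² linear operator on vectorized p×p matrices."""

    entries: np.ndarray
    kind: Literal["commutation", "symmetrizer", "jacobian"]

    @property
    def p(self) -> int:
        return int(round(self.entries.shape[0] ** 0.5))


@dataclass
class MomentEstimates:
    """Estimated covariance of sqrt(n)*vec(Sigma_hat) and sqrt(n)*vec(R_hat)."""

    v_sigma: np.ndarray
    n_used: int
    method: Literal["gaussian", "empirical"]
    v_corr: np.ndarray | None = field(default=None)

    @property
    def p(self) -> int:
        return int(round(self.v_sigma.shape[0] ** 0.5))


def _check_p(p: int, p_max: int = P_MAX_DEFAULT) -> int:
    p = int(p)
    if p < 1:
        raise ValueError(f"matrix dimension must be a positive integer, got {p}")
    if p > p_max:
        raise ValueError(
            f"p={p} exceeds the dense-operator limit p_max={p_max}; "
            "the p^4 memory/time cost of the moment machinery makes larger "
            "regions impractical — split the region or raise p_max explicitly"
        )
    return p


def commutation_matrix(p: int, p_max: int = P_MAX_DEFAULT) -> OperatorMatrix:
    """Permutation matrix ``K_p`` with ``K_p @ vec(A) = vec(A.T)``.

    ``K_p`` is an involution: ``K_p @ K_p = I``.
    """
    p = _check_p(p, p_max)
    k = np.zeros((p * p, p * p))
    # vec(A)[j*p + i] = A[i, j]; vec(A.T)[i*p + j] = A[i, j]
    rows = np.arange(p * p)
    i, j = rows % p, rows // p
    k[i * p + j, rows] = 1.0
    return OperatorMatrix(entries=k, kind="commutation")


def symmetrizer(p: int, p_max: int = P_MAX_DEFAULT) -> OperatorMatrix:
    """Symmetrization operator ``Ms = (I + K_p)/2``.

    Maps ``vec(A)`` to ``vec((A + A.T)/2)``; idempotent and symmetric.
    """
    k = commutation_matrix(p, p_max)
    ms = 0.5 * (np.eye(p * p) + k.entries)
    return OperatorMatrix(entries=ms, kind="symmetrizer")


def _require_symmetric(m: np.ndarray, name: str, tol: float = _SYM_TOL) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {m.shape}")
    scale = max(1.0, float(np.abs(m).max(initial=0.0)))
    if np.abs(m - m.T).max(initial=0.0) > tol * scale:
        raise ValueError(f"{name} is not symmetric within tolerance {tol}")
    return 0.5 * (m + m.T)


def vcov_vec_cov_gaussian(
    sigma_hat: np.ndarray, n_used: int = 0, p_max: int = P_MAX_DEFAULT
) -> MomentEstimates:
    """Gaussian closed form ``2·Ms·(Sigma ⊗ Sigma)`` for the covariance of
    ``sqrt(n)·vec(Sigma_hat)``.

    Exact (asymptotically) only when the rows are multivariate normal; for
    ``p = 1`` it reduces to the classical ``2·sigma⁴`` variance of a Gaussian
    sample variance.
    """
    sigma_hat = _require_symmetric(sigma_hat, "sigma_hat")
    p = _check_p(sigma_hat.shape[0], p_max)
    ms = symmetrizer(p, p_max).entries
    v = 2.0 * ms @ np.kron(sigma_hat, sigma_hat)
    v = 0.5 * (v + v.T)  # exact symmetry despite roundoff
    return MomentEstimates(v_sigma=v, n_used=int(n_used), method="gaussian")


def vcov_vec_cov_empirical(
    x: np.ndarray,
    center: bool = True,
    p_max: int = P_MAX_DEFAULT,
) -> MomentEstimates:
    """Distribution-free estimate of the covariance of ``sqrt(n)·vec(Sigma_hat)``.

    Treats each row's outer product ``x_i x_i'`` as one observation of the
    covariance matrix and returns the empirical covariance of their
    vectorizations:

        V = n⁻¹ Σ_i (vec(x_i x_i') − vec(Sigma_hat)) (…)'

    Parameters
    ----------
    x
        ``n × p`` matrix whose columns are mean zero (e.g. a standardized
        reference panel).  If ``center`` is true, columns are re-centered
        when their means deviate from zero; otherwise un-centered input is
        an error.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"x must be an n×p matrix, got shape {x.shape}")
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 rows to estimate fourth moments")
    _check_p(p, p_max)
    col_means = x.mean(axis=0)
    if np.abs(col_means).max(initial=0.0) > 1e-8:
        if not center:
            raise ValueError(
                "columns are not mean-zero; standardize the panel first or "
                "pass center=True"
            )
        x = x - col_means
    # rows of z are vec(x_i x_i'); symmetric outer products, so the
    # row-major/column-major distinction is immaterial here
    z = (x[:, :, None] * x[:, None, :]).reshape(n, p * p)
    zbar = z.mean(axis=0)
    zc = z - zbar
    v = (zc.T @ zc) / n
    v = 0.5 * (v + v.T)
    return MomentEstimates(v_sigma=v, n_used=n, method="empirical")


def corr_jacobian(sigma: np.ndarray, p_max: int = P_MAX_DEFAULT) -> OperatorMatrix:
    """Jacobian ``J = d vec(R) / d vec(Sigma)`` of the covariance-to-correlation
    map ``R = D^{-1/2} Sigma D^{-1/2}``, ``D = diag(Sigma)``, at ``sigma``.

    Entries (treating every coordinate of ``vec(Sigma)`` as free):

        dR_ij/dSigma_ij = (Sigma_ii Sigma_jj)^{-1/2}
        dR_ij/dSigma_ii = -Sigma_ij / (2 Sigma_ii^{3/2} Sigma_jj^{1/2})
        dR_ij/dSigma_jj = -Sigma_ij / (2 Sigma_jj^{3/2} Sigma_ii^{1/2})

    Rows for diagonal positions of ``R`` are identically zero since
    ``diag(R) ≡ 1``.
    """
    sigma = _require_symmetric(sigma, "sigma")
    p = _check_p(sigma.shape[0], p_max)
    d = np.diag(sigma).copy()
    if np.any(d <= 0):
        bad = int(np.flatnonzero(d <= 0)[0])
        raise ValueError(
            f"sigma has non-positive diagonal entry at index {bad}; the "
            "correlation transform is undefined for degenerate variances"
        )
    s = np.sqrt(d)
    j = np.zeros((p * p, p * p))
    for jj in range(p):
        for ii in range(p):
            if ii == jj:
                continue  # R_ii constant
            row = jj * p + ii
            j[row, jj * p + ii] += 1.0 / (s[ii] * s[jj])
            j[row, ii * p + ii] += -0.5 * sigma[ii, jj] / (d[ii] * s[ii] * s[jj])
            j[row, jj * p + jj] += -0.5 * sigma[ii, jj] / (d[jj] * s[jj] * s[ii])
    return OperatorMatrix(entries=j, kind="jacobian")


def vcov_vec_corr(
    moments: MomentEstimates, sigma: np.ndarray, p_max: int = P_MAX_DEFAULT
) -> MomentEstimates:
    """Fill ``v_corr = J @ v_sigma @ J.T``, the covariance of
    ``sqrt(n)·vec(R_hat)``, by the delta method.

    Rows/columns at diagonal positions of ``R`` are exactly zero.
    """
    sigma = _require_symmetric(sigma, "sigma")
    p = sigma.shape[0]
    if moments.v_sigma.shape != (p * p, p * p):
        raise ValueError(
            f"dimension mismatch: v_sigma is {moments.v_sigma.shape}, "
            f"sigma implies {(p * p, p * p)}"
        )
    j = corr_jacobian(sigma, p_max).entries
    v = j @ moments.v_sigma @ j.T
    v = 0.5 * (v + v.T)
    diag_pos = np.arange(p) * p + np.arange(p)
    v[diag_pos, :] = 0.0
    v[:, diag_pos] = 0.0
    return MomentEstimates(
        v_sigma=moments.v_sigma,
        n_used=moments.n_used,
        method=moments.method,
        v_corr=v,
    )
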