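"""Point estimation from summary statistics and a reference panel.

The data model: an original study of ``n_o`` individuals reported only the
per-variant marginal regression coefficients ``beta_om = X_o' y / n_o`` of a
standardized phenotype on standardized genotype columns.  An independent
reference panel ``X_r`` (``n_r × p``) from the same population provides the
LD (correlation) matrix estimate ``R_r = X_r' X_r / n_r``.  Joint
("fine-mapping") coefficients are reconstructed as ``beta_mc = R_r⁻¹ beta_om``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import linalg, stats

__all__ = [
    "StandardizedPanel",
    "MarginalStats",
    "JointEstimate",
    "standardize",
    "marginal_coefficients",
    "joint_from_marginal",
    "residual_variance",
    "threshold_beta",
]

SIGMA2_FLOOR = 1e-8
COND_LIMIT_DEFAULT = 1e8


@dataclass
class StandardizedPanel:
    """Column-standardized covariate matrix with its correlation estimate.

    Columns have mean 0 and standard deviation 1 computed with divisor ``n``,
    so ``corr = x.T @ x / n`` has an exact unit diagonal.
    """

    x: np.ndarray
    corr: np.ndarray
    variant_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]


@dataclass
class MarginalStats:
    """Marginal (single-variant) regression coefficients with sample size."""

    beta_om: np.ndarray
    n_o: int
    variant_ids: list[str] | None = None

    @property
    def p(self) -> int:
        return self.beta_om.shape[0]


@dataclass
class JointEstimate:
    """Joint coefficients with their covariance and the inference method tag."""

    beta_mc: np.ndarray
    sigma2_hat: float
    sigma_mc: np.ndarray
    method: Literal["full", "naive", "corrected_gaussian", "corrected_empirical"]
    ratio_c: float
    beta_threshold: np.ndarray | None = field(default=None)

    @property
    def p(self) -> int:
        return self.beta_mc.shape[0]


def standardize(
    x_raw: np.ndarray, variant_ids: Sequence[str] | None = None
) -> StandardizedPanel:
    """Standardize columns to mean 0, sd 1 (divisor ``n``) and attach the
    correlation estimate ``X'X/n``.

    Raises on constant (e.g. monomorphic genotype) columns, naming the first
    offending column.
    """
    x_raw = np.asarray(x_raw, dtype=float)
    if x_raw.ndim != 2:
        raise ValueError(f"expected an n×p matrix, got shape {x_raw.shape}")
    n, p = x_raw.shape
    if n < 2:
        raise ValueError("need at least 2 rows to standardize")
    mu = x_raw.mean(axis=0)
    sd = x_raw.std(axis=0)  # divisor n
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = variant_ids[bad] if variant_ids is not None else str(bad)
        raise ValueError(
            f"column {name!r} is constant (zero variance); remove monomorphic "
            "variants before standardizing"
        )
    x = (x_raw - mu) / sd
    corr = x.T @ x / n
    np.fill_diagonal(corr, 1.0)
    corr = 0.5 * (corr + corr.T)
    ids = list(variant_ids) if variant_ids is not None else None
    return StandardizedPanel(x=x, corr=corr, variant_ids=ids)


def marginal_coefficients(panel: StandardizedPanel, y: np.ndarray) -> MarginalStats:
    """Marginal coefficients ``beta_om = X'y/n`` of a standardized phenotype.

    Each entry is the simple-regression slope of ``y`` on the corresponding
    standardized column.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != panel.n:
        raise ValueError(
            f"phenotype length {y.shape[0]} does not match panel rows {panel.n}"
        )
    beta_om = panel.x.T @ y / panel.n
    return MarginalStats(beta_om=beta_om, n_o=panel.n, variant_ids=panel.variant_ids)


def _solve_corr(corr: np.ndarray, rhs: np.ndarray, cond_limit: float) -> np.ndarray:
    """Solve ``corr @ x = rhs`` via Cholesky with a condition-number guard."""
    try:
        cho = linalg.cho_factor(corr, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "reference LD matrix is singular (n_r <= p or perfectly collinear "
            "variants); prune correlated variants or enlarge the panel"
        ) from exc
    cond = np.linalg.cond(corr)
    if cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"reference LD matrix condition number {cond:.3g} exceeds limit "
            f"{cond_limit:.3g}; prune near-duplicate variants"
        )
    return linalg.cho_solve(cho, rhs)


def joint_from_marginal(
    marg: MarginalStats,
    ref: StandardizedPanel,
    cond_limit: float = COND_LIMIT_DEFAULT,
) -> np.ndarray:
    """Reconstruct joint coefficients ``beta_mc = R_r⁻¹ beta_om``.

    The defining identity ``R_r @ beta_mc = beta_om`` holds to numerical
    precision.
    """
    if ref.p != marg.p:
        raise ValueError(
            f"panel has {ref.p} variants but summary stats have {marg.p}"
        )
    return _solve_corr(ref.corr, marg.beta_om, cond_limit)


def residual_variance(
    beta: np.ndarray, corr: np.ndarray, conservative: bool = False
) -> float:
    """Residual variance of the standardized phenotype.

    With ``y`` standardized, ``sigma² = 1 − beta' R beta``; the plug-in
    ``1 − beta_mc' R_r beta_mc`` is asymptotically unbiased.  The result is
    clipped to ``[1e-8, 1]`` so downstream variances stay positive.  With
    ``conservative=True`` returns 1, an always-valid upper bound.
    """
    if conservative:
        return 1.0
    beta = np.asarray(beta, dtype=float).ravel()
    corr = np.asarray(corr, dtype=float)
    s2 = 1.0 - float(beta @ corr @ beta)
    return float(np.clip(s2, SIGMA2_FLOOR, 1.0))


def threshold_beta(
    beta_mc: np.ndarray,
    ref: StandardizedPanel,
    sigma2: float,
    n_o: int,
    level: float = 0.05,
    cond_limit: float = COND_LIMIT_DEFAULT,
) -> np.ndarray:
    """Sparsify ``beta_mc`` for the covariance plug-in.

    Coefficients whose naive-variance test statistic

        T_i = sqrt(n_o) * beta_mc_i / (sigma * sqrt((R_r⁻¹)_ii))

    falls below the two-sided normal critical value at ``level`` are set to
    zero; the rest are kept unchanged.  Because the naive variance is liberal,
    any coefficient significant under the corrected variance survives this
    screen.  With many truly nonzero coefficients the screen can zero genuine
    signal and understate the correction — use a more lenient ``level`` (or
    skip thresholding) for dense regions.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    beta_mc = np.asarray(beta_mc, dtype=float).ravel()
    rinv_diag = np.diag(_solve_corr(ref.corr, np.eye(ref.p), cond_limit))
    t_stat = np.sqrt(n_o) * beta_mc / (np.sqrt(sigma2) * np.sqrt(rinv_diag))
    crit = stats.norm.ppf(1.0 - level / 2.0)
    out = beta_mc.copy()
    out[np.abs(t_stat) < crit] = 0.0
    return out
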