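"""Synthetic study designs and the simulation harness.

Three generators emulate the evaluation settings for reference-panel
fine-mapping:

* **Gaussian covariates** — rows drawn from ``N(0, Sigma)`` with AR(1)
  correlation ``Sigma_ij = rho^|i−j|``.
* **Pseudo-genotypes** — the same latent Gaussians, quantile-thresholded into
  minor-allele counts {0, 1, 2}.  Per-variant minor allele frequencies are
  drawn from ``Beta(1, 2)/2`` truncated below at 0.05; the cut points
  ``z_{1−2q/3}`` and ``z_{1−q/3}`` give ``P(g=1) = P(g=2) = q/3`` so the
  expected minor-allele count per genotype is ``q``.
* **Selection-conditioned phenotypes** — the residual noise is redrawn until
  the screened variant's marginal coefficient clears the genome-wide
  threshold, emulating regions that reach fine-mapping only because they
  were screened in.

The phenotype model is ``y = X beta + eps`` with ``eps ~ N(0, sigma²)``; the
signal strength is parameterized by the heritability
``h = beta'R beta / (sigma² + beta'R beta)`` and ``sigma²`` is solved from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    MarginalStats,
    StandardizedPanel,
    marginal_coefficients,
    standardize,
)
from .inference import finemap_region
from .psat import make_selection, psat_finemap

__all__ = [
    "SelectionConfig",
    "SimConfig",
    "SimResult",
    "ar1_covariance",
    "sample_gaussian_panel",
    "sample_mafs",
    "genotype_transform",
    "sigma2_from_h",
    "simulate_phenotype",
    "simulate_until_selected",
    "fdp_tdp",
    "run_experiment",
]


@dataclass
class SelectionConfig:
    screened_index: int  # 0-based
    alpha: float = 0.05
    m: int = 20_000
    max_resamples: int = 100_000


@dataclass
class SimConfig:
    """One simulation setting.

    Defaults follow the core evaluation design: regions of ``p = 20``
    variants with AR(1) LD at ``rho = 0.8``, causal variants at the two region
    ends (``{1, 20}`` in 1-based terms) with unit coefficients, original-study
    size ``n_o = 10⁴`` and reference panel ``n_r = 10³``, heritability
    ``h = 0.05``, BH at ``q = 0.05``.
    """

    p: int = 20
    rho: float = 0.8
    n_o: int = 10_000
    n_r: int = 1_000
    causal_set: tuple[int, ...] = (0, 19)  # 0-based
    beta_value: float = 1.0
    h: float = 0.05
    covariate_kind: str = "gaussian"  # or "genotype"
    data_seed: int = 0
    maf_seed: int = 1
    reps: int = 1000
    q: float = 0.05
    threshold_level: float = 0.05
    selection: SelectionConfig | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.h < 1.0:
            raise ValueError("h must lie strictly inside (0,1)")
        if not all(0 <= i < self.p for i in self.causal_set):
            raise ValueError("causal_set indices out of range")
        if self.covariate_kind not in ("gaussian", "genotype"):
            raise ValueError(f"unknown covariate_kind {self.covariate_kind!r}")

    @property
    def beta(self) -> np.ndarray:
        b = np.zeros(self.p)
        b[list(self.causal_set)] = self.beta_value
        return b


@dataclass
class SimResult:
    """Aggregated FDR/power estimates for one method in one setting."""

    method: str
    fdr: float
    fdr_se: float
    power: float
    power_se: float
    conditional: bool
    reps: int
    records: pd.DataFrame = field(repr=False, default=None)
    unconditional_power: float | None = None
    unconditional_power_se: float | None = None


def ar1_covariance(p: int, rho: float) -> np.ndarray:
    """AR(1) covariance ``Sigma_ij = rho^|i−j|`` (positive definite for
    |rho| < 1)."""
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _ar1_chol_sample(n: int, p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows of N(0, AR1(rho)) using the AR recursion (O(np))."""
    z = rng.standard_normal((n, p))
    x = np.empty_like(z)
    x[:, 0] = z[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        x[:, j] = rho * x[:, j - 1] + scale * z[:, j]
    return x


def sample_gaussian_panel(
    n: int, sigma: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` iid rows from ``N(0, sigma)`` (raw, un-standardized)."""
    rng = np.random.default_rng(seed)
    sigma = np.asarray(sigma, dtype=float)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("covariance is not positive definite") from exc
    return rng.standard_normal((n, sigma.shape[0])) @ chol.T


def sample_mafs(p: int, seed: int | np.random.Generator) -> np.ndarray:
    """Minor allele frequencies: ``Beta(1,2)/2`` truncated below at 0.05."""
    rng = np.random.default_rng(seed)
    q = rng.beta(1.0, 2.0, size=p) / 2.0
    return np.maximum(q, 0.05)


def genotype_transform(w: np.ndarray, q: float | np.ndarray) -> np.ndarray:
    """Quantile-threshold standard-normal draws into minor-allele counts.

    Cut points ``z_{1−2q/3} < z_{1−q/3}`` give genotype probabilities
    ``P(1) = P(2) = q/3``, hence ``E[g] = q``.  ``q`` may be a scalar or a
    per-column vector broadcast over the columns of ``w``.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q > 0.5)):
        raise ValueError("MAF q must lie in (0, 0.5]")
    lo = stats.norm.ppf(1.0 - 2.0 * q / 3.0)
    hi = stats.norm.ppf(1.0 - q / 3.0)
    w = np.asarray(w, dtype=float)
    return (w > lo).astype(np.int8) + (w >= hi).astype(np.int8)


def sigma2_from_h(beta: np.ndarray, corr: np.ndarray, h: float) -> float:
    """Residual variance that yields heritability ``h``:
    ``sigma² = beta'R beta (1−h)/h``."""
    if not 0.0 < h < 1.0:
        raise ValueError("h must lie strictly inside (0,1)")
    g = float(np.asarray(beta) @ np.asarray(corr) @ np.asarray(beta))
    if g <= 0:
        raise ValueError("beta' R beta must be positive to set heritability")
    return g * (1.0 - h) / h


def simulate_phenotype(
    x_std: StandardizedPanel,
    beta: np.ndarray,
    sigma2: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Phenotype ``y = X beta + eps``, returned standardized (mean 0, sd 1,
    divisor n)."""
    rng = np.random.default_rng(seed)
    y = x_std.x @ np.asarray(beta, dtype=float)
    y = y + rng.normal(scale=np.sqrt(sigma2), size=x_std.n)
    y = y - y.mean()
    return y / y.std()


def simulate_until_selected(
    x_std: StandardizedPanel,
    beta: np.ndarray,
    sigma2: float,
    screened_index: int,
    threshold_t: float,
    seed: int | np.random.Generator,
    max_resamples: int = 100_000,
) -> tuple[np.ndarray, int]:
    """Redraw the noise until the screened variant's squared marginal
    coefficient exceeds ``threshold_t``; returns the phenotype and the number
    of draws (for unconditional-power accounting)."""
    rng = np.random.default_rng(seed)
    signal = x_std.x @ np.asarray(beta, dtype=float)
    xj = x_std.x[:, screened_index]
    n = x_std.n
    sd = np.sqrt(sigma2)
    for count in range(1, max_resamples + 1):
        y = signal + rng.normal(scale=sd, size=n)
        y = y - y.mean()
        y = y / y.std()
        beta_om_j = float(xj @ y) / n
        if beta_om_j * beta_om_j > threshold_t:
            return y, count
    rate = 0 if max_resamples == 0 else 1.0 / max_resamples
    raise RuntimeError(
        f"selection event not reached in {max_resamples} noise draws "
        f"(empirical selection rate < {rate:.2g}); the screening threshold "
        "is too strict for this configuration"
    )


def fdp_tdp(
    rejected: np.ndarray, causal_set: tuple[int, ...] | set[int]
) -> tuple[float, float]:
    """False / true discovery proportions of a rejection vector.

    ``FDP = |s \\ s*| / max(|s|, 1)``; ``TDP = |s ∩ s*| / max(|s*|, 1)``.
    """
    s = set(np.flatnonzero(np.asarray(rejected, dtype=bool)).tolist())
    s_star = set(int(i) for i in causal_set)
    fdp = len(s - s_star) / max(len(s), 1)
    tdp = len(s & s_star) / max(len(s_star), 1)
    return fdp, tdp


def _draw_panel(
    n: int, config: SimConfig, mafs: np.ndarray | None, rng: np.random.Generator
) -> StandardizedPanel:
    """One raw covariate draw, standardized; genotype columns that come out
    monomorphic (possible at low MAF) are redrawn."""
    if config.covariate_kind == "gaussian":
        raw = _ar1_chol_sample(n, config.p, config.rho, rng)
        return standardize(raw)
    for _ in range(100):
        w = _ar1_chol_sample(n, config.p, config.rho, rng)
        raw = genotype_transform(w, mafs)
        if np.all(raw.std(axis=0) > 0):
            return standardize(raw.astype(float))
    raise RuntimeError("could not draw a polymorphic genotype panel in 100 tries")


def run_experiment(
    config: SimConfig,
    methods: tuple[str, ...] = ("naive", "corrected_empirical"),
) -> dict[str, SimResult]:
    """Replicate the full pipeline and aggregate FDP/TDP per method.

    Each replicate draws fresh original and reference panels and a phenotype
    (noise-resampled until selection when a screening rule is configured),
    computes marginal summary statistics from the original panel only, then
    runs each method's fine-mapping pipeline against the reference panel and
    applies BH at ``config.q``.  The ``full`` method is the infeasible oracle
    that fine-maps with the original panel itself.

    With selection active, ``psat_mle`` runs the selection-adjusted
    truncated-normal pipeline, while the plain methods ignore selection
    (their conditional FDR is what the adjustment is for).  Reported power is
    conditional on selection; unconditional power divides by the observed
    resampling effort.
    """
    rng_master = np.random.default_rng(config.data_seed)
    mafs = (
        sample_mafs(config.p, config.maf_seed)
        if config.covariate_kind == "genotype"
        else None
    )
    beta = config.beta
    records: dict[str, list[dict]] = {m: [] for m in methods}
    failures = 0

    for rep in range(config.reps):
        rep_rng = np.random.default_rng(rng_master.integers(0, 2**31 - 1))
        try:
            x_o = _draw_panel(config.n_o, config, mafs, rep_rng)
            x_r = _draw_panel(config.n_r, config, mafs, rep_rng)
            if np.any(beta != 0):
                sigma2 = sigma2_from_h(beta, x_o.corr, config.h)
            else:
                sigma2 = 1.0  # global null: pure noise, h is vacuous
            if config.selection is not None:
                t = _screen_t(config)
                y, n_draws = simulate_until_selected(
                    x_o,
                    beta,
                    sigma2,
                    config.selection.screened_index,
                    t,
                    rep_rng,
                    config.selection.max_resamples,
                )
            else:
                t, n_draws = None, 1
                y = simulate_phenotype(x_o, beta, sigma2, rep_rng)
            marg = marginal_coefficients(x_o, y)
            for m in methods:
                res = _run_method(m, marg, x_o, x_r, config, t)
                fdp, tdp = fdp_tdp(res.rejected, config.causal_set)
                records[m].append(
                    {"rep": rep, "fdp": fdp, "tdp": tdp, "n_draws": n_draws}
                )
        except (np.linalg.LinAlgError, RuntimeError, ValueError) as exc:
            failures += 1
            if failures > max(10, config.reps // 10):
                raise RuntimeError(
                    f"too many replicate failures ({failures}); last: {exc}"
                ) from exc
            continue

    out: dict[str, SimResult] = {}
    conditional = config.selection is not None
    for m in methods:
        df = pd.DataFrame.from_records(records[m])
        nrep = len(df)
        fdr, power = df["fdp"].mean(), df["tdp"].mean()
        fdr_se = df["fdp"].std(ddof=1) / np.sqrt(nrep)
        power_se = df["tdp"].std(ddof=1) / np.sqrt(nrep)
        res = SimResult(
            method=m,
            fdr=float(fdr),
            fdr_se=float(fdr_se),
            power=float(power),
            power_se=float(power_se),
            conditional=conditional,
            reps=nrep,
            records=df,
        )
        if conditional:
            # detected-and-selected over all noise draws, not just accepted ones
            upower = df["tdp"] / df["n_draws"]
            res.unconditional_power = float(upower.mean())
            res.unconditional_power_se = float(upower.std(ddof=1) / np.sqrt(nrep))
        out[m] = res
    return out


def _screen_t(config: SimConfig) -> float:
    from .psat import marginal_screen_threshold

    sc = config.selection
    return marginal_screen_threshold(config.n_o, sc.m, sc.alpha)


def _run_method(
    method: str,
    marg: MarginalStats,
    x_o: StandardizedPanel,
    x_r: StandardizedPanel,
    config: SimConfig,
    threshold_t: float | None,
):
    if method == "full":
        return finemap_region(
            marg, x_o, method="full", q=config.q,
            threshold_level=config.threshold_level,
        )
    if method == "psat_mle":
        if threshold_t is None:
            raise ValueError("psat_mle requires an active selection rule")
        sel = make_selection(x_r, config.selection.screened_index, threshold_t)
        return psat_finemap(
            marg, x_r, sel, method="corrected_empirical", q=config.q,
            threshold_level=config.threshold_level,
        )
    return finemap_region(
        marg, x_r, method=method, q=config.q,
        threshold_level=config.threshold_level,
    )
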