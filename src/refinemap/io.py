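"""Reading summary statistics and reference panels; writing result tables.

Summary statistics are a delimited table with columns ``variant_id``,
``beta_marginal`` and ``n`` (one shared original-study sample size).  The
reference panel is either a delimited numeric matrix (rows = individuals,
header = variant ids) or a VCF with hard genotype calls, converted to
minor-allele dosages 0/1/2 with "minor" defined within the panel.
"""

from __future__ import annotations

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import MarginalStats, StandardizedPanel, standardize
from .inference import RegionResult

__all__ = ["read_summary_stats", "read_panel", "write_results"]

REQUIRED_COLUMNS = ("variant_id", "beta_marginal", "n")


def read_summary_stats(path: str | Path, dialect: str | None = None) -> MarginalStats:
    """Read marginal coefficients and the original-study sample size.

    ``dialect`` forces the delimiter ("tsv" or "csv"); by default it is
    sniffed from the extension/content.
    """
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(dialect) if dialect else None
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate variant_id {dup.iloc[0]!r}")
    beta = pd.to_numeric(df["beta_marginal"], errors="coerce")
    if beta.isna().any():
        line = int(beta.index[beta.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: non-numeric beta_marginal at line {line}")
    n_vals = pd.unique(df["n"])
    if len(n_vals) != 1:
        raise ValueError(
            f"{path}: heterogeneous sample sizes {sorted(n_vals)}; a single "
            "n per file is required"
        )
    return MarginalStats(
        beta_om=beta.to_numpy(dtype=float),
        n_o=int(n_vals[0]),
        variant_ids=df["variant_id"].astype(str).tolist(),
    )


def read_panel(
    path: str | Path,
    format: str = "matrix",
    variant_ids: list[str] | None = None,
    missing: str = "impute",
) -> StandardizedPanel:
    """Load a reference panel and standardize its columns.

    ``format="matrix"``: delimited numeric matrix with a header of variant
    ids.  ``format="vcf"``: biallelic hard calls converted to minor-allele
    dosage (allele orientation chosen so the counted allele is the rarer one
    *within the panel*).  ``variant_ids`` subsets and re-orders columns;
    absent ids are an error.  Missing genotypes are mean-imputed before
    standardization (``missing="error"`` raises instead).
    """
    path = Path(path)
    if format == "matrix":
        df = pd.read_csv(path, sep=None, engine="python")
        ids = [str(c) for c in df.columns]
        raw = df.to_numpy(dtype=float)
    elif format == "vcf":
        ids, raw = _read_vcf_dosages(path)
    else:
        raise ValueError(f"unknown panel format {format!r}")

    if variant_ids is not None:
        index = {v: i for i, v in enumerate(ids)}
        absent = [v for v in variant_ids if v not in index]
        if absent:
            raise ValueError(f"{path}: variants not found in panel: {absent}")
        cols = [index[v] for v in variant_ids]
        raw = raw[:, cols]
        ids = list(variant_ids)

    if np.isnan(raw).any():
        if missing == "error":
            raise ValueError(f"{path}: panel contains missing genotypes")
        col_mean = np.nanmean(raw, axis=0)
        nan_pos = np.isnan(raw)
        raw[nan_pos] = np.take(col_mean, np.nonzero(nan_pos)[1])
        warnings.warn(
            f"{path}: mean-imputed {int(nan_pos.sum())} missing genotype(s)",
            stacklevel=2,
        )
    return standardize(raw, variant_ids=ids)


def _read_vcf_dosages(path: Path) -> tuple[list[str], np.ndarray]:
    from cyvcf2 import VCF

    ids: list[str] = []
    cols: list[np.ndarray] = []
    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 = alt count, 3 = missing
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic site {rec.ID or rec.POS}", stacklevel=2
            )
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (cyvcf2 with gts012), 3=missing
        gts = np.asarray(rec.gt_types, dtype=float)
        alt_dosage = gts.copy()
        alt_dosage[gts == 2] = 2.0
        alt_dosage[gts == 3] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            alt_freq = np.nanmean(alt_dosage) / 2.0
        dosage = alt_dosage if alt_freq <= 0.5 else 2.0 - alt_dosage
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        cols.append(dosage)
    if not cols:
        raise ValueError(f"{path}: no usable biallelic sites")
    print(
        "note: genotypes oriented to the minor allele within the panel; "
        "summary-statistic effect alleles must match this orientation",
        file=sys.stderr,
    )
    return ids, np.column_stack(cols)


def write_results(result: RegionResult, path: str | Path) -> None:
    """Write a region's per-variant results as a tab-delimited table.

    Numeric columns use ``repr`` round-trip precision so a read-back is
    bit-exact.
    """
    est = result.estimate
    p = est.p
    ids = result.variant_ids or [str(i + 1) for i in range(p)]
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "beta_mc": est.beta_mc,
            "se": np.sqrt(np.diag(est.sigma_mc)),
            "z": result.z_scores,
            "p": result.p_values,
            "p_rank": np.argsort(np.argsort(result.p_values)) + 1,
            "rejected": result.rejected,
            "method": est.method,
            "sigma2_hat": est.sigma2_hat,
            "fdr_level": result.fdr_level,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
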