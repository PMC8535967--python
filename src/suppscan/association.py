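"""Per-SNP additive-model linear association under configurable adjustment sets.

Each SNP is tested by OLS of the (log-transformed) outcome on minor-allele
dosage plus covariates; the "base" adjustment set is age + sex + BMI +
smoking, and "base+mediator" additionally adjusts for the (log) mediator.
Comparing the two sets exposes suppression: a mediator acting opposite in
sign to the direct effect attenuates the marginal association, so a SNP can
be null in the base scan yet highly significant once the mediator is held
fixed. Missing data are handled by list-wise deletion over all model
variables, per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from suppscan.containers import GenotypeMatrix, PhenotypeTable

BASE_COVARIATES = ("age", "sex", "bmi", "smoking")
GENOME_WIDE_THRESHOLD = 5e-8

ADJUSTMENT_SETS = {
    "base": BASE_COVARIATES,
    "base+mediator": BASE_COVARIATES + ("mediator",),
}


@dataclass
class RegressionFit:
    """OLS estimates with classical (homoscedastic) standard errors."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    n_used: int


@dataclass
class AssociationRecord:
    snp_id: str
    chrom: str
    pos: int
    minor_allele: str
    adjustment: str
    beta: float
    se: float
    p: float
    n_used: int
    testable: bool = True


class RankDeficientError(ValueError):
    pass


def ols_fit(response: np.ndarray, design: pd.DataFrame) -> RegressionFit:
    """Least-squares fit with t-distribution p-values.

    `design` must already contain its intercept column. Rank-deficient
    designs raise `RankDeficientError` naming the collinear columns.
    """
    y = np.asarray(response, dtype=float)
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if len(y) != n:
        raise ValueError("response and design row counts differ")
    if n <= k:
        raise ValueError(f"insufficient rows after deletion: n={n} <= {k} predictors")
    # name collinear columns via pivoted QR before delegating the fit
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, k) * np.finfo(float).eps if diag.size else 0.0
    if (diag <= tol).any():
        bad = [design.columns[piv[i]] for i in range(k) if diag[i] <= tol]
        raise RankDeficientError(f"design is rank deficient; collinear columns: {bad}")

    res = sm.OLS(y, X).fit()
    idx = list(design.columns)
    return RegressionFit(
        params=pd.Series(res.params, index=idx),
        se=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        df_resid=int(res.df_resid),
        n_used=n,
    )


def transform_phenotype(values: np.ndarray, transform: str = "log") -> np.ndarray:
    """Element-wise phenotype transform ('log' = natural log, or 'identity')."""
    v = np.asarray(values, dtype=float)
    if transform == "identity":
        return v.copy()
    if transform != "log":
        raise ValueError(f"unknown transform {transform!r}; use 'log' or 'identity'")
    bad = np.flatnonzero(~(v > 0) & np.isfinite(v))
    if bad.size:
        raise ValueError(
            f"log transform requires strictly positive values; offending rows: {bad.tolist()[:10]}"
        )
    return np.log(v)


def _model_frame(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable, snp_id: str,
                 adjustment: str, outcome: str, mediator: str,
                 covariates: Sequence[str], log_outcome: bool,
                 log_mediator: bool) -> tuple[np.ndarray, pd.DataFrame]:
    """List-wise-deleted response and design for one SNP."""
    if adjustment not in ADJUSTMENT_SETS:
        raise ValueError(f"unknown adjustment set {adjustment!r}")
    pheno = phenotypes.aligned_to(genotypes.sample_ids)
    cols = {"genotype": genotypes.dosage(snp_id), "__outcome__": pheno[outcome].to_numpy(float)}
    for c in covariates:
        cols[c] = pheno[c].to_numpy(float)
    if "mediator" in ADJUSTMENT_SETS[adjustment]:
        cols["mediator"] = pheno[mediator].to_numpy(float)
    frame = pd.DataFrame(cols)
    frame = frame.dropna()
    y = frame.pop("__outcome__").to_numpy()
    if log_outcome:
        y = transform_phenotype(y, "log")
    if "mediator" in frame.columns and log_mediator:
        frame["mediator"] = transform_phenotype(frame["mediator"].to_numpy(), "log")
    design = frame[["genotype", *[c for c in frame.columns if c != "genotype"]]].copy()
    design.insert(0, "intercept", 1.0)
    return y, design


def snp_association(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable, snp_id: str,
                    adjustment: str = "base", outcome: str = "hdl_c",
                    mediator: str = "adiponectin",
                    covariates: Sequence[str] = BASE_COVARIATES,
                    log_outcome: bool = True, log_mediator: bool = True) -> AssociationRecord:
    """Additive association of one SNP with the outcome under one adjustment set.

    A SNP monomorphic after list-wise deletion yields an untestable record
    (beta/se/p = nan, testable=False) rather than an exception.
    """
    j = genotypes.snp_index(snp_id)
    meta = genotypes.snp_meta.iloc[j]
    y, design = _model_frame(genotypes, phenotypes, snp_id, adjustment, outcome,
                             mediator, covariates, log_outcome, log_mediator)
    record = AssociationRecord(
        snp_id=snp_id, chrom=str(meta["chrom"]), pos=int(meta["pos"]),
        minor_allele=str(meta["minor_allele"]), adjustment=adjustment,
        beta=np.nan, se=np.nan, p=np.nan, n_used=len(y), testable=False,
    )
    if len(y) == 0 or design["genotype"].nunique() < 2:
        return record
    fit = ols_fit(y, design)
    record.beta = float(fit.params["genotype"])
    record.se = float(fit.se["genotype"])
    record.p = float(fit.pvalues["genotype"])
    record.n_used = fit.n_used
    record.testable = True
    return record


def genome_scan(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                adjustments: Sequence[str] = ("base", "base+mediator"),
                threshold: float = GENOME_WIDE_THRESHOLD, *,
                outcome: str = "hdl_c", mediator: str = "adiponectin",
                covariates: Sequence[str] = BASE_COVARIATES,
                log_outcome: bool = True, log_mediator: bool = True) -> pd.DataFrame:
    """Scan every SNP under every adjustment set.

    Returns a table with one row per SNP x adjustment, sorted by p within
    adjustment, with genome-wide significance flags and a Manhattan-ready
    -log10(p) column.
    """
    rows = []
    for adj in adjustments:
        for snp_id in genotypes.snp_meta["snp_id"]:
            rec = snp_association(genotypes, phenotypes, snp_id, adjustment=adj,
                                  outcome=outcome, mediator=mediator,
                                  covariates=covariates, log_outcome=log_outcome,
                                  log_mediator=log_mediator)
            rows.append(vars(rec))
    table = pd.DataFrame(rows)
    table["significant"] = table["p"] < threshold
    with np.errstate(divide="ignore"):
        table["neg_log10_p"] = -np.log10(table["p"])
    table = (table.sort_values(["adjustment", "p"], na_position="last")
             .reset_index(drop=True))
    return table


def plot_manhattan(scan_table: pd.DataFrame, path: str | Path, adjustment: str = "base",
                   threshold: float = GENOME_WIDE_THRESHOLD) -> None:
    """Manhattan plot of one adjustment set of a `genome_scan` table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = scan_table[scan_table["adjustment"] == adjustment].dropna(subset=["p"])
    sub = sub.sort_values(["chrom", "pos"])
    fig, ax = plt.subplots(figsize=(9, 3))
    offset, ticks = 0, {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        x = offset + np.arange(len(grp))
        ax.scatter(x, grp["neg_log10_p"], s=4)
        ticks[chrom] = offset + len(grp) / 2
        offset += len(grp)
    ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    ax.set_xticks(list(ticks.values()), list(ticks.keys()), fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"adjustment: {adjustment}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
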