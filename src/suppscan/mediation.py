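"""Four-criterion mediation analysis with Sobel test and suppression classification.

For a SNP G, mediator M and outcome Y (both log-transformed by default),
three OLS regressions are fit on the identical list-wise-deleted sample:

    (i)   M ~ G + covariates            -> alpha   (criterion 1)
    (ii)  Y ~ M + G + covariates        -> beta    (criterion 2) and
                                           gamma_prime (direct effect)
    (iii) Y ~ G + covariates            -> total effect (criterion 3)

The indirect (mediation) effect is alpha*beta, tested by the Sobel
normal approximation (criterion 4). In nested linear models the total
effect decomposes exactly as alpha*beta + gamma_prime. A *suppression*
effect is declared when the indirect and direct effects oppose in sign and
the direct effect exceeds the total in magnitude: the mediator masks the
genotype-outcome association, which surfaces only after adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from suppscan.association import BASE_COVARIATES, ols_fit, transform_phenotype
from suppscan.containers import GenotypeMatrix, PhenotypeTable

CLASSIFICATIONS = ("none", "full_mediation", "partial_mediation", "suppression")


@dataclass
class MediationResult:
    """Path decomposition, criteria flags and effect classification for one SNP."""

    snp_id: str
    alpha: float
    alpha_se: float
    alpha_p: float
    beta: float
    beta_se: float
    beta_p: float
    gamma_prime: float
    gamma_prime_se: float
    gamma_prime_p: float
    indirect: float          # alpha * beta
    total: float             # genotype coefficient of regression (iii)
    total_se: float
    total_p: float
    total_sum: float         # alpha*beta + gamma_prime (the decomposition form)
    sobel_z: float
    sobel_p: float
    criteria_met: tuple[bool, bool, bool, bool]
    classification: str
    n_used: int
    testable: bool = True


def sobel_test(a: float, se_a: float, b: float, se_b: float,
               aroian: bool = False) -> tuple[float, float]:
    """Sobel test of the indirect effect a*b.

    First-order delta-method variance a^2 se_b^2 + b^2 se_a^2 by default;
    `aroian=True` adds the se_a^2 se_b^2 cross term. Returns (z, two-sided p).
    a = b = 0 is a defined null: z = 0, p = 1.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    var = a * a * se_b * se_b + b * b * se_a * se_a
    if aroian:
        var += se_a * se_a * se_b * se_b
    if var == 0.0:
        return 0.0, 1.0
    z = a * b / math.sqrt(var)
    return z, float(2.0 * norm.sf(abs(z)))


def classify_effect(criteria_met: Sequence[bool], direct: float, direct_p: float,
                    indirect: float, total: float,
                    significance: float = 0.05) -> str:
    """Classify a mediation decomposition.

    suppression: criteria 1, 2, 4 hold, |direct| > |total| and the indirect
    effect opposes the direct effect in sign (criterion 3 typically fails —
    the total effect is abolished). full mediation: all four criteria and a
    non-significant direct effect. partial mediation: all four criteria,
    significant direct effect, same-sign indirect effect. Otherwise none.
    """
    c1, c2, c3, c4 = (bool(c) for c in criteria_met)
    opposing = indirect * direct < 0
    if c1 and c2 and c4 and abs(direct) > abs(total) and opposing:
        return "suppression"
    if c1 and c2 and c3 and c4:
        if direct_p >= significance:
            return "full_mediation"
        if indirect * direct > 0:
            return "partial_mediation"
    return "none"


def mediation_analyze(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable, snp_id: str,
                      covariates: Sequence[str] = BASE_COVARIATES,
                      significance: float = 0.05, outcome: str = "hdl_c",
                      mediator: str = "adiponectin", log_outcome: bool = True,
                      log_mediator: bool = True, aroian: bool = False) -> MediationResult:
    """Run the three-regression mediation analysis for one SNP.

    All three regressions share the identical list-wise-deleted sample
    (rows missing any of outcome, mediator, genotype or a covariate are
    dropped once, up front), which makes total = alpha*beta + gamma_prime
    an algebraic identity up to floating-point error.
    """
    pheno = phenotypes.aligned_to(genotypes.sample_ids)
    frame = pd.DataFrame({
        "genotype": genotypes.dosage(snp_id),
        "outcome": pheno[outcome].to_numpy(float),
        "mediator": pheno[mediator].to_numpy(float),
        **{c: pheno[c].to_numpy(float) for c in covariates},
    }).dropna()

    nan_result = MediationResult(
        snp_id=snp_id, alpha=np.nan, alpha_se=np.nan, alpha_p=np.nan,
        beta=np.nan, beta_se=np.nan, beta_p=np.nan,
        gamma_prime=np.nan, gamma_prime_se=np.nan, gamma_prime_p=np.nan,
        indirect=np.nan, total=np.nan, total_se=np.nan, total_p=np.nan,
        total_sum=np.nan, sobel_z=np.nan, sobel_p=np.nan,
        criteria_met=(False, False, False, False), classification="none",
        n_used=len(frame), testable=False,
    )
    if len(frame) == 0 or frame["genotype"].nunique() < 2:
        return nan_result

    y = transform_phenotype(frame["outcome"].to_numpy(), "log" if log_outcome else "identity")
    m = transform_phenotype(frame["mediator"].to_numpy(), "log" if log_mediator else "identity")

    base = frame[["genotype", *covariates]].copy()
    base.insert(0, "intercept", 1.0)
    fit_med = ols_fit(m, base)                       # (i)  alpha
    with_med = base.copy()
    with_med.insert(2, "mediator", m)
    fit_full = ols_fit(y, with_med)                  # (ii) beta, gamma_prime
    fit_total = ols_fit(y, base)                     # (iii) total effect

    alpha, alpha_se = fit_med.params["genotype"], fit_med.se["genotype"]
    beta, beta_se = fit_full.params["mediator"], fit_full.se["mediator"]
    gamma, gamma_se = fit_full.params["genotype"], fit_full.se["genotype"]
    total, total_se = fit_total.params["genotype"], fit_total.se["genotype"]
    indirect = alpha * beta
    sobel_z, sobel_p = sobel_test(alpha, alpha_se, beta, beta_se, aroian=aroian)

    criteria = (
        bool(fit_med.pvalues["genotype"] < significance),    # 1: G -> M
        bool(fit_full.pvalues["mediator"] < significance),   # 2: M -> Y | G
        bool(fit_total.pvalues["genotype"] < significance),  # 3: total effect
        bool(sobel_p < significance),                        # 4: Sobel
    )
    classification = classify_effect(criteria, gamma, fit_full.pvalues["genotype"],
                                     indirect, total, significance)
    return MediationResult(
        snp_id=snp_id,
        alpha=float(alpha), alpha_se=float(alpha_se),
        alpha_p=float(fit_med.pvalues["genotype"]),
        beta=float(beta), beta_se=float(beta_se),
        beta_p=float(fit_full.pvalues["mediator"]),
        gamma_prime=float(gamma), gamma_prime_se=float(gamma_se),
        gamma_prime_p=float(fit_full.pvalues["genotype"]),
        indirect=float(indirect),
        total=float(total), total_se=float(total_se),
        total_p=float(fit_total.pvalues["genotype"]),
        total_sum=float(indirect + gamma),
        sobel_z=float(sobel_z), sobel_p=float(sobel_p),
        criteria_met=criteria, classification=classification,
        n_used=fit_med.n_used,
    )


def mediation_scan(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                   snp_ids: Sequence[str], **kwargs) -> pd.DataFrame:
    """`mediation_analyze` over a candidate list, sorted by |Sobel z| descending."""
    rows = [vars(mediation_analyze(genotypes, phenotypes, s, **kwargs)) for s in snp_ids]
    table = pd.DataFrame(rows, columns=list(MediationResult.__dataclass_fields__))
    if len(table):
        table = (table.reindex(table["sobel_z"].abs()
                               .sort_values(ascending=False, na_position="last").index)
                 .reset_index(drop=True))
    return table
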