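"""Synthetic cohort generator.

Emulates the statistical structure of a Taiwanese biobank adiponectin /
HDL-C study: ~2,199 unrelated adults with sex-stratified age, BMI, smoking,
adiponectin and HDL-C distributions; a focal SNP pair in strong LD
(MAF 0.32 / 0.22, minor alleles coupled on the risk haplotype); a panel of
phenotype-independent null SNPs under Hardy-Weinberg equilibrium; and a
three-variable mediation path

    log(mediator)  = alpha * G + covariates + noise
    log(outcome)   = beta * log(mediator) + gamma_prime * G + covariates + noise

with ``alpha * beta`` (indirect) and ``gamma_prime`` (direct) of opposing
sign, so the marginal genotype-outcome association is suppressed toward
zero while the mediator-adjusted association is strong.

All phenotype means/SDs are specified on the raw measurement scale per sex
and converted internally to natural-log-normal location/scale by moment
matching; the per-sex raw means of simulated phenotypes are therefore
unbiased for the configured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from suppscan.containers import GenotypeMatrix, PhenotypeTable

# Per-sex raw-scale defaults: {variable: {sex: (mean, sd)}}, sex 0=male 1=female.
DEFAULT_LOCATION_SCALE: dict[str, dict[int, tuple[float, float]]] = {
    "age": {0: (48.6, 11.1), 1: (48.2, 10.7)},
    "bmi": {0: (25.1, 3.4), 1: (23.4, 3.5)},
    "adiponectin": {0: (2.88, 1.45), 1: (4.01, 1.97)},
    "hdl_c": {0: (49.7, 11.4), 1: (59.4, 13.3)},
}

DEFAULT_SMOKING_RATE = {0: 0.334, 1: 0.055}

# Covariate coefficients on the natural-log phenotype scales. Sex acts
# through per-sex intercepts, not a slope, so these cover age/bmi/smoking.
DEFAULT_COVARIATE_EFFECTS = {
    "mediator": {"age": 0.004, "bmi": -0.03, "smoking": -0.05},
    "outcome": {"age": 0.001, "bmi": -0.01, "smoking": -0.04},
}

FOCAL_SNP_IDS = ("rs4783244", "rs12051272")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given raw mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal moment matching needs mean > 0 and sd > 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    The path coefficients ``alpha`` (genotype -> log mediator per minor-allele
    copy), ``beta`` (log mediator -> log outcome) and ``gamma_prime``
    (genotype -> log outcome, direct) default to the suppression structure
    of the motivating study: indirect effect alpha*beta ~ -0.017 opposing a
    direct effect +0.015, so the total effect is ~ -0.002 and the marginal
    scan is null while the mediator-adjusted scan is genome-wide notable.
    """

    n_samples: int = 2199
    maf_focal: tuple[float, float] = (0.32, 0.22)
    ld_dprime: float = 0.9
    n_null_snps: int = 300
    maf_range_null: tuple[float, float] = (0.05, 0.5)
    alpha: float = -0.079
    beta: float = 0.21
    gamma_prime: float = 0.015
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()}
    )
    sex_fraction: float = 1213 / 2199  # fraction female
    phenotype_location_scale: dict[str, dict[int, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LOCATION_SCALE.items()}
    )
    smoking_rate: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SMOKING_RATE))
    log_transform_mediator: bool = True
    noise_sd_outcome: float = 0.09
    noise_sd_mediator: float | None = None  # None -> derived from location/scale
    missing_rate_genotype: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for f in (*self.maf_focal, *self.maf_range_null):
            if not 0.0 < f < 1.0:
                raise ValueError(f"allele frequency {f} outside (0, 1)")
        if not 0.0 <= self.ld_dprime <= 1.0:
            raise ValueError("ld_dprime must lie in [0, 1]")
        if not 0.0 <= self.missing_rate_genotype < 1.0:
            raise ValueError("missing_rate_genotype must lie in [0, 1)")
        if not 0.0 <= self.sex_fraction <= 1.0:
            raise ValueError("sex_fraction must lie in [0, 1]")
        if self.noise_sd_outcome <= 0:
            raise ValueError("noise_sd_outcome must be > 0")
        if self.noise_sd_mediator is not None and self.noise_sd_mediator <= 0:
            raise ValueError("noise_sd_mediator must be > 0")
        for var, per_sex in self.phenotype_location_scale.items():
            for sex, (_, sd) in per_sex.items():
                if sd <= 0:
                    raise ValueError(f"SD for {var} (sex {sex}) must be > 0")


@dataclass
class SyntheticCohort:
    """Generated genotypes + phenotypes plus the generative truth record."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict[str, Any]


def haplotype_freqs_from_d(maf1: float, maf2: float, d: float) -> np.ndarray:
    """Four-haplotype frequencies from allele frequencies and raw D.

    Order: (major,major), (major,minor), (minor,major), (minor,minor);
    D is the coupling disequilibrium of the two minor alleles. Raises if the
    requested D falls outside the Frechet bounds (a frequency would go
    negative).
    """
    p, q = maf1, maf2
    freqs = np.array([
        (1 - p) * (1 - q) + d,
        (1 - p) * q - d,
        p * (1 - q) - d,
        p * q + d,
    ])
    if (freqs < -1e-12).any():
        raise ValueError(
            f"infeasible (maf, D) combination: maf=({p}, {q}), D={d} implies "
            f"haplotype frequencies {np.round(freqs, 6).tolist()}; D must lie in "
            f"[{-min(p * q, (1 - p) * (1 - q)):.6f}, {min(p * (1 - q), (1 - p) * q):.6f}]"
        )
    return np.clip(freqs, 0.0, None)


def haplotype_frequencies(maf_pair: tuple[float, float], ld_dprime: float) -> np.ndarray:
    """Haplotype frequencies implied by (MAF pair, normalized D') with the
    minor alleles in coupling phase."""
    p, q = maf_pair
    d_max = min(p * (1 - q), (1 - p) * q)
    return haplotype_freqs_from_d(p, q, ld_dprime * d_max)


def simulate_focal_pair(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw two haplotypes per sample for the focal SNP pair.

    Returns an (n_samples, 2) integer array of haplotype codes in {0,1,2,3}
    where code = 2*a1 + a2 and a_i = 1 marks the minor allele at site i.
    Dosages follow by counting minor alleles per site (random mating: the
    two haplotypes are independent draws).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    freqs = haplotype_frequencies(config.maf_focal, config.ld_dprime)
    return rng.choice(4, size=(config.n_samples, 2), p=freqs / freqs.sum())


def focal_dosages(haplotype_pairs: np.ndarray) -> np.ndarray:
    """(n, 2) minor-allele dosages from (n, 2) haplotype-code pairs."""
    a1 = haplotype_pairs // 2
    a2 = haplotype_pairs % 2
    return np.stack([a1.sum(axis=1), a2.sum(axis=1)], axis=1).astype(float)


def _mediator_noise_sd(config: SimulationConfig, sex: int) -> float:
    """Residual SD of the (log) mediator for one sex.

    Derived so the total per-sex variance matches the configured raw
    location/scale: total log-variance minus the variance explained by
    genotype and covariates.
    """
    if config.noise_sd_mediator is not None:
        return config.noise_sd_mediator
    mean, sd = config.phenotype_location_scale["adiponectin"][sex]
    if config.log_transform_mediator:
        _, total_sd = _lognormal_params(mean, sd)
    else:
        total_sd = sd
    eff = config.covariate_effects["mediator"]
    p1 = config.maf_focal[0]
    explained = config.alpha ** 2 * 2 * p1 * (1 - p1)
    explained += eff.get("age", 0.0) ** 2 * config.phenotype_location_scale["age"][sex][1] ** 2
    explained += eff.get("bmi", 0.0) ** 2 * config.phenotype_location_scale["bmi"][sex][1] ** 2
    r = config.smoking_rate[sex]
    explained += eff.get("smoking", 0.0) ** 2 * r * (1 - r)
    resid_var = total_sd ** 2 - explained
    if resid_var <= 0:
        raise ValueError(
            "configured path/covariate effects explain more variance than the "
            f"total mediator variance for sex {sex}; reduce effects or raise the SD"
        )
    return math.sqrt(resid_var)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a fully reproducible synthetic cohort.

    Mediator and outcome are generated on the natural-log scale then
    exponentiated; null SNPs are binomial under HWE, independent of all
    phenotypes; genotype missingness is completely at random.
    """
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_cov, rng_hap, rng_med, rng_out, rng_null, rng_miss = (
        np.random.default_rng(s) for s in streams
    )
    n = config.n_samples
    loc = config.phenotype_location_scale

    # --- covariates -------------------------------------------------------
    sex = (rng_cov.random(n) < config.sex_fraction).astype(int)  # 1 = female
    age = np.empty(n)
    bmi = np.empty(n)
    smoking = np.empty(n, dtype=int)
    for s in (0, 1):
        m = sex == s
        age[m] = rng_cov.normal(*loc["age"][s], size=m.sum())
        bmi[m] = rng_cov.normal(*loc["bmi"][s], size=m.sum())
        smoking[m] = (rng_cov.random(m.sum()) < config.smoking_rate[s]).astype(int)

    # --- focal genotypes --------------------------------------------------
    hap_pairs = simulate_focal_pair(config, rng_hap)
    focal = focal_dosages(hap_pairs)
    g = focal[:, 0]  # causal site

    # --- mediator ---------------------------------------------------------
    eff_m = config.covariate_effects["mediator"]
    p1 = config.maf_focal[0]
    med_lin = config.alpha * (g - 2 * p1)
    noise_sd_m = {}
    log_med = np.empty(n)
    for s in (0, 1):
        m = sex == s
        mean, sd = loc["adiponectin"][s]
        mu = _lognormal_params(mean, sd)[0] if config.log_transform_mediator else mean
        noise_sd_m[s] = _mediator_noise_sd(config, s)
        log_med[m] = (
            mu
            + med_lin[m]
            + eff_m.get("age", 0.0) * (age[m] - loc["age"][s][0])
            + eff_m.get("bmi", 0.0) * (bmi[m] - loc["bmi"][s][0])
            + eff_m.get("smoking", 0.0) * (smoking[m] - config.smoking_rate[s])
            + rng_med.normal(0.0, noise_sd_m[s], size=m.sum())
        )
    adiponectin = np.exp(log_med) if config.log_transform_mediator else log_med

    # --- outcome ----------------------------------------------------------
    eff_y = config.covariate_effects["outcome"]
    log_out = np.empty(n)
    for s in (0, 1):
        m = sex == s
        mean, sd = loc["hdl_c"][s]
        mu_med = _lognormal_params(*loc["adiponectin"][s])[0] if config.log_transform_mediator \
            else loc["adiponectin"][s][0]
        # intercept set so the raw per-sex mean matches the configured mean
        # under the variance the model actually generates
        mediator_term = config.beta * (log_med[m] - mu_med)
        lin = (
            config.gamma_prime * (g[m] - 2 * p1)
            + mediator_term
            + eff_y.get("age", 0.0) * (age[m] - loc["age"][s][0])
            + eff_y.get("bmi", 0.0) * (bmi[m] - loc["bmi"][s][0])
            + eff_y.get("smoking", 0.0) * (smoking[m] - config.smoking_rate[s])
        )
        noise = rng_out.normal(0.0, config.noise_sd_outcome, size=m.sum())
        total_var = np.var(lin) + config.noise_sd_outcome ** 2
        mu_y = math.log(mean) - total_var / 2.0
        log_out[m] = mu_y + lin + noise
    hdl_c = np.exp(log_out)

    # --- null SNP panel ---------------------------------------------------
    null_mafs = rng_null.uniform(*config.maf_range_null, size=config.n_null_snps)
    null_dos = rng_null.binomial(2, null_mafs, size=(n, config.n_null_snps)).astype(float)

    dosages = np.hstack([focal, null_dos])
    snp_meta = pd.DataFrame({
        "snp_id": list(FOCAL_SNP_IDS) + [f"null{i:04d}" for i in range(config.n_null_snps)],
        "chrom": ["16", "16"] + [str(1 + i % 22) for i in range(config.n_null_snps)],
        "pos": [82_662_268, 82_665_268] + [1_000_000 + 1_000 * i for i in range(config.n_null_snps)],
        "minor_allele": ["T"] * 2 + ["A"] * config.n_null_snps,
        "major_allele": ["G"] * 2 + ["C"] * config.n_null_snps,
    })

    if config.missing_rate_genotype > 0:
        mask = rng_miss.random(dosages.shape) < config.missing_rate_genotype
        dosages[mask] = np.nan

    sample_ids = [f"S{i:05d}" for i in range(n)]
    genotypes = GenotypeMatrix(sample_ids=sample_ids, snp_meta=snp_meta, dosages=dosages)
    phenotypes = PhenotypeTable(pd.DataFrame({
        "sample_id": sample_ids,
        "sex": sex,
        "age": age,
        "bmi": bmi,
        "smoking": smoking,
        "adiponectin": adiponectin,
        "hdl_c": hdl_c,
    }))

    truth = {
        "config": asdict(config),
        "noise_sd_mediator_by_sex": {str(s): noise_sd_m[s] for s in (0, 1)},
        "noise_sd_outcome": config.noise_sd_outcome,
        "haplotype_frequencies": haplotype_frequencies(config.maf_focal, config.ld_dprime).tolist(),
        "per_snp_effects": {
            FOCAL_SNP_IDS[0]: {"alpha": config.alpha, "gamma_prime": config.gamma_prime},
            FOCAL_SNP_IDS[1]: {"alpha": 0.0, "gamma_prime": 0.0,
                               "note": "associated only through LD with the causal site"},
            "null*": {"alpha": 0.0, "gamma_prime": 0.0},
        },
    }
    return SyntheticCohort(genotypes=genotypes, phenotypes=phenotypes, truth=truth)
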