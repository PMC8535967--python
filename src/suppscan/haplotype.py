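"""Two-locus haplotype frequency estimation (EM) and LD statistics.

Phase is ambiguous only for double heterozygotes; the EM algorithm iterates
between splitting those samples across the two compatible phases (E-step)
and recounting haplotype frequencies (M-step), starting from linkage
equilibrium. From the converged frequencies it reports D, |D'| and r^2.
Posterior (fractional) haplotype dosages feed the haplotype association
regression, with the most frequent haplotype as reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from suppscan.association import BASE_COVARIATES, ols_fit, transform_phenotype
from suppscan.containers import GenotypeMatrix, PhenotypeTable

# haplotype order: (major,major), (major,minor), (minor,major), (minor,minor)
HAPLOTYPE_LABELS = ("MM", "Mm", "mM", "mm")


@dataclass
class HaplotypeEstimate:
    """EM haplotype frequencies over two biallelic sites, plus LD summary."""

    frequencies: np.ndarray          # length 4, order HAPLOTYPE_LABELS
    d: float                         # raw coupling disequilibrium of minor alleles
    d_prime: float                   # |D| / Dmax, in [0, 1]
    r_squared: float
    log_likelihood: float
    log_likelihood_path: np.ndarray  # per-iteration, non-decreasing
    iterations: int
    converged: bool
    degenerate: bool = False         # monomorphic site: LD undefined, r^2 = 0


def _pair_log_likelihood(freqs: np.ndarray, counts: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype-pair count table.

    `counts[g1, g2]` holds samples with dosages (g1, g2). Genotype-pair
    probabilities come from random union of haplotypes.
    """
    f = np.asarray(freqs, float)
    probs = np.zeros((3, 3))
    for h1 in range(4):
        for h2 in range(4):
            g1 = h1 // 2 + h2 // 2
            g2 = h1 % 2 + h2 % 2
            probs[g1, g2] += f[h1] * f[h2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = counts * np.log(probs)
    return float(np.nansum(np.where(counts > 0, ll, 0.0)))


def ld_statistics(freqs: np.ndarray) -> tuple[float, float, float]:
    """(D, |D'|, r^2) from four haplotype frequencies."""
    f = np.asarray(freqs, float)
    p = f[2] + f[3]  # minor-allele freq at site 1
    q = f[1] + f[3]  # minor-allele freq at site 2
    d = f[3] - p * q
    denom = p * (1 - p) * q * (1 - q)
    if denom <= 0:
        return float(d), 0.0, 0.0
    d_max = min(p * (1 - q), (1 - p) * q) if d >= 0 else min(p * q, (1 - p) * (1 - q))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    return float(d), float(min(d_prime, 1.0)), float(d * d / denom)


def em_haplotype_freqs(dosage1: np.ndarray, dosage2: np.ndarray,
                       tol: float = 1e-10, max_iter: int = 1000) -> HaplotypeEstimate:
    """EM estimate of two-locus haplotype frequencies from unphased dosages.

    Samples missing either dosage are dropped. Convergence: max absolute
    frequency change < `tol`, or `max_iter` iterations. The deterministic
    start is the linkage-equilibrium product of allele frequencies.
    """
    d1 = np.asarray(dosage1, float)
    d2 = np.asarray(dosage2, float)
    if d1.shape != d2.shape:
        raise ValueError("dosage vectors must cover the same samples")
    keep = np.isfinite(d1) & np.isfinite(d2)
    d1, d2 = d1[keep], d2[keep]
    if d1.size == 0:
        raise ValueError("no samples with both sites genotyped")

    counts = np.zeros((3, 3))
    for g1, g2 in zip(d1.astype(int), d2.astype(int)):
        counts[g1, g2] += 1
    n = counts.sum()
    p = (counts * np.arange(3)[:, None]).sum() / (2 * n)
    q = (counts * np.arange(3)[None, :]).sum() / (2 * n)

    if p in (0.0, 1.0) or q in (0.0, 1.0):
        freqs = np.array([(1 - p) * (1 - q), (1 - p) * q, p * (1 - q), p * q])
        ll = _pair_log_likelihood(freqs, counts)
        return HaplotypeEstimate(frequencies=freqs, d=0.0, d_prime=0.0, r_squared=0.0,
                                 log_likelihood=ll, log_likelihood_path=np.array([ll]),
                                 iterations=0, converged=True, degenerate=True)

    # unambiguous haplotype counts contributed by each genotype pair
    fixed = np.zeros(4)
    for g1 in range(3):
        for g2 in range(3):
            c = counts[g1, g2]
            if c == 0 or (g1 == 1 and g2 == 1):
                continue
            # each sample contributes two haplotypes with known phase
            for (a1, a2), w in _phase_contributions(g1, g2):
                fixed[2 * a1 + a2] += c * w
    n_dh = counts[1, 1]  # double heterozygotes: MM/mm+Mm/mM wait — phases (MM,mm) or (Mm,mM)

    freqs = np.array([(1 - p) * (1 - q), (1 - p) * q, p * (1 - q), p * q])
    ll_path = [_pair_log_likelihood(freqs, counts)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split double heterozygotes between the two phases
        w_coupling = freqs[0] * freqs[3]           # (MM, mm)
        w_repulsion = freqs[1] * freqs[2]          # (Mm, mM)
        tot = w_coupling + w_repulsion
        share = 0.5 if tot == 0 else w_coupling / tot
        counts_h = fixed.copy()
        counts_h[[0, 3]] += n_dh * share
        counts_h[[1, 2]] += n_dh * (1 - share)
        # M-step
        new = counts_h / (2 * n)
        ll_path.append(_pair_log_likelihood(new, counts))
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            converged = True
            break
        freqs = new

    d, d_prime, r2 = ld_statistics(freqs)
    return HaplotypeEstimate(frequencies=freqs, d=d, d_prime=d_prime, r_squared=r2,
                             log_likelihood=ll_path[-1],
                             log_likelihood_path=np.array(ll_path),
                             iterations=it, converged=converged)


def _phase_contributions(g1: int, g2: int):
    """Haplotype pairs ((a1,a2) alleles, weight per haplotype) for a
    phase-unambiguous genotype pair; weight units are haplotype copies."""
    a1_pair = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g1]
    a2_pair = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g2]
    if g1 == 1 and g2 == 1:
        raise ValueError("double heterozygote phase is ambiguous")
    # at most one site is het, so pairing is unique
    if g1 == 1:
        return [((0, a2_pair[0]), 1.0), ((1, a2_pair[0]), 1.0)]
    if g2 == 1:
        return [((a1_pair[0], 0), 1.0), ((a1_pair[0], 1), 1.0)]
    return [((a1_pair[0], a2_pair[0]), 2.0)]


def posterior_haplotype_dosages(dosage1: np.ndarray, dosage2: np.ndarray,
                                estimate: HaplotypeEstimate) -> pd.DataFrame:
    """Expected per-sample haplotype counts given the EM frequencies.

    For all genotype pairs except the double heterozygote the counts are
    deterministic; the double heterozygote splits its two haplotypes across
    the coupling/repulsion phases by their posterior odds. Rows with a
    missing dosage get nan.
    """
    d1 = np.asarray(dosage1, float)
    d2 = np.asarray(dosage2, float)
    f = estimate.frequencies
    out = np.full((d1.size, 4), np.nan)
    w_c = f[0] * f[3]
    w_r = f[1] * f[2]
    share = 0.5 if (w_c + w_r) == 0 else w_c / (w_c + w_r)
    for i, (g1, g2) in enumerate(zip(d1, d2)):
        if not (np.isfinite(g1) and np.isfinite(g2)):
            continue
        g1, g2 = int(g1), int(g2)
        row = np.zeros(4)
        if g1 == 1 and g2 == 1:
            row[[0, 3]] = share
            row[[1, 2]] = 1 - share
        else:
            for (a1, a2), w in _phase_contributions(g1, g2):
                row[2 * a1 + a2] += w
        out[i] = row
    return pd.DataFrame(out, columns=HAPLOTYPE_LABELS)


def haplotype_association(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                          snp_pair: tuple[str, str], outcome: str = "hdl_c",
                          covariates: Sequence[str] = BASE_COVARIATES,
                          mediator: str | None = None, log_outcome: bool = True,
                          log_mediator: bool = True,
                          min_expected_count: float = 5.0) -> pd.DataFrame:
    """Regress the outcome on expected haplotype dosages.

    The most frequent haplotype is the reference; one coefficient per
    remaining haplotype with nonzero expected count. Haplotypes with total
    expected count below `min_expected_count` are flagged unstable.
    Optionally adjusts for the (log) mediator.
    """
    est = em_haplotype_freqs(genotypes.dosage(snp_pair[0]), genotypes.dosage(snp_pair[1]))
    if not est.converged:
        raise RuntimeError("EM did not converge; haplotype association unavailable")
    hap_dos = posterior_haplotype_dosages(genotypes.dosage(snp_pair[0]),
                                          genotypes.dosage(snp_pair[1]), est)

    pheno = phenotypes.aligned_to(genotypes.sample_ids)
    frame = pd.concat([hap_dos, pheno[[outcome, *covariates]].reset_index(drop=True)], axis=1)
    if mediator is not None:
        frame["mediator"] = pheno[mediator].to_numpy(float)
    frame = frame.dropna()
    y = transform_phenotype(frame[outcome].to_numpy(), "log" if log_outcome else "identity")
    if mediator is not None and log_mediator:
        frame["mediator"] = transform_phenotype(frame["mediator"].to_numpy(), "log")

    ref = int(np.argmax(est.frequencies))
    expected = frame[list(HAPLOTYPE_LABELS)].sum()
    labels = [h for i, h in enumerate(HAPLOTYPE_LABELS)
              if i != ref and expected[h] > 1e-9]
    design = frame[labels + [c for c in frame.columns
                             if c not in (*HAPLOTYPE_LABELS, outcome)]].copy()
    design.insert(0, "intercept", 1.0)
    fit = ols_fit(y, design)

    rows = []
    for h in labels:
        rows.append({
            "haplotype": h,
            "reference": HAPLOTYPE_LABELS[ref],
            "frequency": float(est.frequencies[HAPLOTYPE_LABELS.index(h)]),
            "beta": float(fit.params[h]),
            "se": float(fit.se[h]),
            "p": float(fit.pvalues[h]),
            "n_used": fit.n_used,
            "stable": bool(expected[h] >= min_expected_count),
        })
    return pd.DataFrame(rows)
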