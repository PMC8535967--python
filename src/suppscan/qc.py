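"""Sample- and SNP-level quality control.

Filter set: sample call rate >= 97%, then per-SNP minor allele frequency
>= 0.05, missingness <= 3%, and Hardy-Weinberg exact p >= 1e-6, computed on
the retained samples. The HWE test is the conditional exact test (plain
two-sided tail summation over heterozygote counts given the allele counts,
no mid-p correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from suppscan.containers import GenotypeMatrix


@dataclass
class QCThresholds:
    min_maf: float = 0.05
    max_snp_missing: float = 0.03
    min_sample_call_rate: float = 0.97
    hwe_p_floor: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_snp_missing", "min_sample_call_rate", "hwe_p_floor"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")


@dataclass
class QCReport:
    """Per-SNP and per-sample QC metrics with pass flags and reason codes."""

    snp_table: pd.DataFrame
    sample_table: pd.DataFrame
    n_samples_retained: int = field(init=False)
    n_snps_retained: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_samples_retained = int(self.sample_table["pass"].sum())
        self.n_snps_retained = int(self.snp_table["pass"].sum())

    def write(self, out_dir: str | Path, prefix: str = "qc") -> None:
        out = Path(out_dir)
        self.snp_table.to_csv(out / f"{prefix}_snps.tsv", sep="\t", index=False)
        self.sample_table.to_csv(out / f"{prefix}_samples.tsv", sep="\t", index=False)
        summary = {
            "n_samples_retained": self.n_samples_retained,
            "n_snps_retained": self.n_snps_retained,
            "n_samples_excluded": int((~self.sample_table["pass"]).sum()),
            "n_snps_excluded": int((~self.snp_table["pass"]).sum()),
        }
        import json

        (out / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


class EmptyAfterQCError(ValueError):
    """Raised when QC removes every sample or every SNP; carries the report."""

    def __init__(self, message: str, report: QCReport):
        super().__init__(message)
        self.report = report


def minor_allele_frequency(dosages: np.ndarray, return_swapped: bool = False):
    """Minor allele frequency of one dosage vector (nan = missing).

    Counts alternate alleles over 2 x non-missing samples; if the raw
    frequency exceeds 0.5 the minor/major labels are considered swapped and
    the complementary frequency is returned (flagged via `return_swapped`).
    """
    d = np.asarray(dosages, dtype=float)
    obs = d[np.isfinite(d)]
    if obs.size == 0:
        raise ValueError("all-missing dosage vector: MAF undefined")
    freq = obs.sum() / (2.0 * obs.size)
    swapped = freq > 0.5
    if swapped:
        freq = 1.0 - freq
    return (freq, swapped) if return_swapped else freq


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg equilibrium.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than that of the
    observed configuration. Monomorphic input returns 1.0 by convention.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # Conditional probabilities over het counts of the same parity as
    # n_rare, in log space (robust at biobank sample sizes):
    #   P(h) = 2^h n! / (hom_r! h! hom_c!) * n_rare!(2n-n_rare)!/(2n)!
    het_obs = n_het
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    log_p = (hets * np.log(2.0)
             - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1))
    log_p -= log_p.max()
    probs = np.exp(log_p)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, het_obs)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    d = dosages[np.isfinite(dosages)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def apply_qc(genotypes: GenotypeMatrix,
             thresholds: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Filter samples on call rate, then SNPs on MAF / missingness / HWE.

    Sample filtering runs first; all SNP statistics are computed on the
    retained samples (matching the convention that sample call rate is a
    property of the analyzed set). Every exclusion carries its reason codes.
    """
    if thresholds is None:
        thresholds = QCThresholds()

    d = genotypes.dosages
    call_rate = np.isfinite(d).mean(axis=1) if genotypes.n_snps else np.ones(genotypes.n_samples)
    sample_pass = call_rate >= thresholds.min_sample_call_rate
    sample_table = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "call_rate": call_rate,
        "pass": sample_pass,
        "reasons": ["" if ok else "call_rate" for ok in sample_pass],
    })

    retained = d[sample_pass]
    rows = []
    for j in range(genotypes.n_snps):
        col = retained[:, j]
        n_obs = int(np.isfinite(col).sum())
        missing_frac = 1.0 - n_obs / max(len(col), 1)
        reasons = []
        if n_obs == 0:
            maf, hwe_p = np.nan, np.nan
            reasons.append("missing")
        else:
            maf = minor_allele_frequency(col)
            hwe_p = hwe_exact_test(*_genotype_counts(col))
            if maf < thresholds.min_maf:
                reasons.append("maf")
            if missing_frac > thresholds.max_snp_missing:
                reasons.append("missing")
            if hwe_p < thresholds.hwe_p_floor:
                reasons.append("hwe")
        rows.append({
            "snp_id": genotypes.snp_meta["snp_id"].iloc[j],
            "maf": maf,
            "missing_frac": missing_frac,
            "hwe_p": hwe_p,
            "pass": not reasons,
            "reasons": ",".join(reasons),
        })
    snp_table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["snp_id", "maf", "missing_frac", "hwe_p", "pass", "reasons"])

    report = QCReport(snp_table=snp_table, sample_table=sample_table)
    snp_pass = snp_table["pass"].to_numpy(dtype=bool) if len(snp_table) else np.array([], bool)
    filtered = genotypes.subset(sample_mask=sample_pass, snp_mask=snp_pass)
    if filtered.n_samples == 0 or filtered.n_snps == 0:
        raise EmptyAfterQCError("QC removed every sample or SNP", report)
    return filtered, report
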