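#!/usr/bin/env python
"""Quality control of the simulated cohort.

Reloads results/cohort/genotypes.vcf, applies the standard GWAS filter set
(sample call rate >= 97%; SNP MAF >= 0.05, missingness <= 3%, HWE exact
p >= 1e-6) and writes the filtered VCF plus per-SNP/per-sample QC tables
under results/qc/.
"""

from pathlib import Path

from suppscan import io as sio
from suppscan.qc import QCThresholds, apply_qc

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    genotypes = sio.read_vcf(ROOT / "cohort" / "genotypes.vcf")
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    thresholds = QCThresholds()
    filtered, report = apply_qc(genotypes, thresholds)
    sio.write_vcf(filtered, out / "genotypes_qc.vcf")
    report.write(out)

    n_ex_samples = len(report.sample_table) - report.n_samples_retained
    n_ex_snps = len(report.snp_table) - report.n_snps_retained
    print(f"samples: {report.n_samples_retained} retained, {n_ex_samples} excluded "
          f"(call rate < {thresholds.min_sample_call_rate:.0%})")
    print(f"SNPs: {report.n_snps_retained} retained, {n_ex_snps} excluded")
    failed = report.snp_table[~report.snp_table["pass"]]
    if len(failed):
        print(failed[["snp_id", "maf", "missing_frac", "hwe_p", "reasons"]]
              .to_string(index=False))


if __name__ == "__main__":
    main()
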