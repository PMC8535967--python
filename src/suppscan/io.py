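"""Readers and writers for genotype / phenotype files.

Genotypes travel either as uncompressed VCF (biallelic diploid rows, GT
field; ``./.`` marks missing) or as a dosage TSV (samples x SNPs, values
0/1/2, ``NA`` for missing). ALT always carries the minor allele, so GT
allele counts equal minor-allele dosages.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from suppscan.containers import GenotypeMatrix

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=suppscan
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCF with REF=major, ALT=minor allele."""
    path = Path(path)
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        meta = genotypes.snp_meta
        for chrom in sorted(set(meta["chrom"].astype(str))):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].to_numpy()))
        for j in order:
            row = meta.iloc[j]
            calls = "\t".join(
                gt_strings.get(d, "./.") if np.isfinite(d) else "./."
                for d in genotypes.dosages[:, j]
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.major_allele}\t"
                     f"{row.minor_allele}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix; non-biallelic or non-SNP rows are rejected."""
    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 = missing
    sample_ids = list(vcf.samples)
    records, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"only biallelic sites supported; {var.ID} has ALT={var.ALT}")
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValueError(f"only SNPs supported; {var.ID} is {var.REF}>{var.ALT[0]}")
        records.append({
            "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
            "chrom": str(var.CHROM),
            "pos": int(var.POS),
            "minor_allele": var.ALT[0],
            "major_allele": var.REF,
        })
        g = var.gt_types.astype(float)
        g[g == 3] = np.nan
        columns.append(g)
    vcf.close()
    dosages = np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids=sample_ids, snp_meta=pd.DataFrame(records), dosages=dosages)


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path,
                     meta_path: str | Path | None = None) -> None:
    """Samples x SNPs dosage TSV (first column sample_id, NA = missing)."""
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.snp_meta["snp_id"])
    df.insert(0, "sample_id", genotypes.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")
    if meta_path is not None:
        genotypes.snp_meta.to_csv(meta_path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path, meta_path: str | Path | None = None) -> GenotypeMatrix:
    """Inverse of `write_dosage_tsv`; synthesizes placeholder metadata if none given."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    sample_ids = df.pop("sample_id").tolist()
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
    else:
        meta = pd.DataFrame({
            "snp_id": df.columns,
            "chrom": "0",
            "pos": np.arange(1, len(df.columns) + 1),
            "minor_allele": "A",
            "major_allele": "C",
        })
    return GenotypeMatrix(sample_ids=sample_ids, snp_meta=meta,
                          dosages=df.to_numpy(dtype=float))


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=float) + "\n")
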