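"""In-memory containers for genotype and phenotype data.

Genotypes are held as a samples x SNPs dosage matrix (minor-allele counts
0/1/2, ``nan`` for missing) alongside per-SNP metadata; phenotypes as a
pandas DataFrame keyed by sample id. Sex is coded 0 = male, 1 = female;
smoking 0 = non-smoker, 1 = current smoker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: required metadata columns, one row per SNP
SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "minor_allele", "major_allele"]

#: phenotype columns every table must carry
PHENOTYPE_COLUMNS = ["sample_id", "sex", "age", "bmi", "smoking", "adiponectin", "hdl_c"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with missingness mask.

    Parameters
    ----------
    sample_ids : list of str
        One id per row of `dosages`.
    snp_meta : pandas.DataFrame
        One row per column of `dosages`, with columns `SNP_META_COLUMNS`.
        Positions are 1-based (VCF convention).
    dosages : numpy.ndarray, float
        Minor-allele counts in {0, 1, 2}; missing entries are ``nan``.
    """

    sample_ids: list[str]
    snp_meta: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs array")
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_meta)):
            raise ValueError(
                f"shape mismatch: dosages {self.dosages.shape} vs "
                f"{len(self.sample_ids)} samples x {len(self.snp_meta)} SNPs"
            )
        missing = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing:
            raise ValueError(f"snp_meta missing columns: {missing}")
        if self.snp_meta["snp_id"].duplicated().any():
            dups = self.snp_meta.loc[self.snp_meta["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate SNP ids: {sorted(set(dups))}")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
            bad = np.unique(finite[~np.isin(finite, [0.0, 1.0, 2.0])])
            raise ValueError(f"dosages must be 0/1/2/nan; found {bad}")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_meta)

    def snp_index(self, snp_id: str) -> int:
        idx = self.snp_meta.index[self.snp_meta["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not found")
        return int(idx[0])

    def dosage(self, snp_id: str) -> np.ndarray:
        """Dosage vector (length n_samples, nan = missing) for one SNP."""
        return self.dosages[:, self.snp_index(snp_id)]

    def subset(self, sample_mask: np.ndarray | None = None,
               snp_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        """Boolean-mask rows (samples) and/or columns (SNPs)."""
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        km = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask, bool)
        return GenotypeMatrix(
            sample_ids=[s for s, keep in zip(self.sample_ids, sm) if keep],
            snp_meta=self.snp_meta.loc[km].reset_index(drop=True),
            dosages=self.dosages[np.ix_(sm, km)],
        )


@dataclass
class PhenotypeTable:
    """Per-sample outcome, mediator and covariates.

    Wraps a DataFrame with at least `PHENOTYPE_COLUMNS`; extra phenotype
    columns (triglycerides, LDL-C, ...) pass through untouched.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].astype(str).tolist()

    def aligned_to(self, sample_ids: list[str]) -> pd.DataFrame:
        """Rows reordered to `sample_ids`; alignment is by id, never by position."""
        indexed = self.data.set_index("sample_id")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise KeyError(f"samples absent from phenotype table: {missing[:5]}...")
        return indexed.loc[sample_ids].reset_index()

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        return cls(df)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")
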