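"""End-to-end pipeline: simulate/load -> QC -> scan -> mediation -> haplotype/LD.

Each stage writes its outputs under the run directory and registers them in
a manifest with content hashes; a rerun with the same config and seed
reproduces the manifest byte-for-byte. Stage logging goes to stderr and to
``run.log``; stdout carries only the manifest path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from suppscan import io as sio
from suppscan.association import GENOME_WIDE_THRESHOLD, genome_scan, plot_manhattan
from suppscan.containers import PhenotypeTable
from suppscan.haplotype import em_haplotype_freqs, haplotype_association
from suppscan.mediation import mediation_scan
from suppscan.qc import QCThresholds, apply_qc
from suppscan.simulate import FOCAL_SNP_IDS, SimulationConfig, simulate_cohort

logger = logging.getLogger("suppscan")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of (`vcf_path` + `pheno_path`) or `simulation` must be set.
    """

    out_dir: str | Path
    simulation: SimulationConfig | None = None
    vcf_path: str | Path | None = None
    pheno_path: str | Path | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    adjustments: Sequence[str] = ("base", "base+mediator")
    outcome: str = "hdl_c"
    mediator: str = "adiponectin"
    covariates: Sequence[str] = ("age", "sex", "bmi", "smoking")
    significance: float = 0.05
    genome_threshold: float = GENOME_WIDE_THRESHOLD
    candidate_threshold: float = 1e-4   # mediator-adjusted p cut for mediation candidates
    focal_pair: tuple[str, str] | None = None
    log_outcome: bool = True
    log_mediator: bool = True
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.vcf_path is not None and self.pheno_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError("provide exactly one of (vcf_path+pheno_path) or simulation")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim = dict(raw["simulation"])
            if "maf_focal" in sim:
                sim["maf_focal"] = tuple(sim["maf_focal"])
            raw["simulation"] = SimulationConfig(**sim)
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = QCThresholds(**raw["thresholds"])
        return cls(**raw)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict[str, Any] = {"config": _jsonable(config), "stages": {}}

    def record(stage: str, files: list[Path], started: float, **counts) -> None:
        # wall time goes to the log only, so the manifest is seed-deterministic
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files},
            **counts,
        }
        logger.info("stage %s done in %.2fs (%s)", stage, time.monotonic() - started, counts)

    stage = "input"
    try:
        t0 = time.monotonic()
        if config.simulation is not None:
            cohort = simulate_cohort(config.simulation)
            genotypes, phenotypes = cohort.genotypes, cohort.phenotypes
            sio.write_vcf(genotypes, out / "genotypes.vcf")
            phenotypes.to_tsv(out / "phenotypes.tsv")
            sio.write_truth_json(cohort.truth, out / "truth.json")
            files = [out / "genotypes.vcf", out / "phenotypes.tsv", out / "truth.json"]
        else:
            genotypes = sio.read_vcf(config.vcf_path)
            phenotypes = PhenotypeTable.from_tsv(config.pheno_path)
            files = []
        record(stage, files, t0, n_samples=genotypes.n_samples, n_snps=genotypes.n_snps)

        stage = "qc"
        t0 = time.monotonic()
        genotypes, report = apply_qc(genotypes, config.thresholds)
        report.write(out)
        record(stage, [out / "qc_snps.tsv", out / "qc_samples.tsv", out / "qc_summary.json"],
               t0, n_samples=report.n_samples_retained, n_snps=report.n_snps_retained)

        stage = "scan"
        t0 = time.monotonic()
        scan = genome_scan(genotypes, phenotypes, adjustments=config.adjustments,
                           threshold=config.genome_threshold, outcome=config.outcome,
                           mediator=config.mediator, covariates=config.covariates,
                           log_outcome=config.log_outcome, log_mediator=config.log_mediator)
        scan.to_csv(out / "scan.tsv", sep="\t", index=False, float_format="%.6g")
        files = [out / "scan.tsv"]
        if config.make_plots:
            for adj in config.adjustments:
                p = out / f"manhattan_{adj.replace('+', '_')}.png"
                plot_manhattan(scan, p, adjustment=adj, threshold=config.genome_threshold)
                files.append(p)
        record(stage, files, t0, n_records=len(scan),
               n_significant=int(scan["significant"].sum()))

        stage = "mediate"
        t0 = time.monotonic()
        adjusted = scan[scan["adjustment"] == "base+mediator"]
        candidates = adjusted.loc[adjusted["p"] < config.candidate_threshold, "snp_id"].tolist()
        if not candidates:  # always analyze the focal pair if present
            candidates = [s for s in FOCAL_SNP_IDS if s in set(genotypes.snp_meta["snp_id"])]
        med = mediation_scan(genotypes, phenotypes, candidates,
                             covariates=tuple(config.covariates),
                             significance=config.significance, outcome=config.outcome,
                             mediator=config.mediator, log_outcome=config.log_outcome,
                             log_mediator=config.log_mediator)
        med_out = med.drop(columns=["criteria_met"]).assign(
            criteria_met=[",".join(str(int(b)) for b in c) for c in med["criteria_met"]])
        med_out.to_csv(out / "mediation.tsv", sep="\t", index=False, float_format="%.6g")
        (out / "mediation.json").write_text(
            json.dumps(_jsonable(med.to_dict(orient="records")), indent=2) + "\n")
        record(stage, [out / "mediation.tsv", out / "mediation.json"], t0,
               n_candidates=len(candidates),
               n_suppression=int((med["classification"] == "suppression").sum()))

        stage = "haplo"
        t0 = time.monotonic()
        pair = config.focal_pair or FOCAL_SNP_IDS
        present = set(genotypes.snp_meta["snp_id"])
        files = []
        if pair[0] in present and pair[1] in present:
            est = em_haplotype_freqs(genotypes.dosage(pair[0]), genotypes.dosage(pair[1]))
            hap = haplotype_association(genotypes, phenotypes, tuple(pair),
                                        outcome=config.outcome,
                                        covariates=config.covariates,
                                        mediator=config.mediator,
                                        log_outcome=config.log_outcome,
                                        log_mediator=config.log_mediator)
            hap.to_csv(out / "haplotype_association.tsv", sep="\t", index=False,
                       float_format="%.6g")
            ld = {
                "snp_pair": list(pair),
                "frequencies": est.frequencies.tolist(),
                "D": est.d, "D_prime": est.d_prime, "r_squared": est.r_squared,
                "log_likelihood": est.log_likelihood,
                "iterations": est.iterations, "converged": bool(est.converged),
            }
            (out / "ld_report.json").write_text(json.dumps(ld, indent=2) + "\n")
            files = [out / "haplotype_association.tsv", out / "ld_report.json"]
        record(stage, files, t0, pair_present=bool(files))
    except Exception as exc:  # noqa: BLE001 - abort with stage name + partial manifest
        logger.removeHandler(handler)
        handler.close()
        raise PipelineStageError(stage, manifest, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True) + "\n")
    logger.removeHandler(handler)
    handler.close()
    return manifest
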