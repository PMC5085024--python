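"""End-to-end pipeline: QC -> LD prune -> ROH calling -> Froh -> association.

A :class:`PipelineConfig` fully determines a run given a seed; every stage
writes its artifact as TSV (plus ``.hom`` for segments) and a manifest
records the config hash, seed and artifact list so any stage can be re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import genotype_io
from .association import (
    build_covariates,
    fit_logistic,
    per_dataset_fits,
    sweep_association,
)
from .autozygosity import (
    MAPPABLE_BP,
    compute_froh,
    froh_descriptives,
    split_froh,
)
from .datamodel import GenotypeMatrix
from .null_experiments import site_flip_permutation
from .qc import QCThresholds, sample_filters, snp_filters, vif_prune
from .roh import CallingParams, ROHSet, ThresholdGrid, call_roh, filter_roh
from .synthetic_cohort import CohortSpec, SiteSpec, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial artifacts remain."""


@dataclass
class PipelineConfig:
    """Serializable configuration; defaults reproduce the headline analysis
    (110 consecutive homozygous SNPs and the 2.3 Mb length threshold)."""

    seed: int = 0
    # input: simulate a cohort, or read files
    cohort: dict | None = None
    ped_path: str | None = None
    map_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    calling: CallingParams = field(default_factory=CallingParams)
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    headline_snp_threshold: int = 110
    headline_mb_threshold: float = 2.3
    split_cutoff_mb: float = 8.0
    n_pcs: int = 20
    mappable_bp: float | None = None  # default: simulated genome size, else 2.77e9
    run_sweep: bool = False
    run_per_dataset: bool = True
    run_permutation: bool = False
    n_perm: int = 200
    alpha: float = 0.05

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc"] = asdict(self.qc)
        d["calling"] = asdict(self.calling)
        d["grid"] = {"snp_thresholds": list(self.grid.snp_thresholds),
                     "mb_thresholds": list(self.grid.mb_thresholds)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("qc"), dict):
            d["qc"] = QCThresholds(**d["qc"])
        if isinstance(d.get("calling"), dict):
            d["calling"] = CallingParams(**d["calling"])
        if isinstance(d.get("grid"), dict):
            d["grid"] = ThresholdGrid(
                snp_thresholds=tuple(d["grid"]["snp_thresholds"]),
                mb_thresholds=tuple(d["grid"]["mb_thresholds"]),
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cohort_spec(config: PipelineConfig) -> CohortSpec:
    c = dict(config.cohort or {})
    sites = [SiteSpec(**s) if isinstance(s, dict) else s for s in c.pop("sites")]
    c.setdefault("seed", config.seed)
    return CohortSpec(sites=sites, **c)


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run every configured stage in order; returns the result bundle.

    Artifacts are written into ``outdir`` as they are produced, so a failed
    stage leaves everything upstream on disk.
    """
    os.makedirs(outdir, exist_ok=True)
    artifacts: list[str] = []
    bundle: dict = {}

    def emit(name: str, writer) -> None:
        path = os.path.join(outdir, name)
        writer(path)
        artifacts.append(name)

    stage = "load"
    try:
        if config.cohort is not None:
            spec = _cohort_spec(config)
            matrix, truth = simulate_cohort(spec)
            mappable = config.mappable_bp or float(spec.genome_bp)
            bundle["truth"] = truth
            emit("truth.tsv", lambda p: pd.DataFrame(
                {"sample_id": [t.sample_id for t in truth],
                 "f_true": [t.f_true for t in truth],
                 "n_planted": [len(t.planted_segments) for t in truth]}
            ).to_csv(p, sep="\t", index=False))
        elif config.ped_path and config.map_path:
            matrix = genotype_io.read_plink_text(config.ped_path, config.map_path)
            mappable = config.mappable_bp or MAPPABLE_BP
        else:
            raise ValueError("config must give either a cohort spec or ped/map paths")
        bundle["input_shape"] = (matrix.n_samples, matrix.n_variants)

        stage = "qc_samples"
        matrix, sample_report = sample_filters(matrix, config.qc)
        bundle["sample_qc"] = sample_report
        emit("qc_samples.tsv", lambda p: sample_report.to_frame().to_csv(p, sep="\t", index=False))

        stage = "qc_snps"
        matrix, snp_report = snp_filters(matrix, config.qc)
        bundle["snp_qc"] = snp_report
        emit("qc_snps.tsv", lambda p: snp_report.to_frame().to_csv(p, sep="\t", index=False))

        stage = "vif_prune"
        matrix, kept = vif_prune(matrix, config.qc.vif_limit, config.qc.vif_window,
                                 config.qc.vif_step)
        logger.info("vif_prune kept %d variants", len(kept))
        bundle["pruned_shape"] = (matrix.n_samples, matrix.n_variants)
        bundle["matrix"] = matrix

        stage = "covariates"
        covariates = build_covariates(matrix, n_pcs=min(config.n_pcs, matrix.n_samples))
        bundle["covariates"] = covariates
        emit("covariates.tsv", lambda p: covariates.to_csv(p, sep="\t", index=False))

        stage = "call_roh"
        base_roh = call_roh(matrix, config.calling)
        bundle["roh_base"] = base_roh
        ds_of = {s.sample_id: s.dataset_id for s in matrix.samples}
        emit("roh_base.hom", lambda p: genotype_io.write_hom(
            base_roh, p, p + ".indiv", ds_of))

        stage = "filter_roh"
        roh_snp = filter_roh(base_roh, min_snps=config.headline_snp_threshold)
        roh_mb = filter_roh(base_roh, min_mb=config.headline_mb_threshold)
        bundle["roh_snp"] = roh_snp
        bundle["roh_mb"] = roh_mb
        emit("roh_snp.hom", lambda p: genotype_io.write_hom(roh_snp, p, None, ds_of))
        emit("roh_mb.hom", lambda p: genotype_io.write_hom(roh_mb, p, None, ds_of))

        stage = "froh"
        froh_df = split_froh(roh_snp, matrix.samples, config.split_cutoff_mb, mappable)
        bundle["froh"] = froh_df
        emit("froh.tsv", lambda p: froh_df.to_csv(p, sep="\t", index=False))
        desc = froh_descriptives(froh_df, roh_snp)
        bundle["descriptives"] = desc
        emit("descriptives.tsv", lambda p: desc.to_csv(p, sep="\t", index=False))

        stage = "association"
        y = froh_df["phenotype"].to_numpy()
        ds = froh_df["dataset_id"].to_numpy()
        use_ds = ds if len(pd.unique(ds)) > 1 else None
        froh_mb_df = compute_froh(roh_mb, matrix.samples, mappable)
        fits = {
            "snp_headline": fit_logistic(
                y, froh_df["froh"].to_numpy(), covariates, use_ds,
                threshold=f"{config.headline_snp_threshold}snp"),
            "mb_headline": fit_logistic(
                y, froh_mb_df["froh"].to_numpy(), covariates, use_ds,
                threshold=f"{config.headline_mb_threshold}mb"),
            "froh_short": fit_logistic(
                y, froh_df["froh_short"].to_numpy(),
                pd.concat([covariates, froh_df[["froh_long"]].reset_index(drop=True)], axis=1),
                use_ds, threshold="froh_short"),
            "froh_long": fit_logistic(
                y, froh_df["froh_long"].to_numpy(),
                pd.concat([covariates, froh_df[["froh_short"]].reset_index(drop=True)], axis=1),
                use_ds, threshold="froh_long"),
        }
        bundle["association"] = fits
        emit("association.tsv", lambda p: pd.DataFrame(
            [r.to_dict() for r in fits.values()]).to_csv(p, sep="\t", index=False))

        if config.run_per_dataset and use_ds is not None:
            per, pooled = per_dataset_fits(y, froh_df["froh"].to_numpy(), covariates, ds)
            bundle["per_dataset"] = per
            emit("per_dataset.tsv", lambda p: pd.DataFrame(
                [r.to_dict() for r in per.values()] + [pooled.to_dict()]
            ).to_csv(p, sep="\t", index=False))

        if config.run_sweep:
            stage = "sweep"
            sweeps = sweep_association(base_roh, matrix.samples, config.grid,
                                       covariates, mappable_bp=mappable)
            bundle["sweeps"] = sweeps
            for sw in sweeps:
                emit(f"sweep_{sw.grid_type}.tsv",
                     lambda p, sw=sw: sw.to_frame().to_csv(p, sep="\t", index=False))

        if config.run_permutation and use_ds is not None:
            stage = "permutation"
            perm = site_flip_permutation(
                y, froh_df["froh"].to_numpy(), covariates, ds,
                n_perm=config.n_perm, alpha=config.alpha, seed=config.seed)
            bundle["permutation"] = perm
            emit("permutation.json", lambda p: json.dump(
                perm.to_dict(), open(p, "w"), indent=2))
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": artifacts,
        "config": config.to_dict(),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small two-site synthetic cohort that exercises every stage quickly."""
    genome = {"1": 60_000_000, "2": 60_000_000, "3": 40_000_000, "4": 40_000_000}
    return PipelineConfig(
        seed=seed,
        cohort={
            "sites": [
                {"name": "alpha", "n_cases": 130, "n_controls": 120},
                {"name": "beta", "n_cases": 120, "n_controls": 130},
            ],
            "n_snps": 16_000,
            "chrom_lengths_bp": genome,
            "f_zero_fraction": 0.4,
            "f_mean": 0.02,
            "segment_mean_mb": 4.0,
            "beta_true": 10.0,
            "missing_rate": 0.002,
        },
        n_pcs=5,
        run_sweep=False,
        run_permutation=True,
        n_perm=50,
    )
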