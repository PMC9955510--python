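"""End-to-end orchestration: simulate (or load) -> meta-radiomics -> DEG +
dual screens -> transcriptomic signature -> p-metaomics models -> validation.

A single master seed deterministically derives per-stage seeds (stage-name
hashing) so any stage can be rerun in isolation from the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io as rio
from . import meta_radiomics as mr
from . import pmetaomics as pm
from . import signature as sig_mod
from . import synthetic as syn
from . import validation as val

__all__ = [
    "PipelineConfig",
    "RunResult",
    "derive_seed",
    "run_all",
    "truth_metrics",
]

log = logging.getLogger(__name__)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 from the master seed and stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters plus either a synthetic study config or file paths."""

    simulate: bool = True
    study: dict = field(default_factory=dict)  # StudyConfig overrides
    paths: dict = field(default_factory=dict)  # input files when simulate=False
    k_min: int = 2
    k_max: int = 100
    kmeans_iters: int = 200
    kmeans_restarts: int = 10
    homogeneity: float = 0.75
    fdr: float = 0.05
    fold_change: float = 2.0
    n_perm: int = 1000
    delta_override: float | None = None
    r2_threshold: float = 0.70
    corr_fdr: float = 0.05
    granularity: str = "gene"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.homogeneity <= 1.0:
            raise ValueError("homogeneity threshold must be in [-1, 1]")
        for name in ("fdr", "corr_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.k_min < 2 or self.k_min > self.k_max:
            raise ValueError("invalid K range")
        if self.granularity not in ("gene", "pair"):
            raise ValueError("granularity must be 'gene' or 'pair'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunResult:
    manifest: dict
    study: syn.StudyData | None
    meta: mr.MetaRadiomicsSignature
    k_table: mr.KSelectionTable
    degs: sig_mod.DegSet
    signature: sig_mod.TranscriptomicSignature
    models: list[pm.PMetaomicsModel]
    pmeta: pm.PMetaomicsSignature
    svm_report: val.ClassificationReport | None
    cluster_report: val.ClusterValidityReport | None
    pmeta_cluster_report: val.ClusterValidityReport | None
    applied: object = None  # samples x models DataFrame


def _load_inputs(cfg: PipelineConfig):
    p = cfg.paths
    need = ["tumor_normal", "tumor_normal_labels", "control", "paired", "features", "external", "external_labels"]
    missing = [k for k in need if k not in p]
    if missing:
        raise ValueError(f"missing input paths: {missing}")
    for key in need:
        if not os.path.exists(p[key]):
            raise FileNotFoundError(p[key])
    tn = rio.read_expression_table(
        p["tumor_normal"], rio.read_class_labels(p["tumor_normal_labels"]), "tumor_normal"
    )
    control = rio.read_expression_table(p["control"], batch_id="control")
    control.sample_class = ["normal"] * control.n_samples
    paired = rio.read_expression_table(p["paired"], batch_id="paired")
    paired.sample_class = ["cancer"] * paired.n_samples
    external = rio.read_expression_table(
        p["external"], rio.read_class_labels(p["external_labels"]), "external"
    )
    features = rio.read_feature_table(p["features"])
    cohorts = {
        "paired": paired,
        "tumor_normal": tn,
        "control": control,
        "external": external,
    }
    return syn.StudyData(cohorts, features, syn.SyntheticTruth())


def run_all(cfg: PipelineConfig) -> RunResult:
    """Execute every stage in order, recording a manifest of parameters,
    per-stage seeds, filter funnel counts, timings and written files."""
    timings: dict[str, float] = {}
    counts: dict[str, float] = {}
    files: list[str] = []
    seeds = {
        s: derive_seed(cfg.seed, s)
        for s in ("simulate", "meta_radiomics", "deg", "screens", "pmetaomics")
    }

    def tick(stage):
        timings[stage] = time.perf_counter()

    def tock(stage):
        timings[stage] = round(time.perf_counter() - timings[stage], 3)

    # --- stage: data ---------------------------------------------------
    tick("data")
    if cfg.simulate:
        study = syn.generate_paired_study(syn.StudyConfig(**cfg.study), seeds["simulate"])
    else:
        study = _load_inputs(cfg)
    paired = study.cohorts["paired"]
    tumor_normal = study.cohorts["tumor_normal"]
    control = study.cohorts["control"]
    external = study.cohorts["external"]
    counts["genes_in"] = paired.n_genes
    counts["features_in"] = study.features.n_features
    tock("data")

    # --- stage: meta-radiomics -----------------------------------------
    tick("meta_radiomics")
    std_features, dropped = mr.prepare_features(study.features)
    counts["constant_features_dropped"] = len(dropped)
    counts["features_retained"] = std_features.n_features
    k, k_table = mr.select_k(
        std_features,
        cfg.k_min,
        cfg.k_max,
        cfg.kmeans_iters,
        cfg.kmeans_restarts,
        seeds["meta_radiomics"],
    )
    model = mr.kmeans_fit(
        std_features, k, cfg.kmeans_iters, cfg.kmeans_restarts, seeds["meta_radiomics"]
    )
    h = mr.homogeneity_scores(model, std_features)
    meta = mr.extract_meta_features(
        model, h, std_features, cfg.homogeneity, seeds["meta_radiomics"]
    )
    counts["k_selected"] = k
    counts["clusters_qualifying"] = meta.n_meta_features
    tock("meta_radiomics")

    # --- stage: DEGs ----------------------------------------------------
    tick("deg")
    degs = sig_mod.select_degs(
        tumor_normal,
        control,
        n_perm=cfg.n_perm,
        fdr_target=cfg.fdr,
        fold_change=cfg.fold_change,
        delta_override=cfg.delta_override,
        seed=seeds["deg"],
    )
    counts["degs_cross_dataset"] = len(degs.passed_cross)
    counts["degs"] = len(degs)
    deg_in_paired = [g for g in degs.gene_ids if g in set(paired.gene_ids)]
    counts["degs_in_paired"] = len(deg_in_paired)
    tock("deg")

    # --- stage: screens + signature ------------------------------------
    tick("screens")
    paired_degs = paired.subset_genes(deg_in_paired)
    screen_a = sig_mod.screen_spearman(paired_degs, std_features, cfg.fdr)
    screen_b = sig_mod.screen_samquant(
        paired_degs, std_features, cfg.fdr, cfg.n_perm, seeds["screens"]
    )
    signature = sig_mod.build_signature(degs, screen_a, screen_b, cfg.granularity)
    counts["signature_size"] = len(signature)
    tock("screens")

    # --- stage: p-metaomics ---------------------------------------------
    tick("pmetaomics")
    models: list[pm.PMetaomicsModel] = []
    pmeta = pm.PMetaomicsSignature([], [], list(signature.gene_ids), cfg.r2_threshold)
    applied = None
    if len(signature) > 0 and meta.n_meta_features > 0:
        sig_expr = paired.subset_genes(signature.gene_ids)
        X = sig_expr.values.T
        for fid, y in zip(meta.meta_feature_ids, meta.meta_values):
            models.append(
                pm.fit_lasso_loocv(
                    X, y, signature.gene_ids, fid, seed=seeds["pmetaomics"]
                )
            )
        pmeta = pm.select_pmetaomics(models, sig_expr, cfg.r2_threshold, cfg.corr_fdr)
        if pmeta.models:
            applied = pm.apply_models(pmeta, tumor_normal, drop_incomplete_models=True)
    counts["models_fit"] = len(models)
    counts["models_kept"] = len(pmeta.models)
    tock("pmetaomics")

    # --- stage: validation ----------------------------------------------
    tick("validation")
    svm_report = None
    cluster_report = None
    pmeta_cluster_report = None
    if len(signature) > 0:
        svm_report = val.svm_linear_eval(tumor_normal, external, signature.gene_ids)
        counts["svm_accuracy"] = svm_report.accuracy
        counts["svm_sensitivity"] = svm_report.sensitivity
        counts["svm_specificity"] = svm_report.specificity
        genes_present = [g for g in signature.gene_ids if g in set(external.gene_ids)]
        if len(genes_present) >= 2:  # BSI deletes one condition at a time
            data = val._zscore_genes(external.subset_genes(genes_present).values).T
            labels, _ = val.hcluster_cut(data, k=2)
            classes = np.asarray(external.sample_class)
            cluster_report = val.ClusterValidityReport(
                bhi=val.bhi(labels, classes),
                bsi=val.bsi(data, classes, k=2),
                linkage="complete",
                metric="euclidean",
                k=2,
            )
            counts["bhi_samples"] = cluster_report.bhi
            counts["bsi_samples"] = cluster_report.bsi
    if applied is not None and applied.shape[1] >= 2:
        pdata = applied.to_numpy()
        plabels, _ = val.hcluster_cut(pdata, k=2)
        pclasses = np.asarray(tumor_normal.sample_class)
        pmeta_cluster_report = val.ClusterValidityReport(
            bhi=val.bhi(plabels, pclasses),
            bsi=val.bsi(pdata, pclasses, k=2),
            linkage="complete",
            metric="euclidean",
            k=2,
        )
        counts["bhi_pmetaomics"] = pmeta_cluster_report.bhi
        counts["bsi_pmetaomics"] = pmeta_cluster_report.bsi
    tock("validation")

    # --- outputs ---------------------------------------------------------
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        files += rio.write_outputs(meta, os.path.join(cfg.out_dir, "meta_radiomics"))
        files += rio.write_outputs(degs, os.path.join(cfg.out_dir, "degs"))
        files += rio.write_outputs(signature, os.path.join(cfg.out_dir, "signature"))
        files += rio.write_outputs(pmeta, os.path.join(cfg.out_dir, "pmetaomics"))
        k_path = os.path.join(cfg.out_dir, "k_selection.tsv")
        k_table.table.to_csv(k_path, sep="\t", index=False)
        files.append(k_path)
        if applied is not None:
            a_path = os.path.join(cfg.out_dir, "pmetaomics_applied.tsv")
            applied.to_csv(a_path, sep="\t", float_format=rio.FLOAT_FMT)
            files.append(a_path)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seeds": seeds,
        "counts": counts,
        "files": sorted(files),
        "timings": timings,
    }
    if cfg.out_dir:
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=rio._json_default)
    log.info("pipeline funnel: %s", counts)
    return RunResult(
        manifest,
        study,
        meta,
        k_table,
        degs,
        signature,
        models,
        pmeta,
        svm_report,
        cluster_report,
        pmeta_cluster_report,
        applied,
    )


def truth_metrics(result: RunResult) -> dict:
    """Planted-truth recovery metrics for a simulated run.

    driver_recall: fraction of planted driver genes in the final signature;
    nondriver_deg_rate: fraction of recovered non-driver DEGs entering it;
    driver_gate_pass_rate / noise_gate_pass_rate: fraction of fitted models
    for gene-driven / noise-driven meta-features whose in-sample R-squared
    clears the selection threshold.
    """
    if result.study is None or not result.study.truth.deg_ids:
        raise ValueError("truth metrics need a simulated study")
    truth = result.study.truth
    drivers = truth.driver_genes
    sig_genes = set(result.signature.gene_ids)
    deg_genes = set(result.degs.gene_ids)
    nondriver_degs = (deg_genes - drivers)
    metrics = {
        "driver_recall": (len(drivers & sig_genes) / len(drivers)) if drivers else np.nan,
        "nondriver_deg_rate": (
            len(nondriver_degs & sig_genes) / len(nondriver_degs) if nondriver_degs else np.nan
        ),
    }
    thr = result.pmeta.r2_threshold
    driver_pass = []
    noise_pass = []
    for m in result.models:
        cluster = truth.cluster_assignment.get(m.feature_id)
        if cluster is None:
            continue
        ok = m.diagnostics.get("r_squared", np.nan) > thr
        (driver_pass if cluster in truth.driver_clusters else noise_pass).append(ok)
    metrics["driver_gate_pass_rate"] = float(np.mean(driver_pass)) if driver_pass else np.nan
    metrics["noise_gate_pass_rate"] = float(np.mean(noise_pass)) if noise_pass else np.nan
    metrics["n_driver_models"] = len(driver_pass)
    metrics["n_noise_models"] = len(noise_pass)
    return metrics
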