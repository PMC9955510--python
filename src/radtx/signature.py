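"""Transcriptomic signature derivation.

Differentially expressed genes (DEGs) come from a two-class SAM with a
2-fold-change gate between a tumor/normal dataset's cancer samples and an
independent control dataset (each dataset mean-centered to control batch
effects), intersected with a within-dataset 2-fold-change criterion. The
DEGs are then screened against the radiomic feature table with two
independent statistics — per-gene Spearman tests with Benjamini-Hochberg
correction across the feature family, and one quantitative SAM per feature —
and the genes significant under both methods form the signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import sam as sam_mod
from .io import ExpressionMatrix, FeatureTable, intersect_genes, mean_center
from .stats import bh_adjust

__all__ = [
    "DegSet",
    "ScreenResult",
    "TranscriptomicSignature",
    "select_degs",
    "screen_spearman",
    "screen_samquant",
    "build_signature",
]

log = logging.getLogger(__name__)


@dataclass
class DegSet:
    gene_ids: list[str]
    signs: dict[str, int]  # +1 higher in cancer, -1 higher in normal
    passed_cross: set[str]  # cross-dataset SAM + fold change
    passed_within: set[str]  # within-dataset fold change

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.signs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "sign": [self.signs[g] for g in self.gene_ids],
                "passed_cross_dataset": [g in self.passed_cross for g in self.gene_ids],
                "passed_within_dataset": [g in self.passed_within for g in self.gene_ids],
            }
        )


def select_degs(
    tumor_normal: ExpressionMatrix,
    control: ExpressionMatrix,
    n_perm: int = 1000,
    fdr_target: float = 0.05,
    fold_change: float = 2.0,
    delta_override: float | None = None,
    seed: int = 0,
) -> DegSet:
    """DEGs from cross-dataset SAM + fold change and within-dataset fold change.

    `tumor_normal` carries both classes (a matched design); `control` holds
    normal samples only. Both are restricted to their common genes and
    mean-centered per gene within each dataset; the cross-dataset SAM then
    compares the centered cancer samples of `tumor_normal` against the
    centered controls. The fold-change gates use the original (uncentered)
    group means: centering a class-balanced dataset halves the apparent
    cancer/normal difference, so the gate is applied on the raw scale. Signs
    follow the within-dataset cancer-minus-normal direction.
    """
    if not any(c == "cancer" for c in tumor_normal.sample_class) or not any(
        c == "normal" for c in tumor_normal.sample_class
    ):
        raise ValueError("tumor_normal dataset must contain both classes")
    tn, ctrl = intersect_genes(tumor_normal, control)

    tn_centered = mean_center(tn)
    ctrl_centered = mean_center(ctrl)
    cancer_centered = tn_centered.subset_samples(
        [s for s, c in zip(tn.sample_ids, tn.sample_class) if c == "cancer"]
    )

    combined = ExpressionMatrix(
        list(tn.gene_ids),
        cancer_centered.sample_ids + ctrl_centered.sample_ids,
        np.hstack([cancer_centered.values, ctrl_centered.values]),
        ["cancer"] * cancer_centered.n_samples + ["normal"] * ctrl_centered.n_samples,
        batch_id="cross-dataset",
    )
    res = sam_mod.sam_two_class(
        combined,
        n_perm=n_perm,
        fdr_target=fdr_target,
        delta_override=delta_override,
        seed=seed,
    )
    sam_called = set(res.called)

    # cross-dataset fold gate on raw group means
    cancer_raw = tn.subset_samples(cancer_centered.sample_ids)
    cross_gate = sam_mod.fold_change_filter(
        ExpressionMatrix(
            list(tn.gene_ids),
            cancer_raw.sample_ids + ctrl.sample_ids,
            np.hstack([cancer_raw.values, ctrl.values]),
            ["cancer"] * cancer_raw.n_samples + ["normal"] * ctrl.n_samples,
        ),
        threshold=fold_change,
    )
    passed_cross = sam_called & set(cross_gate)

    within_gate = sam_mod.fold_change_filter(tn, threshold=fold_change)
    passed_within = set(within_gate)

    final = [g for g in tn.gene_ids if g in passed_cross and g in passed_within]
    signs = {g: within_gate[g] for g in final}
    log.info(
        "DEG funnel: %d common genes -> %d SAM+FC cross -> %d after within-dataset FC",
        tn.n_genes,
        len(passed_cross),
        len(final),
    )
    return DegSet(final, signs, passed_cross, passed_within)


# ---------------------------------------------------------------------------
# dual radiomics screens


@dataclass
class ScreenResult:
    method: str  # "spearman_bh" | "sam_quant"
    gene_ids: list[str]
    feature_ids: list[str]
    significant: np.ndarray  # genes x features boolean

    def genes_with_evidence(self) -> list[str]:
        mask = self.significant.any(axis=1)
        return [g for g, m in zip(self.gene_ids, mask) if m]

    def features_for(self, gene: str) -> list[str]:
        i = self.gene_ids.index(gene)
        return [f for f, m in zip(self.feature_ids, self.significant[i]) if m]


def _check_alignment(expr: ExpressionMatrix, features: FeatureTable) -> FeatureTable:
    if set(expr.sample_ids) != set(features.sample_ids):
        raise ValueError("expression and feature table cover different samples")
    return features.subset_samples(expr.sample_ids)


def screen_spearman(
    expr: ExpressionMatrix, features: FeatureTable, fdr: float = 0.05
) -> ScreenResult:
    """Per-gene Spearman tests against every feature, BH within each gene's
    feature family (pair significant iff q <= fdr)."""
    features = _check_alignment(expr, features)
    n = expr.n_samples
    zg = sam_mod._rank_standardize(expr.values)
    zf = sam_mod._rank_standardize(features.values.T)
    rho = np.clip(zg @ zf.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, np.finfo(float).tiny, p)
    significant = np.zeros_like(p, dtype=bool)
    for i in range(p.shape[0]):
        significant[i] = bh_adjust(p[i], fdr).rejected
    return ScreenResult("spearman_bh", list(expr.gene_ids), list(features.feature_ids), significant)


def screen_samquant(
    expr: ExpressionMatrix,
    features: FeatureTable,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ScreenResult:
    """One quantitative SAM per feature (the feature as response); a pair is
    significant iff the gene is called at the delta achieving FDR <= fdr."""
    features = _check_alignment(expr, features)
    significant = np.zeros((expr.n_genes, features.n_features), dtype=bool)
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    seeds = np.random.SeedSequence(seed).generate_state(features.n_features)
    for j in range(features.n_features):
        res = sam_mod.sam_quantitative(
            expr,
            features.values[:, j],
            n_perm=n_perm,
            fdr_target=fdr,
            seed=int(seeds[j] % (2**31)),
        )
        for g in res.called:
            significant[pos[g], j] = True
    return ScreenResult("sam_quant", list(expr.gene_ids), list(features.feature_ids), significant)


@dataclass
class TranscriptomicSignature:
    gene_ids: list[str]
    signs: dict[str, int]
    evidence: pd.DataFrame  # per gene: n significant features per method

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        df = self.evidence.loc[self.evidence["gene_id"].isin(self.gene_ids)].copy()
        df["sign"] = [self.signs[g] for g in df["gene_id"]]
        return df[["gene_id", "sign", "n_spearman_features", "n_samquant_features"]]


def build_signature(
    degs: DegSet,
    spearman_screen: ScreenResult,
    samquant_screen: ScreenResult,
    granularity: str = "gene",
) -> TranscriptomicSignature:
    """Genes with significant feature associations under BOTH screens.

    `granularity='gene'` keeps a gene when each method flags at least one
    feature for it; `granularity='pair'` requires at least one (gene, feature)
    pair significant under both methods simultaneously.
    """
    if granularity not in ("gene", "pair"):
        raise ValueError("granularity must be 'gene' or 'pair'")
    if spearman_screen.gene_ids != samquant_screen.gene_ids:
        raise ValueError("screens were computed on different gene sets")
    genes = spearman_screen.gene_ids
    a = spearman_screen.significant
    b = samquant_screen.significant
    if granularity == "gene":
        keep = a.any(axis=1) & b.any(axis=1)
    else:
        if spearman_screen.feature_ids != samquant_screen.feature_ids:
            raise ValueError("screens were computed on different feature sets")
        keep = (a & b).any(axis=1)
    selected = [g for g, m in zip(genes, keep) if m and g in degs]
    if not selected:
        log.warning("empty transcriptomic signature: no gene passed both screens")
    evidence = pd.DataFrame(
        {
            "gene_id": genes,
            "n_spearman_features": a.sum(axis=1),
            "n_samquant_features": b.sum(axis=1),
        }
    )
    return TranscriptomicSignature(selected, {g: degs.signs[g] for g in selected}, evidence)
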