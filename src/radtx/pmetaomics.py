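"""Sparse linear "p-metaomics" models: meta-radiomic features regressed on
the transcriptomic signature with Lasso, tuned by leave-one-out cross
validation (LOOCV), gated on in-sample R-squared and a post-hoc gene
correlation check, and applicable to external expression cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .io import ExpressionMatrix
from .stats import bh_adjust, pearson, spearman

__all__ = [
    "PMetaomicsModel",
    "PMetaomicsSignature",
    "fit_lasso_loocv",
    "evaluate_model",
    "select_pmetaomics",
    "apply_models",
]

log = logging.getLogger(__name__)


@dataclass
class PMetaomicsModel:
    feature_id: str
    gene_ids: list[str]
    intercept: float
    coef: np.ndarray  # standardized-predictor scale, aligned with gene_ids
    lambda_: float
    x_mean: np.ndarray  # training per-gene transform
    x_sd: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    cv_predictions: np.ndarray | None = field(default=None, repr=False)

    @property
    def coefficients(self) -> dict[str, float]:
        """Sparse gene -> weight map (nonzero coefficients only)."""
        return {g: float(w) for g, w in zip(self.gene_ids, self.coef) if w != 0.0}

    def predict(self, X: np.ndarray, standardize: str = "train") -> np.ndarray:
        """Predict from a samples x genes matrix (column order = gene_ids).

        `standardize='train'` applies the stored training transform;
        `standardize='self'` z-scores genes within X (external cohorts, to
        neutralize batch location/scale).
        """
        X = np.asarray(X, dtype=float)
        if standardize == "train":
            Z = (X - self.x_mean) / self.x_sd
        elif standardize == "self":
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            Z = (X - X.mean(axis=0)) / sd
        else:
            raise ValueError("standardize must be 'train' or 'self'")
        return self.intercept + Z @ self.coef


def _lambda_grid(Z: np.ndarray, yc: np.ndarray, size: int = 100) -> np.ndarray:
    lam_max = np.abs(Z.T @ yc).max() / Z.shape[0]
    if lam_max <= 0:
        lam_max = 1e-6
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), size)


def _path_coefs(Z, y, alphas):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        out_alphas, coefs, _ = lasso_path(Z, y, alphas=alphas, max_iter=10000, tol=1e-6)
    order = np.argsort(out_alphas)[::-1]
    return out_alphas[order], coefs[:, order]


def fit_lasso_loocv(
    X: np.ndarray,
    y: np.ndarray,
    gene_ids: list[str] | None = None,
    feature_id: str = "",
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> PMetaomicsModel:
    """Lasso over a log-spaced lambda grid, tuned by LOOCV mean squared error.

    Predictors are z-scored (the transform is stored with the model) and the
    grid runs from lambda_max = max|X'y|/n down to 1e-4 * lambda_max. Ties in
    cross-validated MSE resolve to the larger (sparser) lambda; the final
    model is refit on all samples at the chosen lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError("LOOCV Lasso requires at least 5 samples")
    if y.shape != (n,):
        raise ValueError("y length must match the number of samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to model")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(p)]

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    Z = (X - x_mean) / x_sd
    yc = y - y.mean()

    alphas = np.sort(
        _lambda_grid(Z, yc) if lambda_grid is None else np.asarray(lambda_grid, float)
    )[::-1]

    preds = np.empty((n, alphas.size))
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Zt = Z[tr]
        yt = y[tr]
        zm = Zt.mean(axis=0)
        ym = yt.mean()
        out_alphas, coefs = _path_coefs(Zt - zm, yt - ym, alphas)
        preds[i] = (Z[i] - zm) @ coefs + ym
    cv_mse = ((preds - y[:, None]) ** 2).mean(axis=0)
    best_mse = cv_mse.min()
    chosen = int(np.nonzero(cv_mse == best_mse)[0][0])  # alphas descend: first = largest

    _, coefs_full = _path_coefs(Z, yc, alphas)
    coef = coefs_full[:, chosen]
    model = PMetaomicsModel(
        feature_id=feature_id,
        gene_ids=list(gene_ids),
        intercept=float(y.mean()),
        coef=coef,
        lambda_=float(alphas[chosen]),
        x_mean=x_mean,
        x_sd=x_sd,
        cv_predictions=preds[:, chosen],
    )
    model.diagnostics = evaluate_model(model, X, y)
    return model


def evaluate_model(model: PMetaomicsModel, X: np.ndarray, y: np.ndarray) -> dict:
    """In-sample R-squared, range-normalized RMSE, LOOCV NRMSE, Pearson r.

    nrmse = RMSE / (max(y) - min(y)); cv_nrmse uses the stored LOOCV held-out
    predictions; Pearson is between prediction and truth (NaN-flagged when
    the prediction is constant).
    """
    y = np.asarray(y, dtype=float)
    pred = model.predict(X)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    yrange = float(np.ptp(y))
    rmse = np.sqrt(ss_res / y.size)
    diag = {
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        "nrmse": rmse / yrange if yrange > 0 else np.nan,
        "cv_nrmse": np.nan,
        "pearson_r": np.nan,
        "pearson_p": np.nan,
    }
    if model.cv_predictions is not None and yrange > 0:
        cv_rmse = float(np.sqrt(((model.cv_predictions - y) ** 2).mean()))
        diag["cv_nrmse"] = cv_rmse / yrange
    if np.ptp(pred) > 0:
        res = pearson(pred, y)
        diag["pearson_r"] = res.rho
        diag["pearson_p"] = res.p_value
    return diag


@dataclass
class PMetaomicsSignature:
    models: list[PMetaomicsModel]
    rejected: list[tuple[str, str]]  # (feature_id, reason)
    gene_ids: list[str]
    r2_threshold: float

    @property
    def feature_ids(self) -> list[str]:
        return [m.feature_id for m in self.models]

    def diagnostics_table(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            rows.append(
                {
                    "feature_id": m.feature_id,
                    "lambda": m.lambda_,
                    "n_nonzero": int(np.count_nonzero(m.coef)),
                    **m.diagnostics,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "r2_threshold": self.r2_threshold,
            "gene_ids": list(self.gene_ids),
            "rejected": [list(r) for r in self.rejected],
            "models": [
                {
                    "feature_id": m.feature_id,
                    "gene_ids": list(m.gene_ids),
                    "intercept": m.intercept,
                    "coef": m.coef.tolist(),
                    "lambda": m.lambda_,
                    "x_mean": m.x_mean.tolist(),
                    "x_sd": m.x_sd.tolist(),
                    "diagnostics": {k: float(v) for k, v in m.diagnostics.items()},
                }
                for m in self.models
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PMetaomicsSignature":
        models = [
            PMetaomicsModel(
                feature_id=m["feature_id"],
                gene_ids=list(m["gene_ids"]),
                intercept=float(m["intercept"]),
                coef=np.asarray(m["coef"], dtype=float),
                lambda_=float(m["lambda"]),
                x_mean=np.asarray(m["x_mean"], dtype=float),
                x_sd=np.asarray(m["x_sd"], dtype=float),
                diagnostics=dict(m["diagnostics"]),
            )
            for m in d["models"]
        ]
        return cls(
            models,
            [tuple(r) for r in d["rejected"]],
            list(d["gene_ids"]),
            float(d["r2_threshold"]),
        )


def select_pmetaomics(
    models: list[PMetaomicsModel],
    expr: ExpressionMatrix,
    r2_threshold: float = 0.70,
    corr_fdr: float = 0.05,
) -> PMetaomicsSignature:
    """Keep models with r_squared > threshold whose predictions correlate
    with at least one signature gene (Spearman + BH within the model family).

    `expr` is the training expression restricted to the signature genes; the
    correlation check uses all signature genes, not only the nonzero support.
    """
    kept: list[PMetaomicsModel] = []
    rejected: list[tuple[str, str]] = []
    gene_ids = list(expr.gene_ids)
    for m in models:
        r2 = m.diagnostics.get("r_squared", np.nan)
        if not (r2 > r2_threshold):
            rejected.append((m.feature_id, "low_r2"))
            continue
        X = expr.subset_genes(m.gene_ids).values.T
        pred = m.predict(X)
        if np.ptp(pred) == 0:
            rejected.append((m.feature_id, "no_gene_correlation"))
            continue
        pvals = []
        for row in expr.values:
            if np.ptp(row) == 0:
                pvals.append(1.0)
            else:
                pvals.append(spearman(pred, row).p_value)
        if bh_adjust(np.asarray(pvals), corr_fdr).rejected.any():
            kept.append(m)
        else:
            rejected.append((m.feature_id, "no_gene_correlation"))
    for fid, reason in rejected:
        log.info("model %s rejected: %s", fid, reason)
    return PMetaomicsSignature(kept, rejected, gene_ids, r2_threshold)


def apply_models(
    sig: PMetaomicsSignature,
    expr: ExpressionMatrix,
    drop_incomplete_models: bool = False,
) -> pd.DataFrame:
    """Evaluate every retained model on an external expression cohort.

    Genes are z-scored within `expr` before the standardized-scale linear
    form is applied. A model whose genes are missing raises by default;
    `drop_incomplete_models=True` drops it with a logged list instead.
    Returns a samples x models table of simulated p-metaomics values.
    """
    available = set(expr.gene_ids)
    out = {}
    dropped = []
    for m in sig.models:
        support = [g for g, w in zip(m.gene_ids, m.coef) if w != 0.0]
        missing = [g for g in support if g not in available]
        if missing:
            if drop_incomplete_models:
                dropped.append((m.feature_id, missing))
                continue
            raise KeyError(
                f"model {m.feature_id!r} needs genes absent from the cohort: {missing[:5]}"
            )
        if not support:
            out[m.feature_id] = np.full(expr.n_samples, m.intercept)
            continue
        X = expr.subset_genes(support).values.T
        w = np.array([m.coefficients[g] for g in support])
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=0)) / sd
        out[m.feature_id] = m.intercept + Z @ w
    if dropped:
        log.warning("dropped %d incomplete models: %s", len(dropped), [d[0] for d in dropped])
    return pd.DataFrame(out, index=expr.sample_ids)
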