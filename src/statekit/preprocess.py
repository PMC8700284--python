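"""QC filtering, normalization, scaling, batch adjustment, covariate regression.

The pipeline order is: :func:`qc_filter` on raw counts, :func:`normalize_log`
(counts per 10,000, ln(1+x)), :func:`combat_adjust` (parametric empirical-
Bayes location/scale batch correction), :func:`regress_out` (e.g. raw Xist
counts per cell, to absorb residual sex signal), then :func:`scale_features`
(per-gene zero mean, unit variance) ahead of PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AnalysisConfig, CountMatrix, ExpressionMatrix

logger = logging.getLogger("statekit")

__all__ = ["QCReport", "qc_filter", "normalize_log", "scale_features",
           "combat_adjust", "regress_out"]


@dataclass
class QCReport:
    """Cell/gene filter accounting; rule counts refer to the pre-filter
    population, so one cell may appear under several rules."""

    cells_in: int = 0
    cells_out: int = 0
    genes_in: int = 0
    genes_out: int = 0
    rule_counts: dict = field(default_factory=dict)


def qc_filter(counts: CountMatrix, cells: pd.DataFrame,
              config: AnalysisConfig | None = None
              ) -> tuple[CountMatrix, pd.DataFrame, QCReport]:
    """Remove cells failing any QC rule, then rarely-detected genes.

    Rules (thresholds from ``config``): total UMIs < ``min_umi``; detected
    genes below the population floor (HSC gate: ``min_genes_hsc``, others:
    ``min_genes_mpp``); total counts above the population ceiling;
    mitochondrial UMI fraction > ``max_mito_frac``. Genes detected in fewer
    than ``min_cells_per_gene`` of the *surviving* cells are then dropped.
    """
    config = config or AnalysisConfig()
    if len(cells) != counts.shape[0]:
        raise ValueError("cell table inconsistent with matrix")
    totals = counts.cell_totals()
    ngenes = counts.genes_detected()
    is_hsc = (cells["gate"].astype(str) == "HSC").to_numpy()
    min_genes = np.where(is_hsc, config.min_genes_hsc, config.min_genes_mpp)
    max_counts = np.where(is_hsc, config.max_counts_hsc,
                          config.max_counts_mpp)
    if config.max_mito_frac is not None:
        if "mito" not in counts.features.columns:
            raise ValueError(
                "mitochondrial flags missing from feature metadata; flag "
                "features or disable max_mito_frac")
        mito_mask = counts.features["mito"].to_numpy(dtype=bool)
        mito_counts = np.asarray(
            counts.values[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(
                totals, 1), 0.0)
        fail_mito = mito_frac > config.max_mito_frac
    else:
        fail_mito = np.zeros(len(totals), dtype=bool)

    fails = {
        "min_umi": totals < config.min_umi,
        "min_genes": ngenes < min_genes,
        "max_counts": totals > max_counts,
        "mito": fail_mito,
    }
    keep_cells = ~np.logical_or.reduce(list(fails.values())) \
        if fails else np.ones(len(totals), dtype=bool)
    filtered = counts.subset_cells(keep_cells)
    cells_out = cells.loc[keep_cells].reset_index(drop=True)

    detected_in = np.asarray((filtered.values > 0).sum(axis=0)).ravel()
    keep_genes = detected_in >= config.min_cells_per_gene
    n_gene_drop = int((~keep_genes).sum())
    filtered = filtered.subset_features(keep_genes)

    report = QCReport(
        cells_in=counts.shape[0], cells_out=int(keep_cells.sum()),
        genes_in=counts.shape[1], genes_out=filtered.shape[1],
        rule_counts={**{k: int(v.sum()) for k, v in fails.items()},
                     "gene_prevalence": n_gene_drop})
    logger.info("qc_filter: %d/%d cells, %d/%d genes kept",
                report.cells_out, report.cells_in,
                report.genes_out, report.genes_in)
    return filtered, cells_out, report


def normalize_log(counts: CountMatrix, target_sum: float = 10000.0
                  ) -> ExpressionMatrix:
    """Counts per ``target_sum`` per cell, then ln(1 + x)."""
    totals = counts.cell_totals().astype(float)
    if np.any(totals == 0):
        bc = counts.barcodes[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"zero-total cell {bc!r}; run qc_filter first")
    X = counts.to_dense()
    X = np.log1p(target_sum * X / totals[:, None])
    return ExpressionMatrix(X, counts.barcodes, counts.feature_ids,
                            "cp10k_log",
                            [("normalize_log", {"target_sum": target_sum})])


def scale_features(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score with population SD (ddof 0); constant genes -> 0."""
    if expr.transform not in ("cp10k_log", "batch_adjusted"):
        raise ValueError(
            f"scale_features expects a log-scale matrix, got "
            f"{expr.transform!r}")
    mean = expr.values.mean(axis=0)
    sd = expr.values.std(axis=0, ddof=0)
    out = np.where(sd > 0, (expr.values - mean) / np.where(sd > 0, sd, 1.0),
                   0.0)
    return expr.with_values(out, "scaled", "scale_features")


def combat_adjust(expr: ExpressionMatrix, batch_labels,
                  covariates: pd.DataFrame | None = None
                  ) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Standard ComBat (normal prior on batch means, inverse-gamma on batch
    variances, iterated conditional posterior means, back-transform),
    applied to a log-scale matrix. A single batch is an identity. Delegates
    to ``scanpy.pp.combat``.
    """
    batch = pd.Series(np.asarray(batch_labels, dtype=object),
                      index=expr.barcodes)
    if len(batch) != expr.shape[0]:
        raise ValueError("one batch label per cell required")
    sizes = batch.value_counts()
    if (sizes < 2).any():
        bad = list(sizes.index[sizes < 2])
        raise ValueError(f"batch(es) with a single cell: {bad}")
    if expr.transform not in ("cp10k_log", "batch_adjusted"):
        raise ValueError("combat_adjust expects a log-scale matrix")
    if len(sizes) == 1:
        return expr.with_values(expr.values.copy(), "batch_adjusted",
                                "combat_adjust", n_batches=1)
    import anndata as ad
    import scanpy as sc
    adata = ad.AnnData(
        X=expr.values.copy(),
        obs=pd.DataFrame({"batch": pd.Categorical(batch.to_numpy())},
                         index=[str(b) for b in expr.barcodes]))
    kw = {}
    if covariates is not None:
        for c in covariates.columns:
            adata.obs[c] = np.asarray(covariates[c])
        kw["covariates"] = list(covariates.columns)
    adjusted = sc.pp.combat(adata, key="batch", inplace=False, **kw)
    return expr.with_values(np.asarray(adjusted), "batch_adjusted",
                            "combat_adjust", n_batches=int(len(sizes)))


def regress_out(expr: ExpressionMatrix, covariate_values) -> ExpressionMatrix:
    """Remove per-gene simple linear dependence on one numeric covariate.

    Output is residual plus fitted intercept, so each gene's grand mean is
    preserved. A constant covariate yields the identity with a warning.
    """
    x = np.asarray(covariate_values, dtype=float)
    if x.shape != (expr.shape[0],):
        raise ValueError("one covariate value per cell required")
    xc = x - x.mean()
    ssx = float(xc @ xc)
    if ssx == 0.0:
        logger.warning("regress_out: constant covariate, returning input")
        return expr.with_values(expr.values.copy(), expr.transform,
                                "regress_out", constant_covariate=True)
    beta = (xc @ expr.values) / ssx          # per-gene slope
    out = expr.values - np.outer(xc, beta)
    return expr.with_values(out, expr.transform, "regress_out")
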