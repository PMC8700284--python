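"""Hurdle-model differential expression for zero-inflated single-cell data.

Each gene's normalized-log expression is modeled in two parts: a logistic
regression for whether the gene is detected at all (the discrete hurdle) and
a Gaussian linear model for the expression level in the detecting cells (the
continuous part), both on the same design matrix. A contrast is tested with
a likelihood-ratio test combining both parts (chi-squared, summed degrees of
freedom), which captures shifts in detection rate, in level, or in both.
Covariates — typically the standardized number of detected genes per cell
(the cellular detection rate) and sex — are adjusted for in both parts.

The reported fold change is defined on the combined hurdle expectation
``P(detected) * E[level | detected]`` at reference covariate levels; the
continuous-part coefficient is also emitted. Genes detected in fewer than
``min_expr_frac`` of cells are not tested. Benjamini-Hochberg controls the
FDR across tested genes, and pass flags are reported at fold-change cutoffs
of none, 1.2, and 1.5 at the configured FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix

logger = logging.getLogger("statekit")

__all__ = ["HurdleFit", "fit_hurdle_gene", "differential_expression",
           "de_within_clusters", "signature_groups"]

_LN2 = np.log(2.0)
_COEF_CAP = 10.0


@dataclass
class HurdleFit:
    """Maximum-likelihood fit of the two-part model for one gene."""

    coef_discrete: np.ndarray
    coef_continuous: np.ndarray | None
    sigma2: float | None
    loglik_discrete: float
    loglik_continuous: float
    n_detected: int
    separation_flag: bool = False
    continuous_skipped: bool = False

    @property
    def loglik(self) -> float:
        return self.loglik_discrete + self.loglik_continuous


def _logistic_ml(z: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, bool]:
    """Unpenalized logistic ML; coefficients capped at +/-10 under
    (quasi-)separation, flagged."""
    if z.all() or not z.any():
        # intercept-only degeneracy: detection probability 0 or 1
        beta = np.zeros(X.shape[1])
        beta[0] = _COEF_CAP if z.all() else -_COEF_CAP
        return beta, True
    clf = LogisticRegression(C=np.inf, fit_intercept=False,
                             solver="newton-cholesky", max_iter=200,
                             tol=1e-10)
    with warnings.catch_warnings():
        # (quasi-)separation triggers line-search fallbacks; handled below
        # by the coefficient cap
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, z.astype(int))
    beta = clf.coef_.ravel()
    flagged = bool(np.any(np.abs(beta) > _COEF_CAP))
    if flagged:
        beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
    return beta, flagged


def _logistic_loglik(z, X, beta) -> float:
    eta = X @ beta
    return float(np.sum(z * eta - np.logaddexp(0.0, eta)))


def fit_hurdle_gene(y: np.ndarray, X: np.ndarray) -> HurdleFit:
    """Fit the hurdle model for one gene.

    ``y`` is non-negative log-expression with exact zeros meaning
    undetected; ``X`` is the design matrix with an intercept column. The
    continuous part is skipped (flagged) below 3 detected cells.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    z = y > 0
    beta_d, sep = _logistic_ml(z, X)
    ll_d = _logistic_loglik(z, X, beta_d)
    if z.sum() < 3:
        return HurdleFit(beta_d, None, None, ll_d, 0.0, int(z.sum()),
                         separation_flag=sep, continuous_skipped=True)
    Xd, yd = X[z], y[z]
    beta_c, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
    resid = yd - Xd @ beta_c
    m = len(yd)
    sigma2 = float(resid @ resid) / m          # ML variance
    sigma2 = max(sigma2, 1e-12)
    ll_c = -0.5 * m * (np.log(2 * np.pi * sigma2) + 1.0)
    return HurdleFit(beta_d, beta_c, sigma2, ll_d, ll_c, m,
                     separation_flag=sep)


def _build_design(group01: np.ndarray,
                  covariates: pd.DataFrame | None) -> np.ndarray:
    """[intercept | group | standardized/encoded covariates]."""
    cols = [np.ones(len(group01)), group01.astype(float)]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                v = col.to_numpy(dtype=float)
                sd = v.std(ddof=0)
                cols.append((v - v.mean()) / sd if sd > 0 else
                            np.zeros_like(v))
            else:
                dummies = pd.get_dummies(col, drop_first=True)
                for d in dummies.columns:
                    cols.append(dummies[d].to_numpy(dtype=float))
    return np.column_stack(cols)


def differential_expression(expr: ExpressionMatrix, groups,
                            covariates: pd.DataFrame | None = None,
                            reference: str | None = None,
                            min_expr_frac: float = 0.05,
                            fdr: float = 0.01) -> pd.DataFrame:
    """Hurdle-model DE between exactly two groups.

    Returns one row per tested gene: detection fractions, hurdle
    coefficients, the combined-expectation ``log2fc`` (and the
    continuous-part ``log2fc_detected``), LRT statistic/df/p, BH ``q`` and
    pass flags at fold-change cutoffs {none, 1.2, 1.5}.
    """
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference {reference!r} not a group level")
        levels = [reference] + [l for l in levels if l != reference]
    g = (groups == levels[1]).astype(float)
    if g.sum() == 0 or g.sum() == len(g):
        raise ValueError("a group has zero cells")
    X_full = _build_design(g, covariates)
    X_red = np.delete(X_full, 1, axis=1)

    Y = expr.values
    detect = Y > 0
    frac_all = detect.mean(axis=0)
    tested = np.flatnonzero(frac_all >= min_expr_frac)
    rows = []
    for j in tested:
        y = Y[:, j]
        full = fit_hurdle_gene(y, X_full)
        red_d, _ = _logistic_ml(y > 0, X_red)
        ll_red_d = _logistic_loglik(y > 0, X_red, red_d)
        lam = 2.0 * (full.loglik_discrete - ll_red_d)
        df = 1
        if not full.continuous_skipped:
            z = y > 0
            Xd, yd = X_red[z], y[z]
            beta_r, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
            resid = yd - Xd @ beta_r
            s2 = max(float(resid @ resid) / len(yd), 1e-12)
            ll_red_c = -0.5 * len(yd) * (np.log(2 * np.pi * s2) + 1.0)
            lam += 2.0 * (full.loglik_continuous - ll_red_c)
            df += 1
        lam = max(lam, 0.0)
        p = float(stats.chi2.sf(lam, df))
        # combined hurdle expectation at reference covariates (0 after
        # standardization), per group, in ln units -> log2
        bd, bc = full.coef_discrete, full.coef_continuous
        p0 = 1.0 / (1.0 + np.exp(-bd[0]))
        p1 = 1.0 / (1.0 + np.exp(-(bd[0] + bd[1])))
        if bc is not None:
            mu0, mu1 = bc[0], bc[0] + bc[1]
            log2fc = (p1 * mu1 - p0 * mu0) / _LN2
            log2fc_detected = bc[1] / _LN2
        else:
            log2fc = np.nan
            log2fc_detected = np.nan
        rows.append({
            "gene": expr.genes[j],
            "frac_detected_ref": float(detect[g == 0, j].mean()),
            "frac_detected_alt": float(detect[g == 1, j].mean()),
            "coef_discrete": float(bd[1]),
            "coef_continuous": float(bc[1]) if bc is not None else np.nan,
            "log2fc": float(log2fc),
            "log2fc_detected": float(log2fc_detected),
            "lrt_stat": float(lam),
            "df": int(df),
            "p": p,
            "separation_flag": full.separation_flag,
        })
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no genes pass the expression-fraction filter")
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    sig = table["q"] <= fdr
    table["pass_none"] = sig
    table["pass_1.2"] = sig & (table["log2fc"].abs() >= np.log2(1.2))
    table["pass_1.5"] = sig & (table["log2fc"].abs() >= np.log2(1.5))
    table.attrs["contrast"] = (levels[1], levels[0])
    return table.sort_values(["p", "gene"], kind="stable"
                             ).reset_index(drop=True)


def de_within_clusters(expr: ExpressionMatrix, groups, clusters,
                       covariates: pd.DataFrame | None = None,
                       min_cells_per_arm: int = 20, **kw
                       ) -> tuple[dict, list]:
    """Run the contrast separately inside each cluster with at least
    ``min_cells_per_arm`` cells in both arms; smaller clusters are skipped
    and reported."""
    clusters = np.asarray(clusters)
    groups = np.asarray(groups)
    results, skipped = {}, []
    for c in pd.unique(clusters):
        mask = clusters == c
        sizes = pd.Series(groups[mask]).value_counts()
        if len(sizes) < 2 or sizes.min() < min_cells_per_arm:
            skipped.append(c)
            continue
        sub = expr.subset_cells(mask)
        cov = covariates.loc[mask].reset_index(drop=True) \
            if covariates is not None else None
        results[c] = differential_expression(sub, groups[mask], cov, **kw)
    return results, skipped


def signature_groups(cluster_means: pd.DataFrame, n_groups: int = 2
                     ) -> tuple[pd.Series, list, np.ndarray]:
    """Group DE genes by the shape of their cross-cluster profile.

    ``cluster_means`` is genes x clusters average expression. Profiles are
    z-scored per gene (constant rows become zero vectors and are kept) and
    clustered by single-linkage agglomeration with Euclidean distance.
    Returns (flat groups at ``n_groups``, leaf order, linkage matrix).
    """
    if len(cluster_means) < 1:
        raise ValueError("no genes to group")
    M = cluster_means.to_numpy(dtype=float)
    if len(cluster_means) == 1:
        return (pd.Series([1], index=cluster_means.index),
                list(cluster_means.index), np.empty((0, 4)))
    mean = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=0, keepdims=True)
    Z = np.where(sd > 0, (M - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    link = linkage(Z, method="single", metric="euclidean")
    order = [cluster_means.index[i] for i in leaves_list(link)]
    flat = fcluster(link, t=n_groups, criterion="maxclust")
    return pd.Series(flat, index=cluster_means.index), order, link
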