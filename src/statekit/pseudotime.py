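"""Diffusion pseudotime along a continuous cell-state manifold.

A diffusion map is built from a Gaussian kernel with per-cell adaptive
widths on PCA coordinates; the kernel is symmetrized, density-normalized
(anisotropy exponent 1, removing sampling-density bias) and row-normalized
into a Markov transition matrix whose spectrum is obtained through the
symmetric conjugate. Diffusion pseudotime from a root cell x0 is

    dpt(x, x0)^2 = sum_i (lambda_i / (1 - lambda_i))^2
                   (psi_i(x) - psi_i(x0))^2

over the non-unit eigenpairs, rescaled to [0, 1]. The root is the cell with
the highest summed *raw* count of activation markers (Nr4a1/Nr4a2/Hes1 by
default), anchoring pseudotime at the most activated cell. Downstream
helpers bin cells into pseudotime quantiles, estimate fixed-bandwidth kernel
densities of the pseudotime distribution, and test condition-wise
distribution shifts with the Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.neighbors import NearestNeighbors

from .cluster_select import pca_embed
from .core_io import CountMatrix, ExpressionMatrix

logger = logging.getLogger("statekit")

__all__ = ["DiffusionMap", "diffusion_map", "select_root_cell",
           "dpt_from_root", "pseudotime_density", "pseudotime_shift_test",
           "binned_profiles"]


@dataclass
class DiffusionMap:
    """Eigenpairs of the diffusion transition matrix.

    ``psi`` columns are right eigenvectors of the transition matrix,
    orthonormal under the stationary weighting; eigenvalues are in
    descending order with ``lambda_0 = 1``.
    """

    eigenvalues: np.ndarray
    psi: np.ndarray            # cells x (n_comps + 1)
    barcodes: pd.Index
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.eigenvalues[0] - 1.0) > 1e-6:
            raise ValueError("leading eigenvalue must be 1")


def _adaptive_kernel(coords: np.ndarray, k: int) -> np.ndarray:
    """Dense symmetrized, density-normalized Gaussian kernel."""
    n = coords.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # per-cell width: distance to the median kNN neighbor
    sigma = np.maximum(dist[:, max(1, (k + 1) // 2)], 1e-12)
    W = np.zeros((n, n))
    for i in range(n):
        j = idx[i, 1:]
        W[i, j] = np.exp(-dist[i, 1:] ** 2 / (sigma[i] * sigma[j]))
    W = np.maximum(W, W.T)                     # symmetrized union of kNN
    q = W.sum(axis=1)
    q[q == 0] = 1.0
    K = W / np.outer(q, q)                     # anisotropy exponent 1
    return K


def diffusion_map(expr, k: int = 30, n_comps: int = 10,
                  n_pcs: int = 50) -> DiffusionMap:
    """Diffusion map of a (re-embedded) expression subset.

    ``expr`` may be an :class:`ExpressionMatrix` (PCA is recomputed on the
    subset), a raw coordinate array, or an Embedding. A disconnected kernel
    graph is allowed with a warning; its extra unit eigenvalues are flagged
    and excluded from pseudotime.
    """
    if isinstance(expr, ExpressionMatrix):
        coords = pca_embed(expr, min(n_pcs, min(expr.shape) - 1)).coords
        barcodes = expr.barcodes
    else:
        coords = np.asarray(getattr(expr, "coords", expr), dtype=float)
        barcodes = pd.Index([f"cell{i}" for i in range(coords.shape[0])])
    n = coords.shape[0]
    if n_comps + 1 > n:
        raise ValueError(f"need >= {n_comps + 1} cells for {n_comps} "
                         "components")
    K = _adaptive_kernel(coords, k)
    d = K.sum(axis=1)
    d[d == 0] = 1.0
    inv_sqrt = 1.0 / np.sqrt(d)
    S = K * np.outer(inv_sqrt, inv_sqrt)       # symmetric conjugate of T
    evals, evecs = linalg.eigh(S, subset_by_index=[n - (n_comps + 1),
                                                   n - 1])
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs * inv_sqrt[:, None]
    # deterministic sign
    top = np.abs(psi).argmax(axis=0)
    psi *= np.sign(psi[top, np.arange(psi.shape[1])])
    n_unit = int(np.sum(evals > 1.0 - 1e-10))
    if n_unit > 1:
        logger.warning("diffusion_map: kernel graph has %d components",
                       n_unit)
    return DiffusionMap(np.clip(evals, -1.0, 1.0), psi, barcodes,
                        {"k": k, "n_comps": n_comps, "n_pcs": n_pcs,
                         "n_unit_eigenvalues": n_unit})


def select_root_cell(raw_counts: CountMatrix,
                     marker_genes=("Nr4a1", "Nr4a2", "Hes1")) -> str:
    """Barcode of the cell maximizing the summed raw marker counts; ties go
    to the lexicographically lowest barcode."""
    missing = [g for g in marker_genes if g not in raw_counts.feature_ids]
    if missing:
        raise ValueError(f"marker genes absent: {missing}")
    cols = raw_counts.feature_ids.get_indexer(pd.Index(marker_genes))
    sums = np.asarray(raw_counts.values[:, cols].sum(axis=1)).ravel()
    if sums.max() == 0:
        raise ValueError("all marker counts are zero")
    best = sums.max()
    candidates = raw_counts.barcodes[sums == best]
    return str(sorted(map(str, candidates))[0])


def dpt_from_root(dm: DiffusionMap, root) -> pd.Series:
    """Per-cell diffusion pseudotime in [0, 1] from the root cell."""
    if isinstance(root, str):
        if root not in dm.barcodes:
            raise ValueError(f"root {root!r} not in the cell set")
        root = dm.barcodes.get_loc(root)
    evals, psi = dm.eigenvalues, dm.psi
    usable = evals < 1.0 - 1e-10
    if (~usable).sum() > 1:
        logger.warning("dpt_from_root: excluding %d unit eigenvalues "
                       "(disconnected components)", int((~usable).sum()))
    lam = evals[usable]
    delta = psi[:, usable] - psi[root, usable]
    d2 = ((lam / (1.0 - lam)) ** 2 * delta ** 2).sum(axis=1)
    pt = np.sqrt(d2)
    if pt.max() > 0:
        pt = pt / pt.max()
    out = pd.Series(pt, index=dm.barcodes, name="dpt")
    out.attrs["root"] = str(dm.barcodes[root])
    return out


def pseudotime_density(pt, bandwidth: float = 0.02,
                       grid: np.ndarray | None = None) -> pd.Series:
    """Fixed-bandwidth Gaussian KDE of pseudotimes on a [0, 1] grid
    (step 0.001 by default); no boundary correction."""
    pt = np.asarray(pt, dtype=float)
    if pt.size == 0:
        raise ValueError("empty pseudotime vector")
    if grid is None:
        grid = np.arange(0.0, 1.0 + 1e-9, 0.001)
    dens = np.exp(-0.5 * ((grid[:, None] - pt[None, :]) / bandwidth) ** 2
                  ).sum(axis=1) / (pt.size * bandwidth * np.sqrt(2 * np.pi))
    return pd.Series(dens, index=grid, name="density")


def pseudotime_shift_test(pt_a, pt_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two pseudotime samples.

    Exact null for combined n <= 20 without ties, tie-corrected normal
    approximation otherwise.
    """
    a, b = np.asarray(pt_a, dtype=float), np.asarray(pt_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def binned_profiles(pt, expr: ExpressionMatrix, genes,
                    n_bins: int = 10) -> pd.DataFrame:
    """Mean expression per pseudotime quantile bin.

    Cells are ranked by ascending pseudotime and split into ``n_bins``
    equal-count bins (remainders go to the earliest bins); bin 1 holds the
    lowest pseudotimes. Returns bins x genes mean normalized-log
    expression.
    """
    pt = np.asarray(pt, dtype=float)
    n = pt.size
    if n < n_bins:
        raise ValueError(f"need >= {n_bins} cells")
    missing = [g for g in genes if g not in expr.genes]
    if missing:
        raise ValueError(f"genes absent: {missing}")
    order = np.argsort(pt, kind="stable")
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    cols = expr.genes.get_indexer(pd.Index(genes))
    rows = []
    for b in range(n_bins):
        cells = order[bounds[b]:bounds[b + 1]]
        rows.append(expr.values[np.ix_(cells, cols)].mean(axis=0))
    return pd.DataFrame(rows, index=pd.RangeIndex(1, n_bins + 1,
                                                  name="bin"),
                        columns=list(genes))
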