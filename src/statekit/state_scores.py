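"""Per-cell transcriptional scores for marker-gene sets.

The score of a gene set in a cell is the mean normalized-log expression of
the set minus the mean expression of a bin-matched random reference set:
genes are binned by average expression across cells, and each set gene draws
its controls from its own bin, so the score is centered against genes of
comparable abundance rather than against the whole transcriptome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix

logger = logging.getLogger("statekit")

__all__ = ["ScoreVector", "gene_set_score", "score_group_comparison"]


@dataclass
class ScoreVector:
    scores: pd.Series
    gene_set_id: str
    n_bins: int
    ctrl_per_gene: int
    seed: int


def gene_set_score(expr: ExpressionMatrix, gene_set, n_bins: int = 25,
                   ctrl_per_gene: int = 1, seed: int = 0,
                   gene_set_id: str = "score") -> ScoreVector:
    """Bin-matched reference score per cell.

    Genes are ranked by mean expression and cut into ``n_bins`` equal-size
    bins; for each set gene, ``ctrl_per_gene`` reference genes are sampled
    without replacement from its bin (set members excluded). Score =
    mean(set) - mean(reference), per cell. Deterministic given ``seed``.
    """
    genes = expr.genes
    present = [g for g in gene_set if g in genes]
    if not present:
        raise ValueError("gene set empty or entirely absent from matrix")
    missing = set(gene_set) - set(present)
    if missing:
        logger.warning("gene_set_score: %d set genes absent", len(missing))
    rng = np.random.default_rng(seed)
    mean_expr = pd.Series(expr.values.mean(axis=0), index=genes)
    # equal-size bins on the rank of mean expression
    ranks = mean_expr.rank(method="first")
    bins = pd.cut(ranks, bins=n_bins, labels=False)
    set_idx = pd.Index(present)
    ctrl: list[str] = []
    for b in sorted(set(bins[set_idx])):
        members = bins.index[bins == b]
        pool = members.difference(set_idx)
        need = ctrl_per_gene * int((bins[set_idx] == b).sum())
        if len(pool) == 0:
            continue
        take = min(need, len(pool))
        ctrl.extend(rng.choice(pool, size=take, replace=False))
    if not ctrl:
        raise ValueError("no reference genes available outside the set")
    set_mean = expr.values[:, genes.get_indexer(set_idx)].mean(axis=1)
    ctrl_mean = expr.values[:, genes.get_indexer(pd.Index(ctrl))].mean(axis=1)
    scores = pd.Series(set_mean - ctrl_mean, index=expr.barcodes,
                       name=gene_set_id)
    return ScoreVector(scores, gene_set_id, n_bins, ctrl_per_gene, seed)


def score_group_comparison(scores, labels
                           ) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across groups plus Tukey-HSD pairwise comparisons.

    Groups with fewer than two members are excluded with a warning. Returns
    (F, p, table) where the table has one row per group pair with the mean
    difference and Tukey-adjusted p (studentized range).
    """
    values = scores.scores if isinstance(scores, ScoreVector) else \
        pd.Series(scores)
    labels = np.asarray(labels)
    groups, keys = [], []
    for key in pd.unique(labels):
        grp = np.asarray(values)[labels == key]
        if len(grp) < 2:
            logger.warning("score_group_comparison: group %r has < 2 "
                           "members, excluded", key)
            continue
        groups.append(grp)
        keys.append(key)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    F, p = stats.f_oneway(*groups)
    if np.allclose([g.mean() for g in groups], groups[0].mean()) and \
            np.isnan(F):
        F, p = 0.0, 1.0
    tuk = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append((keys[i], keys[j],
                         float(groups[i].mean() - groups[j].mean()),
                         float(tuk.pvalue[i, j])))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff",
                                        "p_adj"])
    return float(F), float(p), table
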