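"""Top-N gene lists and hypergeometric overlap/over-representation testing.

Cluster-marker and treatment-induced gene lists are compared pairwise by the
size of their intersection; significance comes from the upper tail of the
hypergeometric distribution (equivalently a one-sided Fisher exact test)
over a stated gene universe, with Benjamini-Hochberg correction across all
cells of the comparison matrix. The same machinery serves generic
over-representation against user-supplied pathway collections (GMT input).

The universe defaults to the genes surviving QC in the analyzed matrix; p
magnitudes depend directly on this choice, so it is explicit everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("statekit")

__all__ = ["GeneList", "OverlapMatrix", "top_n_genes",
           "hypergeometric_tail", "overlap_enrichment_matrix", "read_gmt"]


@dataclass
class GeneList:
    """Ordered, unique gene ids with provenance."""

    genes: list
    source: str = ""
    ranking_key: str = "p"
    n_requested: int = 100
    truncated: bool = False      # fewer than n available

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene list contains duplicates")
        if len(self.genes) > self.n_requested:
            raise ValueError("list longer than requested N")

    def __len__(self) -> int:
        return len(self.genes)


def top_n_genes(de: pd.DataFrame, n: int = 100, direction: str = "up",
                source: str = "") -> GeneList:
    """Top induced (or repressed) genes of one DE contrast.

    Genes with positive (``direction='up'``) or negative (``'down'``)
    ``log2fc`` are ranked by ascending p, then descending |log2fc|, then
    gene id, and truncated to ``n``.
    """
    if de.empty:
        raise ValueError("empty DE table")
    if direction == "up":
        sub = de[de["log2fc"] > 0]
    elif direction == "down":
        sub = de[de["log2fc"] < 0]
    else:
        raise ValueError("direction must be 'up' or 'down'")
    sub = sub.assign(_absfc=sub["log2fc"].abs()).sort_values(
        ["p", "_absfc", "gene"], ascending=[True, False, True],
        kind="stable")
    genes = sub["gene"].tolist()[:n]
    return GeneList(genes, source=source, ranking_key="p,|log2fc|,gene",
                    n_requested=n, truncated=len(genes) < n)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeom(universe N, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent arguments k={k}, K={K}, n={n}, "
                         f"N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class OverlapMatrix:
    overlap: pd.DataFrame      # intersection sizes
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame  # q < threshold
    universe_size: int
    q_threshold: float = 0.01


def overlap_enrichment_matrix(lists_a: dict, lists_b: dict, universe,
                              q_threshold: float = 0.01) -> OverlapMatrix:
    """All-pairs overlap counts and hypergeometric enrichment.

    ``lists_a``/``lists_b`` map names to gene lists (or :class:`GeneList`);
    every member must belong to ``universe``. BH correction runs across all
    cells of the matrix; cells with ``q < q_threshold`` are marked
    significant.
    """
    universe = set(universe)
    N = len(universe)

    def as_set(lst):
        genes = lst.genes if isinstance(lst, GeneList) else list(lst)
        out = set(genes)
        stray = out - universe
        if stray:
            raise ValueError(
                f"genes outside universe: {sorted(stray)[:10]}")
        return out

    sets_a = {name: as_set(lst) for name, lst in lists_a.items()}
    sets_b = {name: as_set(lst) for name, lst in lists_b.items()}
    names_a, names_b = list(sets_a), list(sets_b)
    k = pd.DataFrame(0, index=names_a, columns=names_b, dtype=int)
    p = pd.DataFrame(1.0, index=names_a, columns=names_b)
    for a in names_a:
        for b in names_b:
            kk = len(sets_a[a] & sets_b[b])
            k.loc[a, b] = kk
            p.loc[a, b] = hypergeometric_tail(kk, len(sets_a[a]),
                                              len(sets_b[b]), N)
    flat_q = multipletests(p.to_numpy().ravel(), method="fdr_bh")[1]
    q = pd.DataFrame(flat_q.reshape(p.shape), index=names_a,
                     columns=names_b)
    return OverlapMatrix(k, p, q, q < q_threshold, N, q_threshold)


def read_gmt(path) -> dict:
    """Read a GMT pathway collection: name -> gene list (description
    column dropped)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
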