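"""scATAC fragment-level processing.

Peak summits (from an external caller) are extended to fixed-width windows,
fragments are counted into peaks per cell barcode, cells are filtered on
in-peak fragment totals, sex is called from chrY fragment presence, the
peak x cell matrix is embedded by TF-IDF + truncated SVD (LSI), and
per-cell TF motif-activity scores (an input, e.g. chromVAR deviations) are
tested for differential activity between clusters with a logistic
regression LRT and Bonferroni correction.

All intervals are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.linalg import svds

from .cluster_select import Embedding
from .core_io import CountMatrix
from .hurdle_de import _logistic_loglik, _logistic_ml

logger = logging.getLogger("statekit")

__all__ = ["PeakSet", "extend_summits", "count_fragments_in_peaks",
           "atac_cell_filter", "classify_sex_by_chrY", "tfidf_lsi",
           "differential_activity"]


@dataclass
class PeakSet:
    """Fixed-width peak intervals; overlapping extensions are merged and
    flagged."""

    intervals: pd.DataFrame       # chrom, start, end, name, merged
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.intervals["name"])


def extend_summits(summits: pd.DataFrame, width: int = 300,
                   chrom_sizes: dict | None = None) -> PeakSet:
    """Extend 1-bp summits to ``width``-bp windows centered on the summit.

    A summit at position s becomes ``[s - width/2, s + width/2)``, clipped
    at 0 and at the chromosome end when sizes are given. Overlapping
    extended windows are merged into one flagged interval.
    """
    if ((summits["end"] - summits["start"]) != 1).any():
        raise ValueError("summits must be 1-bp BED intervals")
    half = width // 2
    ext = summits.copy()
    ext["start"] = (summits["start"] - half).clip(lower=0)
    ext["end"] = summits["start"] + (width - half)
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            m = ext["chrom"] == chrom
            ext.loc[m, "end"] = ext.loc[m, "end"].clip(upper=size)
    ext = ext.sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    for chrom, grp in ext.groupby("chrom", sort=True):
        cur_s, cur_e, n_in = None, None, 0
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e, n_in = s, e, 1
            elif s < cur_e:
                cur_e = max(cur_e, e)
                n_in += 1
            else:
                rows.append((chrom, cur_s, cur_e, n_in > 1))
                cur_s, cur_e, n_in = s, e, 1
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, n_in > 1))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "merged"])
    out["name"] = [f"{c}:{s}-{e}" for c, s, e in
                   zip(out["chrom"], out["start"], out["end"])]
    n_merged = int(out["merged"].sum())
    if n_merged:
        logger.warning("extend_summits: %d merged interval(s)", n_merged)
    return PeakSet(out[["chrom", "start", "end", "name", "merged"]],
                   {"width": width, "n_merged": n_merged})


def count_fragments_in_peaks(fragments: pd.DataFrame, peaks: PeakSet,
                             barcodes=None) -> tuple[CountMatrix, dict]:
    """Peak x cell counting by >= 1 bp interval overlap.

    Each fragment contributes its ``support`` to every peak it overlaps
    (a fragment spanning two merged-adjacent peaks counts in each).
    Fragments on chromosomes absent from the peak set are ignored and
    tallied in the report. Returns (CountMatrix with peak modality,
    report).
    """
    iv = peaks.intervals
    if barcodes is not None:
        bc_index = pd.Index(barcodes)
        fragments = fragments[fragments["barcode"].isin(set(bc_index))]
    else:
        bc_index = pd.Index(pd.unique(fragments["barcode"]))
    bc_pos = {b: i for i, b in enumerate(bc_index)}
    peak_offset, peak_arrays = {}, {}
    for chrom, grp in iv.groupby("chrom"):
        peak_offset[chrom] = grp.index.to_numpy()
        peak_arrays[chrom] = (grp["start"].to_numpy(),
                              grp["end"].to_numpy())
    rows_i, cols_j, vals = [], [], []
    ignored = {}
    for chrom, grp in fragments.groupby("chrom"):
        if chrom not in peak_arrays:
            ignored[chrom] = int(grp["support"].sum())
            continue
        starts, ends = peak_arrays[chrom]
        pid = peak_offset[chrom]
        fs = grp["start"].to_numpy()
        fe = grp["end"].to_numpy()
        fbc = grp["barcode"].to_numpy()
        fsup = grp["support"].to_numpy()
        # peaks are sorted, non-overlapping: the overlapping range is
        # [first peak with end > frag_start, last peak with start < frag_end]
        lo = np.searchsorted(ends, fs, side="right")
        hi = np.searchsorted(starts, fe, side="left")
        for f in range(len(fs)):
            for p in range(lo[f], hi[f]):
                rows_i.append(bc_pos[fbc[f]])
                cols_j.append(pid[p])
                vals.append(fsup[f])
    mat = sp.coo_matrix((vals, (rows_i, cols_j)),
                        shape=(len(bc_index), len(iv))).tocsr()
    features = iv.set_index("name")[["chrom", "start", "end"]]
    cm = CountMatrix(mat, bc_index, features, "peak")
    report = {"ignored_chrom_support": ignored,
              "total_counted": int(mat.sum())}
    return cm, report


def atac_cell_filter(peak_counts: CountMatrix, min_frag: int = 1000,
                     max_frag: int = 20000
                     ) -> tuple[CountMatrix, dict]:
    """Keep cells with in-peak fragment totals in [min_frag, max_frag]
    (boundary values kept)."""
    if peak_counts.modality != "peak":
        raise ValueError("peak-modality matrix required")
    totals = peak_counts.cell_totals()
    keep = (totals >= min_frag) & (totals <= max_frag)
    report = {"cells_in": peak_counts.shape[0],
              "cells_out": int(keep.sum()),
              "removed_low": int((totals < min_frag).sum()),
              "removed_high": int((totals > max_frag).sum())}
    return peak_counts.subset_cells(keep), report


def classify_sex_by_chrY(source, y_chrom: str = "chrY",
                         min_reads: int = 1) -> pd.Series:
    """Per-cell sex from chrY fragment presence.

    ``source`` is either a fragments DataFrame or a peak-modality
    CountMatrix with ``chrom`` feature metadata. Cells with >= ``min_reads``
    chrY reads are called male, others female.
    """
    if isinstance(source, CountMatrix):
        if "chrom" not in source.features.columns:
            raise ValueError("chromosome metadata required")
        ymask = (source.features["chrom"] == y_chrom).to_numpy()
        if not ymask.any():
            raise ValueError(f"no {y_chrom} features present; cannot "
                             "classify sex")
        ycounts = np.asarray(source.values[:, ymask].sum(axis=1)).ravel()
        calls = np.where(ycounts >= min_reads, "male", "female")
        return pd.Series(calls, index=source.barcodes, name="sex")
    frags = source
    if not (frags["chrom"] == y_chrom).any():
        raise ValueError(f"no {y_chrom} fragments present; cannot "
                         "classify sex")
    y = frags[frags["chrom"] == y_chrom].groupby("barcode")["support"].sum()
    barcodes = pd.Index(pd.unique(frags["barcode"]))
    ycounts = y.reindex(barcodes).fillna(0)
    return pd.Series(np.where(ycounts >= min_reads, "male", "female"),
                     index=barcodes, name="sex")


def tfidf_lsi(peak_counts: CountMatrix, n_comps: int = 30) -> Embedding:
    """TF-IDF normalization followed by truncated SVD (LSI).

    TF is the within-cell peak fraction, IDF is
    ``n_cells / n_cells detecting the peak``, and the embedded matrix is
    ``ln(1 + TF * IDF * 1e4)``. Peaks detected in no cell are dropped with
    a tally. The per-component Pearson correlation with cell depth is
    reported in the embedding provenance (component 1 of an LSI typically
    tracks depth).
    """
    totals = peak_counts.cell_totals().astype(float)
    if np.any(totals == 0):
        raise ValueError("all-zero cells present; filter first")
    X = sp.csr_matrix(peak_counts.values, dtype=float)
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = df > 0
    n_dropped = int((~keep).sum())
    X = X[:, keep]
    idf = X.shape[0] / df[keep]
    tf = sp.diags(1.0 / totals) @ X
    mat = tf.multiply(idf[None, :]).tocsr()
    mat.data = np.log1p(mat.data * 1e4)
    n_comps = min(n_comps, min(mat.shape))
    if n_comps >= min(mat.shape) - 1 or min(mat.shape) < 20:
        u, s, vt = np.linalg.svd(np.asarray(mat.todense()),
                                 full_matrices=False)
        u, s, vt = u[:, :n_comps], s[:n_comps], vt[:n_comps]
    else:
        u, s, vt = svds(mat, k=n_comps, random_state=0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    flip = np.sign(vt[np.arange(n_comps), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = (u * s) * flip
    var = s ** 2
    depth_corr = [float(np.corrcoef(coords[:, i], totals)[0, 1])
                  if np.std(coords[:, i]) > 0 else 0.0
                  for i in range(n_comps)]
    return Embedding(coords, var / var.sum(),
                     {"method": "tfidf_lsi", "n_comps": n_comps,
                      "dropped_empty_peaks": n_dropped,
                      "depth_correlation": depth_corr})


def differential_activity(scores: pd.DataFrame, labels, target_cluster
                          ) -> pd.DataFrame:
    """Differential TF motif activity for one cluster vs the rest.

    ``scores`` is cells x motifs (real-valued, may be negative). Per motif,
    cluster membership is regressed on the score (logistic regression); the
    1-df LRT against the intercept-only model gives p, Bonferroni-adjusted
    across motifs. Motif deviations are signed, so the effect size is the
    difference of group mean activities, not a fold change.
    """
    labels = np.asarray(labels)
    member = (labels == target_cluster).astype(float)
    n1, n0 = int(member.sum()), int(len(member) - member.sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 cells on both sides of the contrast")
    p_hat = member.mean()
    ll_null = len(member) * (p_hat * np.log(p_hat)
                             + (1 - p_hat) * np.log(1 - p_hat))
    rows = []
    for motif in scores.columns:
        x = scores[motif].to_numpy(dtype=float)
        effect = float(x[member == 1].mean() - x[member == 0].mean())
        if np.std(x) == 0:
            rows.append((motif, 0.0, 0.0, 1.0))
            continue
        X = np.column_stack([np.ones_like(x), x])
        beta, _ = _logistic_ml(member.astype(bool), X)
        ll = _logistic_loglik(member, X, beta)
        lam = max(2.0 * (ll - ll_null), 0.0)
        rows.append((motif, effect, lam, float(stats.chi2.sf(lam, 1))))
    out = pd.DataFrame(rows, columns=["motif", "mean_difference",
                                      "lrt_stat", "p"])
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
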