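import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from statekit.atac import (atac_cell_filter, classify_sex_by_chrY,
                           count_fragments_in_peaks, differential_activity,
                           extend_summits, tfidf_lsi)
from statekit.cluster_select import graph_cluster, knn_graph
from statekit.core_io import CountMatrix
from statekit.synthetic_data import (StateSpec, default_atac_design,
                                     simulate_expression,
                                     simulate_fragments)


def _summits(positions, chroms=None):
    chroms = chroms or ["chr1"] * len(positions)
    return pd.DataFrame({"chrom": chroms, "start": positions,
                         "end": [p + 1 for p in positions],
                         "name": [f"s{i}" for i in range(len(positions))]})


def brute_force_counts(frags, intervals, barcodes):
    out = np.zeros((len(barcodes), len(intervals)), dtype=int)
    bc_pos = {b: i for i, b in enumerate(barcodes)}
    for _, f in frags.iterrows():
        for p, (_, iv) in enumerate(intervals.iterrows()):
            if f["chrom"] == iv["chrom"] and f["start"] < iv["end"] \
                    and iv["start"] < f["end"]:
                out[bc_pos[f["barcode"]], p] += f["support"]
    return out


class TestExtendSummits:
    def test_centered_window(self):
        ps = extend_summits(_summits([1000]), width=300)
        iv = ps.intervals.iloc[0]
        assert (iv["start"], iv["end"]) == (850, 1150)

    def test_clipped_at_chromosome_start(self):
        ps = extend_summits(_summits([100]), width=300)
        iv = ps.intervals.iloc[0]
        assert (iv["start"], iv["end"]) == (0, 250)

    def test_close_summits_merged_and_flagged(self):
        ps = extend_summits(_summits([1000, 1100]), width=300)
        assert len(ps) == 1
        iv = ps.intervals.iloc[0]
        assert (iv["start"], iv["end"], bool(iv["merged"])) == \
            (850, 1250, True)

    def test_chrom_sizes_clip_end(self):
        ps = extend_summits(_summits([990]), width=300,
                            chrom_sizes={"chr1": 1000})
        assert ps.intervals.iloc[0]["end"] == 1000

    def test_non_summit_input_rejected(self):
        bad = _summits([10])
        bad["end"] = [12]
        with pytest.raises(ValueError, match="1-bp"):
            extend_summits(bad)


class TestFragmentCounting:
    def test_hand_overlap_example(self):
        frags = pd.DataFrame({
            "chrom": ["chr1"] * 3, "start": [100, 500, 150],
            "end": [200, 600, 250], "barcode": ["BC1", "BC1", "BC2"],
            "support": [1, 1, 1]})
        peaks = extend_summits(_summits([250]), width=300)  # [100, 400)
        cm, _ = count_fragments_in_peaks(frags, peaks)
        counts = {b: int(cm.values[i].sum())
                  for i, b in enumerate(cm.barcodes)}
        assert counts == {"BC1": 1, "BC2": 1}

    def test_no_overlap_all_zero(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [5000],
                              "end": [5100], "barcode": ["a"],
                              "support": [1]})
        peaks = extend_summits(_summits([100]))
        cm, _ = count_fragments_in_peaks(frags, peaks,
                                         barcodes=["a"])
        assert cm.values.nnz == 0

    def test_unknown_chromosome_tallied(self):
        frags = pd.DataFrame({"chrom": ["chrUn"], "start": [10],
                              "end": [60], "barcode": ["a"],
                              "support": [3]})
        peaks = extend_summits(_summits([100]))
        cm, report = count_fragments_in_peaks(frags, peaks,
                                              barcodes=["a"])
        assert report["ignored_chrom_support"] == {"chrUn": 3}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pk = rng.integers(3, 8)
        starts = np.sort(rng.choice(np.arange(0, 2000, 10), n_pk,
                                    replace=False))
        summits = _summits(list(starts),
                           chroms=list(rng.choice(["chr1", "chr2"], n_pk)))
        peaks = extend_summits(summits, width=150)
        n_fr = rng.integers(10, 40)
        fs = rng.integers(0, 2100, n_fr)
        frags = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2", "chr3"], n_fr),
            "start": fs, "end": fs + rng.integers(20, 120, n_fr),
            "barcode": rng.choice(["b1", "b2", "b3"], n_fr),
            "support": rng.integers(1, 4, n_fr)}).sort_values(
            ["chrom", "start"]).reset_index(drop=True)
        barcodes = ["b1", "b2", "b3"]
        cm, _ = count_fragments_in_peaks(frags, peaks, barcodes=barcodes)
        expected = brute_force_counts(frags, cm.features, barcodes)
        np.testing.assert_array_equal(cm.to_dense(), expected)

    def test_mass_conservation(self):
        rng = np.random.default_rng(99)
        peaks = extend_summits(_summits([200, 800, 1400]), width=200)
        fs = rng.integers(0, 1600, 60)
        frags = pd.DataFrame({
            "chrom": "chr1", "start": fs,
            "end": fs + 50, "barcode": rng.choice(["x", "y"], 60),
            "support": rng.integers(1, 3, 60)}).sort_values("start")
        cm, _ = count_fragments_in_peaks(frags, peaks)
        pair_mass = sum(
            f["support"] * int(((peaks.intervals["chrom"] == f["chrom"])
                                & (peaks.intervals["start"] < f["end"])
                                & (f["start"]
                                   < peaks.intervals["end"])).sum())
            for _, f in frags.iterrows())
        assert cm.values.sum() == pair_mass


class TestCellFilterAndSex:
    def test_boundary_totals_kept(self):
        rows = np.diag([999, 1000, 20000, 20001])
        cm = CountMatrix(sp.csr_matrix(rows), list("abcd"),
                         pd.DataFrame({"chrom": ["chr1"] * 4,
                                       "start": range(4),
                                       "end": range(1, 5)},
                                      index=[f"p{i}" for i in range(4)]),
                         "peak")
        out, report = atac_cell_filter(cm)
        assert list(out.barcodes) == ["b", "c"]
        assert report["removed_low"] == 1 and report["removed_high"] == 1

    def test_empty_matrix(self):
        cm = CountMatrix(sp.csr_matrix((0, 1)), [],
                         pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                       "end": [1]}, index=["p0"]), "peak")
        out, _ = atac_cell_filter(cm)
        assert out.shape[0] == 0

    def test_sex_calls_from_fragments(self):
        frags = pd.DataFrame({
            "chrom": ["chrY", "chr1", "chr1"], "start": [10, 10, 20],
            "end": [60, 60, 70], "barcode": ["m1", "m1", "f1"],
            "support": [3, 1, 1]})
        calls = classify_sex_by_chrY(frags)
        assert calls["m1"] == "male" and calls["f1"] == "female"

    def test_no_chrY_anywhere_fails(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [1],
                              "end": [2], "barcode": ["a"],
                              "support": [1]})
        with pytest.raises(ValueError, match="chrY"):
            classify_sex_by_chrY(frags)

    def test_simulation_accuracy(self):
        spec = StateSpec.separable()
        _, _, truth = simulate_expression(spec, 150, seed=3)
        peaks, acc = default_atac_design(n_peaks=200)
        frags = simulate_fragments(truth, peaks, acc, seed=4)
        calls = classify_sex_by_chrY(frags)
        sex = truth.set_index("barcode")["sex"]
        assert (calls == sex.loc[calls.index]).mean() >= 0.99


class TestTfidfLsi:
    def test_identical_cells_identical_rows(self):
        rng = np.random.default_rng(0)
        row = rng.integers(1, 20, 30)
        cm = CountMatrix(sp.csr_matrix(np.vstack([row, row, row * 2])),
                         ["a", "b", "c"],
                         pd.DataFrame(index=[f"p{i}" for i in range(30)]),
                         "peak")
        emb = tfidf_lsi(cm, n_comps=2)
        np.testing.assert_allclose(emb.coords[0], emb.coords[1],
                                   atol=1e-10)

    def test_matches_dense_svd_oracle(self):
        X = np.array([[3, 0, 1], [0, 2, 1], [1, 1, 4]])
        cm = CountMatrix(sp.csr_matrix(X), list("abc"),
                         pd.DataFrame(index=["p1", "p2", "p3"]), "peak")
        emb = tfidf_lsi(cm, n_comps=2)
        tf = X / X.sum(axis=1, keepdims=True)
        idf = 3 / (X > 0).sum(axis=0)
        M = np.log1p(tf * idf * 1e4)
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        for j in range(2):
            ref = u[:, j] * s[j]
            assert (np.abs(emb.coords[:, j] - ref).max() < 1e-8
                    or np.abs(emb.coords[:, j] + ref).max() < 1e-8)

    def test_depth_correlations_reported(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 10, (40, 60))
        X[:, 0] += 1  # avoid empty cells
        cm = CountMatrix(sp.csr_matrix(X), [f"c{i}" for i in range(40)],
                         pd.DataFrame(index=[f"p{j}" for j in range(60)]),
                         "peak")
        emb = tfidf_lsi(cm, n_comps=5)
        corr = emb.provenance["depth_correlation"]
        assert len(corr) == 5
        assert all(-1.0 <= c <= 1.0 for c in corr)

    def test_undetected_peaks_dropped(self):
        X = np.array([[1, 0], [2, 0]])
        cm = CountMatrix(sp.csr_matrix(X), ["a", "b"],
                         pd.DataFrame(index=["p1", "p2"]), "peak")
        emb = tfidf_lsi(cm, n_comps=1)
        assert emb.provenance["dropped_empty_peaks"] == 1


class TestDifferentialActivity:
    def test_identical_distributions_null(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 100)
        scores = pd.DataFrame({"motifA": np.concatenate([x, x])})
        labels = np.array(["c1"] * 100 + ["c2"] * 100)
        res = differential_activity(scores, labels, "c1")
        assert abs(res.loc[0, "mean_difference"]) < 1e-12
        assert res.loc[0, "p"] > 0.9

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame({
            "motifA": np.concatenate([rng.normal(0, 1, 200),
                                      rng.normal(1, 1, 200)]),
            "motifB": rng.normal(0, 1, 400)})
        labels = np.array(["c1"] * 200 + ["c2"] * 200)
        res = differential_activity(scores, labels,
                                    "c2").set_index("motif")
        assert res.loc["motifA", "p_bonferroni"] < 1e-6
        assert res.loc["motifA", "mean_difference"] == pytest.approx(
            1.0, abs=0.3)
        assert res.loc["motifB", "p_bonferroni"] > 0.05

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame({"m": rng.normal(0, 1, 120)})
        labels = rng.choice(["c1", "c2"], 120)
        a = differential_activity(scores, labels, "c1")
        b = differential_activity(scores * 5.0 + 2.0, labels, "c1")
        assert a.loc[0, "p"] == pytest.approx(b.loc[0, "p"], abs=1e-6)
        assert b.loc[0, "mean_difference"] == pytest.approx(
            5.0 * a.loc[0, "mean_difference"], abs=1e-9)

    def test_constant_scores_p_one(self):
        scores = pd.DataFrame({"m": np.ones(40)})
        labels = np.array(["c1"] * 20 + ["c2"] * 20)
        res = differential_activity(scores, labels, "c1")
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "mean_difference"] == 0.0


class TestPipelineComposition:
    def test_state_recovery_from_fragments(self):
        spec = StateSpec.separable()
        _, _, truth = simulate_expression(spec, 200, seed=1)
        peaks, acc = default_atac_design()
        frags = simulate_fragments(truth, peaks, acc,
                                   depth_params=(np.log(4.0), 0.3), seed=5)
        summits = pd.DataFrame({
            "chrom": peaks["chrom"],
            "start": peaks["start"] + 150,
            "end": peaks["start"] + 151,
            "name": peaks["name"]})
        pkset = extend_summits(summits, width=300)
        counts, _ = count_fragments_in_peaks(frags, pkset)
        filtered, _ = atac_cell_filter(counts)
        assert filtered.shape[0] >= 150
        emb = tfidf_lsi(filtered, n_comps=30)
        labels = graph_cluster(knn_graph(emb, 20), 0.3, seed=0)
        t = truth.set_index("barcode").loc[filtered.barcodes, "state"]
        assert adjusted_rand_score(t, labels) >= 0.8
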