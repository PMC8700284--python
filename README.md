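# statekit

Analysis toolkit for **continuous transcriptional states** in sorted
stem/progenitor single-cell data — the situation where a highly purified
population (e.g. hematopoietic stem cells, HSCs) does not fall apart into
discrete cell types but occupies a continuum of states (quiescent,
signal-activated, metabolically active, ...) whose marker genes are
*enriched* along gradients rather than exclusively expressed. It is aimed at
computational biologists analyzing scRNA-seq, CITE-seq hashing, and scATAC
data from in vivo perturbation experiments.

## What it implements

- **Data-driven cluster-number selection.** Leiden clustering over a grid of
  (k nearest neighbors, resolution); each partition scored in PCA space by
  the mean Silhouette coefficient s̄ and the Davies–Bouldin index; the
  selected cluster number is the largest n before the first relative drop
  of the per-n Silhouette optimum exceeding a tolerance (default 5%).
- **Hurdle-model differential expression.** Per gene, a logistic model for
  detection 1{y>0} and a Gaussian model for the level y | y>0 share a
  design with covariates (cellular detection rate, sex); the contrast is a
  likelihood-ratio test with χ² reference, df summed over the two parts;
  fold changes are defined on the combined expectation
  P(detected)·E[y | detected]; BH-FDR at 1% with 1.2-/1.5-fold cutoffs and
  a 5% minimum detection filter.
- **Differential proportion analysis (DPA).** Permutation test for
  per-cluster composition shifts between two conditions, with the
  (1 + #{|Δ*| ≥ |Δ|})/(n_perm + 1) correction.
- **Diffusion pseudotime (DPT).** Adaptive Gaussian kernel on PCA
  coordinates, density-normalized transition matrix,
  dpt(x, x₀)² = Σᵢ (λᵢ/(1−λᵢ))² (ψᵢ(x) − ψᵢ(x₀))², root anchored at the
  cell with maximal summed raw counts of activation markers
  (Nr4a1/Nr4a2/Hes1 by default); fixed-bandwidth (0.02) kernel densities
  and Mann–Whitney shift tests between conditions; 10-quantile bin
  expression profiles.
- **Gene-set state scores** with expression-bin-matched random reference
  genes, compared across clusters by ANOVA + Tukey HSD.
- **Top-N overlap enrichment**: top-100 induced/marker gene lists, exact
  hypergeometric tails P(X ≥ k), BH across the comparison matrix.
- **HTO demultiplexing**: per-droplet EM mixture of a fixed ambient
  background profile and a Dirichlet-regularized signal composition;
  singlet/doublet/negative calls plus a sex-gene coexpression doublet-rate
  cross-check.
- **scATAC fragment processing**: 300-bp summit extension, fragment-level
  peak counting, 1000–20000 in-peak fragment cell filter, chrY sex calls,
  TF-IDF/LSI embedding, and logistic-regression differential motif
  activity with Bonferroni correction.
- **Limiting-dilution (ELDA-style) frequency**: single-hit Poisson model
  fit as a binomial GLM with complementary log-log link and ln(dose)
  offset.
- **Synthetic data generators** (first-class, tested) emulating all of the
  above: graded marker enrichment along a 1-D manifold, condition-dependent
  state proportions, treatment effects, batch/sex structure, doublets,
  hashtag droplets with ambient background, and fragment files with
  state-dependent accessibility — each with per-cell ground truth for
  parameter-recovery tests.

## Worked example

```python
import numpy as np
from statekit import StateSpec, simulate_expression, AnalysisConfig
from statekit.preprocess import qc_filter, normalize_log, scale_features
from statekit.cluster_select import (pca_embed, hyperparameter_scan,
                                     select_cluster_number, knn_graph,
                                     graph_cluster)
from statekit.hurdle_de import differential_expression

spec = StateSpec.default()              # 3 HSC states, 5 conditions
counts, cells, truth = simulate_expression(spec, 3000, seed=0)
cfg = AnalysisConfig().replace(min_genes_hsc=200, min_genes_mpp=250)
filt, cells, report = qc_filter(counts, cells, cfg)
print(f"QC kept {report.cells_out}/{report.cells_in} cells")

expr = scale_features(normalize_log(filt))
emb = pca_embed(expr, n_pcs=50)
scan = hyperparameter_scan(emb, k_grid=(10, 15, 30),
                           resolution_grid=np.round(np.arange(0.1, 1.3, 0.1), 2),
                           seed=0)
n, k, res = select_cluster_number(scan)
print(f"selected {n} states at k={k}, resolution={res}")

mask = np.isin(cells["condition"], ["control", "dmPGE2"])
de = differential_expression(normalize_log(filt.subset_cells(mask)),
                             cells.loc[mask, "condition"].astype(str),
                             reference="control")
hits = de[de["pass_1.2"]]
print(f"{len(hits)} genes pass FDR<0.01 at the 1.2-fold cutoff")
print(hits.head(5)[["gene", "log2fc", "p", "q"]].to_string(index=False))
```

Output:

```
QC kept 2942/3000 cells
selected 3 states at k=15, resolution=0.2
86 genes pass FDR<0.01 at the 1.2-fold cutoff
 gene   log2fc             p             q
  Fos 1.761799 5.753749e-136 3.216346e-133
  Jun 1.778437 4.427335e-135 1.237440e-132
 Hes1 1.778900 2.565441e-131 4.780272e-129
Nr4a1 1.755540 1.865098e-123 2.606474e-121
Nr4a2 1.772724 6.779941e-118 7.579974e-116
```

The scan recovers the three simulated states, and the dmPGE₂ contrast is
led by the immediate-early genes that the simulation both upregulates
directly and enriches via the condition's shift toward the activated
state — the two signals a hurdle model on aggregate data is expected to
combine. The QC gene/count thresholds are rescaled here because the
simulated panel has ~560 genes; the defaults in `AnalysisConfig` are for
genome-wide data.

A quick limiting-dilution estimate:

```python
import pandas as pd
from statekit.composition_stats import limiting_dilution_frequency
print(limiting_dilution_frequency(pd.DataFrame(
    {"dose": [10], "n_tested": [10], "n_responding": [6]})))
# 1 in 10.9 (95% CI 1 in 4.8 to 1 in 25.0)
```

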