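# Methods

This note documents the models and procedures statekit implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter for reproducing
results.

## Preprocessing

Cells are filtered on total UMIs (< 3000 excluded), detected genes (< 1500
for sorted HSCs, < 2000 for MPP populations), total counts (> 20,000 HSC /
> 30,000 MPP), and mitochondrial UMI fraction (> 10%); genes detected in
fewer than 20 surviving cells are dropped. Rule counts in the QC report
refer to the pre-filter population, so a cell can appear under several
rules. Mitochondrial genes are identified by a configurable name prefix
(default `mt-`). Counts are normalized to 10,000 per cell and transformed
with ln(1+x); natural log is used throughout (the pipeline convention this
package follows). Scaling is a per-gene z-score with population SD;
zero-variance genes map to zero, and no clipping of extremes is applied
(configurable decisions of this package; clipping is a common alternative).

Batch adjustment is parametric empirical-Bayes location/scale correction
(ComBat; delegated to `scanpy.pp.combat`) on the log-scale matrix, applied
before scaling; a single batch is an identity, and batches with one cell
are rejected. Note that EB variance shrinkage rescales per-gene variances
even for perfectly symmetric batches, so adjustment of identical batches is
close to, but not exactly, the identity. Residual per-gene batch-mean gaps
after adjusting a simulated homogeneous +2 shift sit at the sampling/
shrinkage noise floor (~0.05 at 500 cells/batch with per-gene noise SD 0.5,
the typical scale of normalized-log expression); R's `sva::ComBat` leaves
the same residual to three decimals, which is the package's cross-check
that the delegation is faithful. Residual sex signal is removed by
regressing each gene on raw Xist counts per cell (simple OLS, residual plus
intercept so gene means are preserved), after batch adjustment.

## Cluster-number selection

PCA (50 components by default, deterministic component signs), a
symmetrized kNN graph, and Leiden community detection (RBConfiguration
quality, fixed seed, labels ordered by cluster size) are scanned over a
grid of k ∈ {10, 15, 30} × resolution ∈ {0.1 … 1.4}. Each partition with
≥ 2 clusters is scored in PCA space with the mean Silhouette coefficient
and the Davies–Bouldin index (Euclidean metric). For each achieved cluster
number the Silhouette-maximal grid point is the representative; the
selected cluster number is the largest n before the first relative drop of
the per-n optimum exceeding the tolerance (default 0.05). This formalizes
the visual "drop-off" reading of the optimum-vs-n curve; the
Davies–Bouldin optimum is reported alongside as a consistency check but
does not arbitrate. The number of PCs and the Euclidean metric are
assumptions of this package, made explicit in the config. A benchmark
helper runs the same scan on the public PBMC3K dataset, where the
Silhouette optimum drops off after eight clusters; it requires a one-time
download.

## Hurdle differential expression

For gene g with normalized-log expression y (zeros = undetected), the
model is logistic regression of 1{y>0} on the design (ML, coefficients
capped at ±10 under separation and flagged) plus a Gaussian linear model of
y on the design over detecting cells (ML variance; skipped below 3
detected cells). The design contains an intercept, the group indicator,
the standardized number of detected genes per cell (cellular detection
rate), and dummy-coded sex. The group is tested by a likelihood-ratio
statistic summing both parts against χ² with summed df (2, or 1 when the
continuous part is absent). Genes detected in < 5% of cells are not
tested; BH-FDR is computed across tested genes with a 1% threshold, and
pass flags are emitted at no-fold-change, 1.2-fold, and 1.5-fold cutoffs
on |log2FC|. log2FC is defined on the combined hurdle expectation
P(det)·μ at reference covariate levels (the fold-change semantics are
otherwise ambiguous); the continuous-part coefficient is emitted separately
as `log2fc_detected`. No empirical-Bayes variance shrinkage is applied —
transparency and exact ML oracles in tests were preferred. Cluster-wise
contrasts run the same model inside every cluster with ≥ 20 cells per arm.
Null calibration at n=400 cells: the LRT p-values are approximately
uniform (KS distance ~0.02–0.05 over seeds at 1000 genes).

Signature grouping z-scores each DE gene's per-cluster mean profile and
clusters profiles by single-linkage agglomeration with Euclidean distance,
returning leaf order and flat groups at a configurable count.

## Composition statistics

DPA permutes condition labels over pooled cells (condition totals fixed;
the pooled label multiset is put in canonical order first so p-values are
invariant to input order), with two-sided empirical p =
(1 + #{|Δ*| ≥ |Δ|})/(n_perm + 1); default n_perm = 10⁵, BH across clusters
reported but unadjusted p primary. The two-proportion comparison is
Pearson χ² on the 2×2 table, 1 df, no continuity correction. Limiting-
dilution frequency assumes the single-hit Poisson model
P(respond|d) = 1 − exp(−f·d), fit as a binomial GLM with complementary
log-log link and offset ln d; f̂ = exp(intercept) with a Wald 95% CI on the
log scale (profile CIs are a known alternative, not implemented);
all-/none-responding inputs return a flagged bound.

## Scores and enrichment

Gene-set scores bin all genes into 25 equal-size bins by mean expression
and draw, per set gene, one control gene (configurable) from its bin
excluding set members; the score is mean(set) − mean(controls) per cell on
normalized-log (not scaled) expression. Scores across clusters are compared
by one-way ANOVA with Tukey-HSD pairwise adjustment (exact adjusted p
reported). Overlap enrichment takes top-100 lists ranked by ascending p,
then descending |log2FC|, then gene id; significance is the exact
hypergeometric upper tail over a stated universe, BH-corrected across the
whole comparison matrix with a 1% mark. The universe defaults to the
QC-surviving genes of the analyzed matrix — p magnitudes depend directly on
this choice, so it is an explicit argument.

## Diffusion pseudotime

The kernel is Gaussian on PCA coordinates with per-cell adaptive width
(distance to the median kNN neighbor, k=30), symmetrized by elementwise
max, density-normalized with anisotropy exponent 1, and row-normalized;
the spectrum comes from the symmetric conjugate, giving right eigenvectors
orthonormal under the stationary weighting. Pseudotime from root x₀ is
dpt² = Σᵢ₌₁..ₘ (λᵢ/(1−λᵢ))²(ψᵢ(x)−ψᵢ(x₀))² over m=10 components, rescaled
to [0,1] (required for the fixed 0.02 density bandwidth to be meaningful).
With all components retained this equals the dense accumulation form
(I − (T − T∞))⁻¹ under the D⁻¹-weighted norm, which is the test oracle.
The root is the cell with the largest summed raw counts of the activation
markers (ties to the lexicographically lowest barcode); the analysis
subset (e.g. quiescent + activated cells) is caller-supplied. Disconnected
kernel graphs are processed with a warning; extra unit eigenvalues are
excluded from the pseudotime sum. Densities use a plain Gaussian KDE with
bandwidth 0.02 on a 0.001 grid, no boundary correction — only the
Mann–Whitney shift test (exact for combined n ≤ 20 without ties, tie-
corrected normal otherwise) is treated as quantitative. Bin profiles use
quantile-rank binning into 10 equal-count bins, remainders to the earliest
bins.

## HTO demultiplexing

Droplet counts are modeled as a two-component mixture: a fixed ambient
background profile (column sums over empty droplets, normalized; empties
selected by a total-count quantile by default) and a per-droplet signal
composition θ. EM alternates count-level responsibilities with MAP updates
(symmetric Dirichlet α on θ; an `alpha_noise` pseudocount on the
background weight ν that breaks the background/signal degeneracy of
ambient-only droplets); convergence is declared when the mixture weights
change by < 1e-6 (200 iteration cap), and the penalized objective is
non-decreasing per iteration. Tags with posterior signal weight
(1−ν)·θ_t > 0.1 determine the call: none → negative, one → singlet, ≥ 2 →
doublet. Defaults α = 1, alpha_noise = 1 (maximum likelihood); a grid
helper maximizes singlet retrieval over (α, alpha_noise). Ambient-only
droplets that survive cell calling can still draw weak spurious calls at
these weak priors — raising `alpha_noise` or excluding low-count droplets
is the remedy. The doublet rate is cross-checked by the fraction of cells
coexpressing the female-only gene and ≥ 1 chrY gene, scaled by
1/(2·p_m·p_f); because chrY transcripts are sparsely detected in droplet
data this is an under-estimate, and the EM doublet fraction is expected to
exceed it.

## scATAC processing

Summits (1-bp BED) are extended to centered 300-bp windows [s−150, s+150),
clipped at chromosome bounds, with overlapping windows merged and flagged.
Counting is fragment-level: each fragment contributes its support to every
peak it overlaps by ≥ 1 bp (a fragment spanning two merged-adjacent peaks
counts in each; per-cut-site counting was rejected for determinism and is
noted as a variant). Cells outside 1000–20,000 in-peak fragments are
removed (boundaries kept). Sex is called from presence (≥ 1 read) of chrY
fragments. TF-IDF uses ln(1 + TF·IDF·10⁴) with truncated SVD; per-component
Pearson correlation with cell depth is reported so depth-tracking
components can be dropped by the analyst. Differential motif activity
(motif scores are an input, e.g. chromVAR deviations) is a per-motif
logistic regression of cluster membership on the score with a 1-df LRT and
Bonferroni correction; because deviations are signed, the effect size is
the difference of group means, not a fold change.

## Synthetic data

`StateSpec` places K states at anchors on a 1-D manifold; marker
enrichment multiplies baseline means by 1 + (e−1)·w_k(t) with
hat-function membership weights w, so markers are graded and cells between
anchors are intermediate — the defining feature of continuous states.
Counts are negative-binomial (gamma-Poisson, shared dispersion θ=5) around
library-size-scaled compositions; library sizes are log-normal
(median 5000). The default study has three states (quiescent, activated,
metabolism), five conditions (control, dmPGE2, polyIC, GCSF,
indomethacin) with condition-dependent state proportions and
immediate-early-gene treatment effects, two batches with multiplicative
per-gene factors, balanced sexes with an abundant female-only Xist-like
gene and three sparsely expressed chrY genes (reflecting their low
detection in real droplet data), and a 5% doublet rate (doublets sum two
cells' compositions before the count draw). `StateSpec.separable()` is the
benchmark variant: tight positions (SD 0.05), no doublets/batch effects,
one condition, 50 markers/state at 4× enrichment. Hashtag droplets receive
Poisson signal (mean 200) on the gate tag(s) plus Poisson ambient
background (mean 30) from a shared profile, with 500 background-only
droplets. Fragment files draw per-(cell, peak) Poisson counts of
depth × accessibility with uniform placement inside the peak; the default
landscape has 1000 non-overlapping 300-bp peaks, 100 per state at 8×
accessibility, and three chrY peaks (mirroring the tiny chrY share of real
peak sets — with unrealistically many chrY peaks, LSI space splits by sex
instead of state).

What the generators do not emulate: ambient RNA contamination, gene-gene
correlation beyond the manifold, empty-droplet RNA profiles, read-level
noise, chromatin co-accessibility, branching trajectories, and
batch-by-condition confounding. Passing tests therefore demonstrate
correctness of the procedures under the stated statistical structure, not
robustness to every artifact of real data.

## Problem sizes and seeds

Tests and the acceptance script use desk-scale sizes chosen to give stable
statistics: 2000 cells / ~560 genes for state recovery, 1000 null genes at
400 cells for DE calibration, 200 replicates for DPA type-I error and
limiting-dilution coverage, 10 chain seeds of 300 cells for pseudotime,
800 cells + 500 empty droplets for demultiplexing, and 200 cells × 1000
peaks for the fragment pipeline. Every stochastic operation takes an
explicit seed (default 0); `scripts/acceptance.py` derives all of its
streams from `--seed`.
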