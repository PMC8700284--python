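"""Synthetic single-cell data with the structure the downstream analyses assume.

The generator emulates a sorted stem/progenitor compartment profiled under in
vivo perturbations: a small number of transcriptional *states* arranged along
a one-dimensional latent manifold, with marker genes *enriched* toward each
state's anchor position rather than exclusively expressed, condition-dependent
state proportions, within-condition treatment effects on individual genes,
multiplicative batch factors, sex-specific genes (one Xist-like female-only
gene, chrY-like male-only genes), and a configurable doublet rate. Counts are
negative-binomial (gamma-Poisson) around a library-size-scaled composition.

Companion generators produce hashtag-oligo droplet counts (signal on the tag
of each cell's sorting gate plus ambient background, with empty droplets) and
scATAC fragments files with state-dependent peak accessibility.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CountMatrix, make_cell_table, write_fragments

__all__ = ["StateSpec", "simulate_expression", "simulate_hto",
           "simulate_fragments", "state_membership", "default_atac_design"]


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass
class StateSpec:
    """Parameterization of the simulated cell-state landscape.

    Attributes
    ----------
    anchors
        Manifold anchor position in [0, 1] for each of the K states, sorted.
    baseline_mean
        Per-gene baseline mean (relative composition before enrichment).
    markers
        ``{state index (0-based): gene index array}``. Marker enrichment
        interpolates linearly between anchors (hat-function membership), so
        markers are graded, not exclusive.
    enrichment
        Fold enrichment (>= 1) of each state's markers at its anchor.
    proportions
        conditions x K state proportions; each row sums to 1.
    treatment_effects
        List of ``(gene name, condition, log2 effect)`` applied
        multiplicatively to that gene in cells of that condition.
    theta
        Negative-binomial dispersion (shared across genes); ``np.inf``
        degenerates to Poisson.
    """

    n_states: int
    anchors: np.ndarray
    gene_names: list
    baseline_mean: np.ndarray
    markers: dict
    enrichment: float = 4.0
    position_sd: float = 0.12
    proportions: pd.DataFrame = None
    condition_probs: dict = None
    treatment_effects: list = field(default_factory=list)
    theta: float = 5.0
    lib_log_mean: float = np.log(5000.0)
    lib_log_sd: float = 0.25
    batch_names: tuple = ("b0", "b1")
    batch_effect_sd: float = 0.1
    female_frac: float = 0.5
    xist_gene: str = "Xist"
    y_genes: tuple = ("Ddx3y", "Eif2s3y", "Uty")
    doublet_rate: float = 0.05
    gate_probs: dict = None
    state_names: list = None

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=float)
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        if self.proportions is None:
            self.proportions = pd.DataFrame(
                [np.full(self.n_states, 1.0 / self.n_states)],
                index=["control"])
        if self.condition_probs is None:
            conds = list(self.proportions.index)
            self.condition_probs = {c: 1.0 / len(conds) for c in conds}
        if self.gate_probs is None:
            self.gate_probs = {"HSC": 1.0}
        if self.state_names is None:
            self.state_names = [f"state{k + 1}" for k in range(self.n_states)]

    def validate(self) -> None:
        problems = []
        if len(self.anchors) != self.n_states:
            problems.append("anchors length != n_states")
        if np.any(np.diff(self.anchors) < 0):
            problems.append("anchors not sorted")
        if np.any((self.anchors < 0) | (self.anchors > 1)):
            problems.append("anchors outside [0, 1]")
        if len(self.baseline_mean) != len(self.gene_names):
            problems.append("baseline_mean length != number of genes")
        if np.any(self.baseline_mean <= 0):
            problems.append("baseline means must be positive")
        if not self.theta > 0:
            problems.append("theta must be > 0")
        if self.enrichment < 1:
            problems.append("enrichment factors must be >= 1")
        rowsum = self.proportions.to_numpy().sum(axis=1)
        if not np.allclose(rowsum, 1.0):
            problems.append("state proportions must sum to 1 per condition")
        if not 0 <= self.doublet_rate <= 1:
            problems.append("doublet_rate outside [0, 1]")
        if problems:
            raise ValueError("invalid StateSpec: " + "; ".join(problems))

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    # -- canonical study conditions --------------------------------------
    @classmethod
    def default(cls, n_states: int = 3, markers_per_state: int = 50,
                enrichment: float = 4.0, n_background_genes: int = 400,
                seed: int = 0) -> "StateSpec":
        """The default simulated study: three HSC states (quiescent,
        activated, metabolism) under control plus four perturbations, with
        immediate-early genes as activated-state markers and treatment
        targets, sex-specific genes, and mitochondrial genes for QC."""
        rng = np.random.default_rng(seed)
        state_names = ["Quiescent", "Activated", "Metabolism",
                       "Interferon", "CellCycle", "state6", "state7",
                       "state8"][:n_states]
        ieg = ["Nr4a1", "Nr4a2", "Hes1", "Fos", "Fosb", "Jun", "Klf4",
               "Klf6", "Ier2"]
        names, markers = [], {}
        for k, sname in enumerate(state_names):
            block = ieg[:markers_per_state] if sname == "Activated" else []
            block = list(block)
            while len(block) < markers_per_state:
                block.append(f"{sname}_m{len(block):03d}")
            markers[k] = np.arange(len(names), len(names) + markers_per_state)
            names.extend(block)
        names.append("Xist")
        names.extend(["Ddx3y", "Eif2s3y", "Uty"])
        names.extend(f"mt-g{i}" for i in range(5))
        names.extend(f"g{i:04d}" for i in range(n_background_genes))
        mean = rng.lognormal(0.0, 0.6, size=len(names))
        # Xist is abundant; chrY transcripts are sparsely detected in
        # droplet data, so the sex-coexpression doublet estimate is a
        # known under-estimate
        idx = pd.Index(names)
        mean[idx.get_loc("Xist")] = 8.0
        for g in ("Ddx3y", "Eif2s3y", "Uty"):
            mean[idx.get_loc(g)] = 0.05
        for i in range(5):
            mean[idx.get_loc(f"mt-g{i}")] = 8.0  # ~5% of UMIs in total
        anchors = np.linspace(0.0, 1.0, n_states)
        conds = ["control", "dmPGE2", "polyIC", "GCSF", "indomethacin"]
        base = np.full(n_states, 0.2 / max(n_states - 2, 1))
        props = {}
        for c in conds:
            p = np.full(n_states, 1.0 / n_states)
            if n_states >= 3:
                p = np.concatenate(([0.5, 0.3], base))[:n_states]
                if c in ("dmPGE2", "polyIC", "GCSF"):
                    p[0], p[1] = 0.3, 0.5
                if c == "indomethacin":
                    p[0], p[1] = 0.55, 0.25
            props[c] = p / p.sum()
        proportions = pd.DataFrame(props).T
        effects = [(g, "dmPGE2", 1.5) for g in ieg[:6]]
        effects += [(g, "indomethacin", 1.0) for g in ieg[3:]]
        effects += [("g0000", "polyIC", 2.0), ("g0001", "GCSF", 2.0)]
        return cls(n_states=n_states, anchors=anchors, gene_names=names,
                   baseline_mean=mean, markers=markers,
                   enrichment=enrichment, proportions=proportions,
                   treatment_effects=effects, state_names=state_names)


def _separable_spec(n_states: int = 3, markers_per_state: int = 50,
                    enrichment: float = 4.0, seed: int = 0,
                    extreme: bool = False) -> StateSpec:
    """Well-separated benchmark landscape: tight states on the manifold, no
    doublets, no batch effects, a single condition. With ``extreme=True``
    the noiseless separable limit (huge enrichment, Poisson counts, states
    pinned at their anchors) used for exact-recovery checks."""
    spec = StateSpec.default(n_states=n_states,
                            markers_per_state=markers_per_state,
                            enrichment=1000.0 if extreme else enrichment,
                            seed=seed)
    spec.position_sd = 1e-6 if extreme else 0.05
    spec.doublet_rate = 0.0
    spec.batch_effect_sd = 0.0
    spec.theta = np.inf if extreme else 5.0
    spec.proportions = pd.DataFrame(
        [np.full(n_states, 1.0 / n_states)], index=["control"])
    spec.condition_probs = {"control": 1.0}
    spec.treatment_effects = []
    return spec


StateSpec.separable = staticmethod(_separable_spec)


def state_membership(positions: np.ndarray, anchors: np.ndarray
                     ) -> np.ndarray:
    """Hat-function membership weights, cells x K, rows summing to 1.

    Weight of state k decays linearly from 1 at its anchor to 0 at the
    adjacent anchors; positions beyond the terminal anchors clamp to the
    terminal state.
    """
    positions = np.asarray(positions, dtype=float)
    K = len(anchors)
    W = np.zeros((positions.size, K))
    seg = np.clip(np.searchsorted(anchors, positions, side="right"), 1, K - 1) \
        if K > 1 else np.zeros(positions.size, dtype=int)
    if K == 1:
        W[:, 0] = 1.0
        return W
    lo, hi = anchors[seg - 1], anchors[seg]
    frac = np.clip((positions - lo) / np.where(hi > lo, hi - lo, 1.0), 0, 1)
    W[np.arange(positions.size), seg - 1] = 1 - frac
    W[np.arange(positions.size), seg] += frac
    return W


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _expected_composition(spec: StateSpec, positions, conditions, sexes):
    """Per-cell unnormalized expected composition (cells x genes)."""
    genes = pd.Index(spec.gene_names)
    V = np.tile(spec.baseline_mean, (len(positions), 1))
    W = state_membership(positions, spec.anchors)
    for k, gidx in spec.markers.items():
        V[:, gidx] *= 1.0 + (spec.enrichment - 1.0) * W[:, [k]]
    for gene, cond, log2fc in spec.treatment_effects:
        mask = conditions == cond
        if mask.any() and gene in genes:
            V[mask, genes.get_loc(gene)] *= 2.0 ** log2fc
    sexes = np.asarray(sexes)
    if spec.xist_gene in genes:
        V[sexes == "male", genes.get_loc(spec.xist_gene)] = 0.0
    for g in spec.y_genes:
        if g in genes:
            V[sexes == "female", genes.get_loc(g)] = 0.0
    return V


def simulate_expression(spec: StateSpec, n_cells: int, seed: int = 0
                        ) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw a UMI count matrix plus cell table and per-cell ground truth.

    Counts are NB with mean ``library_size * normalized composition``, the
    composition being baseline means modulated by graded marker enrichment
    at the cell's manifold position, batch factors, sex masking, and
    per-condition treatment effects. Doublets sum two cells' compositions
    before the count draw.
    """
    spec.validate()
    if n_cells < spec.n_states:
        raise ValueError("n_cells must be >= n_states")
    rng = np.random.default_rng(seed)
    genes = pd.Index(spec.gene_names)

    conds = list(spec.proportions.index)
    cond_p = np.array([spec.condition_probs[c] for c in conds], dtype=float)
    condition = rng.choice(conds, size=n_cells, p=cond_p / cond_p.sum())
    prop = spec.proportions.to_numpy()
    state = np.empty(n_cells, dtype=int)
    for i, c in enumerate(conds):
        mask = condition == c
        state[mask] = rng.choice(spec.n_states, size=mask.sum(), p=prop[i])
    position = np.clip(spec.anchors[state]
                       + rng.normal(0, spec.position_sd, n_cells), 0, 1)
    batch = rng.choice(spec.batch_names, size=n_cells)
    sex = np.where(rng.random(n_cells) < spec.female_frac, "female", "male")
    gates = list(spec.gate_probs)
    gate_p = np.array([spec.gate_probs[g] for g in gates], dtype=float)
    gate = rng.choice(gates, size=n_cells, p=gate_p / gate_p.sum())
    lib = rng.lognormal(spec.lib_log_mean, spec.lib_log_sd, n_cells)
    doublet = rng.random(n_cells) < spec.doublet_rate
    partner = np.where(doublet, rng.integers(0, n_cells, n_cells), -1)
    # avoid self-partnering
    partner = np.where(partner == np.arange(n_cells),
                       (partner + 1) % n_cells, partner)

    batch_factors = {
        b: rng.lognormal(0.0, spec.batch_effect_sd, spec.n_genes)
        for b in spec.batch_names}

    V = _expected_composition(spec, position, condition, sex)
    for b in spec.batch_names:
        V[batch == b] *= batch_factors[b]
    dbl = np.flatnonzero(doublet)
    if dbl.size:
        V[dbl] = V[dbl] + V[partner[dbl]]
    P = V / V.sum(axis=1, keepdims=True)
    mean = lib[:, None] * P
    if np.isfinite(spec.theta):
        lam = rng.gamma(spec.theta, mean / spec.theta)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)

    barcodes = pd.Index([f"cell{i:05d}" for i in range(n_cells)])
    features = pd.DataFrame(index=genes.copy())
    chrom = np.array(["chr1"] * len(genes), dtype=object)
    chrom[genes == spec.xist_gene] = "chrX"
    for g in spec.y_genes:
        chrom[genes == g] = "chrY"
    chrom[genes.str.startswith("mt-")] = "chrM"
    features["chrom"] = chrom
    features["mito"] = genes.str.startswith("mt-")
    cm = CountMatrix(sp.csr_matrix(counts), barcodes, features, "gene")

    cells = make_cell_table(barcodes, condition=condition, sex=sex,
                            batch=batch, gate=gate)
    truth = pd.DataFrame({
        "barcode": barcodes,
        "state": state + 1,
        "state_name": np.asarray(spec.state_names, dtype=object)[state],
        "position": position,
        "condition": condition,
        "batch": batch,
        "sex": sex,
        "gate": gate,
        "gate2": np.where(doublet, gate[np.clip(partner, 0, None)], ""),
        "doublet": doublet,
        "partner": np.where(doublet, partner, -1),
        "library_size": lib,
    })
    return cm, cells, truth


# ---------------------------------------------------------------------------
# hashtag droplets
# ---------------------------------------------------------------------------

def simulate_hto(truth: pd.DataFrame, n_tags: int,
                 background_profile=None, signal_strength: float = 200.0,
                 background_strength: float = 30.0, n_empty: int = 500,
                 seed: int = 0) -> CountMatrix:
    """Hashtag-oligo counts per droplet.

    Each non-doublet cell's counts concentrate on the tag of its sorting
    gate; doublets split signal across their two gates' tags; every droplet
    additionally receives ambient background drawn from
    ``background_profile``; ``n_empty`` background-only droplets are
    appended. Tag features are named after the gate labels so the truth
    assignment is the gate itself.
    """
    rng = np.random.default_rng(seed)
    gates = sorted(set(truth["gate"]))
    if n_tags < len(gates):
        raise ValueError(
            f"n_tags={n_tags} < {len(gates)} distinct gate labels")
    tags = gates + [f"HTO_extra{i}" for i in range(n_tags - len(gates))]
    tag_idx = {t: i for i, t in enumerate(tags)}
    if background_profile is None:
        background_profile = np.full(n_tags, 1.0 / n_tags)
    bg = np.asarray(background_profile, dtype=float)
    bg = bg / bg.sum() if bg.sum() > 0 else bg

    n_cells = len(truth)
    rows = np.zeros((n_cells + n_empty, n_tags), dtype=np.int64)
    for i, (g1, g2, dbl) in enumerate(zip(truth["gate"], truth["gate2"],
                                          truth["doublet"])):
        s = rng.poisson(signal_strength)
        if dbl and g2:
            split = rng.binomial(s, 0.5)
            rows[i, tag_idx[g1]] += split
            rows[i, tag_idx[g2]] += s - split
        else:
            rows[i, tag_idx[g1]] += s
        if background_strength > 0:
            rows[i] += rng.multinomial(rng.poisson(background_strength), bg)
    for j in range(n_empty):
        if background_strength > 0:
            rows[n_cells + j] = rng.multinomial(
                rng.poisson(background_strength), bg)
    barcodes = list(truth["barcode"]) + [f"empty{j:05d}" for j in
                                         range(n_empty)]
    features = pd.DataFrame(index=pd.Index(tags, name="feature"))
    return CountMatrix(sp.csr_matrix(rows), pd.Index(barcodes), features,
                       "hto")


# ---------------------------------------------------------------------------
# scATAC fragments
# ---------------------------------------------------------------------------

def default_atac_design(n_states: int = 3, n_peaks: int = 1000,
                        hot_per_state: int = 100, hot_factor: float = 8.0,
                        baseline: float = 0.7, peak_width: int = 300
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Canonical simulated peak landscape: ``n_peaks`` non-overlapping
    ``peak_width``-bp peaks (the last three on chrY, matching the tiny chrY
    share of real peak sets), with ``hot_per_state`` disjoint peaks per
    state at ``hot_factor``-fold accessibility over baseline. Returns
    (peaks BED table, states x peaks accessibility)."""
    starts = np.arange(n_peaks) * 1000 + 500
    chrom = np.array(["chr1"] * n_peaks, dtype=object)
    chrom[-3:] = "chrY"
    peaks = pd.DataFrame({"chrom": chrom, "start": starts,
                          "end": starts + peak_width,
                          "name": [f"peak{i:05d}" for i in range(n_peaks)]})
    acc = np.full((n_states, n_peaks), baseline)
    for k in range(n_states):
        acc[k, k * hot_per_state:(k + 1) * hot_per_state] = \
            baseline * hot_factor
    return peaks, acc

def simulate_fragments(truth: pd.DataFrame, peaks: pd.DataFrame,
                       per_state_accessibility: np.ndarray,
                       depth_params: tuple = (np.log(20.0), 0.3),
                       seed: int = 0, path=None,
                       frag_len: int = 50) -> pd.DataFrame:
    """Emit a fragments table with per-peak Poisson counts.

    ``per_state_accessibility`` is a (K, n_peaks) array of relative
    accessibilities; a cell in state k yields
    ``Poisson(depth * accessibility[k, p])`` fragments in peak p, each
    placed uniformly within the peak. chrY peaks are silenced for female
    cells. The output is sorted by (chrom, start); if ``path`` is given the
    table is also written as a 5-column TSV (gzip by extension).
    """
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    for _, grp in peaks.groupby("chrom"):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValueError("overlapping peaks")
    acc = np.asarray(per_state_accessibility, dtype=float)
    if acc.shape[1] != len(peaks):
        raise ValueError("accessibility shape inconsistent with peaks")
    rng = np.random.default_rng(seed)
    depth = rng.lognormal(depth_params[0], depth_params[1], len(truth))
    is_y = (peaks["chrom"] == "chrY").to_numpy()
    state = truth["state"].to_numpy() - 1
    female = truth["sex"].to_numpy() == "female"
    lam = depth[:, None] * acc[state]
    lam[np.ix_(female, is_y)] = 0.0
    counts = rng.poisson(lam)                     # cells x peaks
    cell_idx, peak_idx = np.nonzero(counts)
    reps = counts[cell_idx, peak_idx]
    cell_idx = np.repeat(cell_idx, reps)
    peak_idx = np.repeat(peak_idx, reps)
    p_start = peaks["start"].to_numpy()[peak_idx]
    width = (peaks["end"] - peaks["start"]).to_numpy()[peak_idx]
    L = np.minimum(frag_len, width)
    starts = p_start + (rng.random(len(peak_idx))
                        * (width - L + 1)).astype(np.int64)
    frags = pd.DataFrame({
        "chrom": peaks["chrom"].to_numpy()[peak_idx],
        "start": starts,
        "end": starts + L,
        "barcode": truth["barcode"].to_numpy()[cell_idx],
        "support": 1,
    })
    frags = frags.sort_values(["chrom", "start"], kind="stable"
                              ).reset_index(drop=True)
    if path is not None:
        write_fragments(frags, path)
    return frags
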