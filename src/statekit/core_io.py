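"""Shared containers, configuration, and file I/O.

Everything downstream operates on three containers:

* :class:`CountMatrix` — sparse non-negative integer cells x features counts
  with barcode/feature registries and a modality tag (``gene``/``hto``/``peak``).
* a cell annotation table (a :class:`pandas.DataFrame`, one row per barcode,
  see :func:`make_cell_table`).
* :class:`ExpressionMatrix` — a dense real-valued cells x genes matrix that
  carries a transform tag and a provenance chain so each stage can assert it
  is being fed the representation it expects.

Genomic intervals anywhere in the package are 0-based half-open
``[start, end)`` (BED dialect). Matrices are stored cells x features
internally regardless of on-disk orientation; the CellRanger triplet dialect
(features x cells) is auto-detected from the registry lengths on read.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("statekit")

CONDITIONS = ("control", "dmPGE2", "polyIC", "GCSF", "indomethacin", "other")
SEXES = ("male", "female", "unknown")
GATES = ("HSC", "MPP0", "MPP1", "MPP2", "MPP34", "none")
MODALITIES = ("gene", "hto", "peak")
TRANSFORMS = ("raw", "cp10k_log", "scaled", "batch_adjusted")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse cells x features UMI/fragment/tag count matrix.

    Parameters
    ----------
    values
        ``scipy.sparse`` matrix of non-negative integer counts, cells in rows.
    barcodes
        Ordered unique cell identifiers (length = n rows).
    features
        Feature metadata table indexed by unique feature id. Optional columns
        used downstream: ``chrom`` (genes/peaks), ``mito`` (bool, genes).
    modality
        One of ``gene``, ``hto``, ``peak``. Modalities are never mixed.
    """

    values: sp.spmatrix
    barcodes: pd.Index
    features: pd.DataFrame
    modality: str = "gene"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.barcodes = pd.Index(self.barcodes, name="barcode")
        if not isinstance(self.features, pd.DataFrame):
            self.features = pd.DataFrame(index=pd.Index(self.features))
        self.features.index.name = "feature"
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        n, m = self.values.shape
        if len(self.barcodes) != n:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {n} matrix rows")
        if len(self.features) != m:
            raise ValueError(
                f"{len(self.features)} features for {m} matrix columns")
        if self.barcodes.has_duplicates:
            dup = self.barcodes[self.barcodes.duplicated()][0]
            raise ValueError(f"duplicate barcode {dup!r}")
        if self.features.index.has_duplicates:
            dup = self.features.index[self.features.index.duplicated()][0]
            raise ValueError(f"duplicate feature {dup!r}")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer counts")
        self.values.data = np.asarray(np.round(data), dtype=np.int64)

    # -- convenience ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of features with >=1 count per cell."""
        return np.diff(self.values.indptr)

    def subset_cells(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.values[mask], self.barcodes[mask],
                           self.features, self.modality)

    def subset_features(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.values[:, mask], self.barcodes,
                           self.features.loc[mask] if mask.dtype == bool
                           else self.features.iloc[mask], self.modality)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=float)


@dataclass
class ExpressionMatrix:
    """Dense real-valued cells x genes matrix with transform provenance."""

    values: np.ndarray
    barcodes: pd.Index
    genes: pd.Index
    transform: str = "raw"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.barcodes = pd.Index(self.barcodes, name="barcode")
        self.genes = pd.Index(self.genes, name="gene")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.values.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError("matrix shape inconsistent with registries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values, transform: str, op: str, **params
                    ) -> "ExpressionMatrix":
        """Derived matrix recording ``op`` in the provenance chain."""
        return ExpressionMatrix(values, self.barcodes, self.genes, transform,
                                self.provenance + [(op, params)])

    def subset_cells(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(self.values[mask], self.barcodes[mask],
                                self.genes, self.transform,
                                list(self.provenance))

    def gene_vector(self, gene: str) -> np.ndarray:
        return self.values[:, self.genes.get_loc(gene)]


def make_cell_table(barcodes, condition="control", sex="unknown", batch="b0",
                    gate="none") -> pd.DataFrame:
    """One-row-per-barcode annotation table with declared vocabularies."""
    n = len(barcodes)
    tab = pd.DataFrame({
        "barcode": list(barcodes),
        "condition": pd.Categorical(
            np.broadcast_to(condition, n), categories=CONDITIONS),
        "sex": pd.Categorical(np.broadcast_to(sex, n), categories=SEXES),
        "batch": np.broadcast_to(batch, n),
        "gate": pd.Categorical(np.broadcast_to(gate, n), categories=GATES),
    })
    if tab["condition"].isna().any() or tab["sex"].isna().any() \
            or tab["gate"].isna().any():
        raise ValueError("value outside declared vocabulary")
    if tab["barcode"].duplicated().any():
        raise ValueError("duplicate barcode in cell table")
    return tab


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All thresholds and defaults of the analysis pipeline.

    QC thresholds follow the study design: droplets below 3000 UMIs are
    discarded; the gene floor and count ceiling depend on the sorted
    population (HSC vs MPP); at most 10% of UMIs may map to mitochondrial
    genes; genes seen in fewer than 20 cells are dropped.
    """

    min_umi: int = 3000
    min_genes_hsc: int = 1500
    min_genes_mpp: int = 2000
    max_counts_hsc: int = 20000
    max_counts_mpp: int = 30000
    max_mito_frac: float = 0.10
    min_cells_per_gene: int = 20
    target_sum: float = 10000.0
    n_pcs: int = 50
    k_grid: tuple = (10, 15, 30)
    resolution_grid: tuple = tuple(np.round(np.arange(0.1, 1.5, 0.1), 2))
    top_n: int = 100
    fc_cutoffs: tuple = (1.0, 1.2, 1.5)
    fdr: float = 0.01
    min_expr_frac: float = 0.05
    n_bins_pt: int = 10
    kde_bandwidth: float = 0.02
    summit_width: int = 300
    atac_min_frag: int = 1000
    atac_max_frag: int = 20000
    mito_prefix: str = "mt-"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_umi", "min_genes_hsc", "min_genes_mpp",
                     "max_counts_hsc", "max_counts_mpp", "max_mito_frac",
                     "min_cells_per_gene", "target_sum", "n_pcs", "top_n",
                     "fdr", "min_expr_frac", "n_bins_pt", "kde_bandwidth",
                     "summit_width", "atac_min_frag", "atac_max_frag"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.k_grid or not self.resolution_grid:
            raise ValueError("hyperparameter grids must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("k_grid", "resolution_grid", "fc_cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# MatrixMarket triplet I/O (CellRanger dialect)
# ---------------------------------------------------------------------------

def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_registry(path) -> list[str]:
    with _open_text(path) as fh:
        # features.tsv may have extra columns (id, name, type); keep column 1
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts_triplet(matrix_path, barcodes_path, features_path,
                        modality: str = "gene") -> CountMatrix:
    """Read an MTX + barcodes + features triplet into a :class:`CountMatrix`.

    Orientation is auto-detected from the registry lengths: a features x cells
    file (the CellRanger convention) is transposed so the result is always
    cells x features. Gzip is handled by extension sniffing.
    """
    with _open_text(matrix_path, "rb" if str(matrix_path).endswith(".gz")
                    else "rb") as fh:
        data = fh.read()
    mat = scipy.io.mmread(io.BytesIO(data))
    mat = sp.coo_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"non-integer entries in {matrix_path}")
    barcodes = _read_registry(barcodes_path)
    features = _read_registry(features_path)
    n, m = mat.shape
    if (n, m) == (len(barcodes), len(features)):
        pass
    elif (n, m) == (len(features), len(barcodes)):
        mat = mat.T
    else:
        raise ValueError(
            f"matrix {n}x{m} inconsistent with {len(barcodes)} barcodes / "
            f"{len(features)} features in {matrix_path}")
    feat = pd.DataFrame(index=pd.Index(features, name="feature"))
    return CountMatrix(mat.tocsr(), pd.Index(barcodes), feat, modality)


# ---------------------------------------------------------------------------
# fragments / BED I/O (0-based half-open intervals throughout)
# ---------------------------------------------------------------------------

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "support"]


def read_fragments(path) -> pd.DataFrame:
    """Read a 5-column scATAC fragments file (TSV, optionally gzipped)."""
    df = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS,
                     comment="#")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"fragment with start >= end at line {bad + 1}")
    if (df["support"] < 1).any():
        raise ValueError("fragment with support < 1")
    return df


def write_fragments(frags: pd.DataFrame, path) -> None:
    frags.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED3(+) intervals; extra columns ignored, name kept if present."""
    rows = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {i}: {line!r}") from exc
            rows.append((parts[0], start, end,
                         parts[3] if len(parts) > 3 else f"interval_{i}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name")
            if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_counts_triplet(counts: CountMatrix, matrix_path, barcodes_path,
                         features_path) -> None:
    """Write the triplet; cells x features orientation, integer field."""
    coo = sp.coo_matrix(counts.values)
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, coo, field="integer")
    mode = "wb"
    opener = gzip.open if str(matrix_path).endswith(".gz") else open
    with opener(str(matrix_path), mode) as fh:
        fh.write(buf.getvalue())
    with _open_text(barcodes_path, "wt") as fh:
        fh.write("\n".join(map(str, counts.barcodes)) + "\n")
    with _open_text(features_path, "wt") as fh:
        fh.write("\n".join(map(str, counts.feature_ids)) + "\n")
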