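"""Count-matrix ingest, normalization, and drug x gene x cell tensor assembly.

The observed design is "one drug per cell": a cell contributes an expression
profile for exactly one drug, so the (drug, gene, cell) tensor is structurally
missing everywhere except the treated drug's slab.  Dropout zeros inside an
observed profile are additionally treated as missing by default (see
``build_tensor``), which is what pushes per-group missing ratios above 95%
in real datasets of this kind.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import DataError, FormatError

QUALITY_REMOVE = frozenset({"doublet", "empty-droplet"})


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer UMI counts."""

    values: sp.spmatrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise DataError(
                f"count matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DataError("duplicate cell ids")
        if self.min() < 0:
            raise DataError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def min(self) -> float:
        v = self.values
        if sp.issparse(v):
            return float(v.data.min()) if v.nnz else 0.0
        return float(np.min(v)) if v.size else 0.0

    def dense(self) -> np.ndarray:
        v = self.values
        return np.asarray(v.todense()) if sp.issparse(v) else np.asarray(v)


@dataclass(frozen=True)
class CellAnnotation:
    """Per-cell metadata: the single drug it received, its group, QC flags."""

    cell_id: str
    drug: str
    group: str
    quality_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.group:
            raise DataError(f"cell {self.cell_id}: empty group")


@dataclass
class ExpressionTensor:
    """Dense 3-way array of normalized expression, modes (drugs, genes, cells)."""

    values: np.ndarray
    drug_labels: list[str]
    gene_labels: list[str]
    cell_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.drug_labels), len(self.gene_labels), len(self.cell_labels))
        if self.values.shape != expected:
            raise DataError(
                f"tensor shape {self.values.shape} does not match labels {expected}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class WeightMask:
    """Binary indicator of observed entries; same shape as its tensor."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise DataError("mask entries must be 0 or 1")
        self.values = self.values.astype(float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def n_observed(self) -> int:
        return int(self.values.sum())


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_one(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for cand in (directory / stem, directory / (stem + ".gz")):
            if cand.exists():
                return cand
    raise FormatError(f"none of {stems} found in {directory}")


def read_10x_counts(path: str | Path) -> CountMatrix:
    """Read a 10x-style directory (matrix.mtx + features/genes + barcodes).

    Accepts plain or gzipped files.  Duplicate (gene, cell) coordinate entries
    are summed, per the MatrixMarket coordinate convention.
    """
    directory = Path(path)
    mtx_path = _find_one(directory, ["matrix.mtx"])
    feat_path = _find_one(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find_one(directory, ["barcodes.tsv"])

    try:
        with _open_maybe_gz(mtx_path) as fh:
            buffer = io.StringIO(fh.read())
        matrix = scipy.io.mmread(buffer)
    except ValueError as exc:
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    matrix = sp.coo_matrix(matrix).tocsr()  # tocsr sums duplicate coordinates

    with _open_maybe_gz(feat_path) as fh:
        features = pd.read_csv(fh, sep="\t", header=None)
    with _open_maybe_gz(bc_path) as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None)
    gene_ids = features.iloc[:, 0].astype(str).tolist()
    cell_ids = barcodes.iloc[:, 0].astype(str).tolist()
    if matrix.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix shape {matrix.shape} does not match {len(gene_ids)} features "
            f"x {len(cell_ids)} barcodes"
        )
    return CountMatrix(matrix, gene_ids, cell_ids)


def read_annotations(path: str | Path) -> list[CellAnnotation]:
    """Read a TSV with columns cell_id, drug, group and optional flags."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"cell_id", "drug", "group"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation file must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        flags = getattr(row, "flags", "") or ""
        out.append(
            CellAnnotation(
                cell_id=row.cell_id,
                drug=row.drug,
                group=row.group,
                quality_flags=frozenset(f for f in flags.split(",") if f),
            )
        )
    return out


def filter_cells(
    counts: CountMatrix,
    annotations: Sequence[CellAnnotation],
    min_cells: int = 3,
    min_features: int = 200,
) -> CountMatrix:
    """QC filtering: drop flagged cells, rare genes, and low-complexity cells.

    Genes detected (count > 0) in fewer than ``min_cells`` cells are removed;
    cells with fewer than ``min_features`` detected genes are removed; cells
    flagged as doublets or empty droplets are removed.  Both detection
    thresholds are evaluated on the flag-filtered matrix, and input ordering
    is preserved.
    """
    if min_cells < 0 or min_features < 0:
        raise DataError("thresholds must be non-negative")
    flags = {a.cell_id: a.quality_flags for a in annotations}
    keep_flag = np.array(
        [not (flags.get(c, frozenset()) & QUALITY_REMOVE) for c in counts.cell_ids]
    )
    values = counts.values.tocsc() if sp.issparse(counts.values) else np.asarray(counts.values)
    values = values[:, keep_flag]
    detected = (values > 0)
    if sp.issparse(detected):
        genes_per_cell = np.asarray(detected.sum(axis=0)).ravel()
        cells_per_gene = np.asarray(detected.sum(axis=1)).ravel()
    else:
        genes_per_cell = detected.sum(axis=0)
        cells_per_gene = detected.sum(axis=1)
    keep_gene = cells_per_gene >= min_cells
    keep_cell = genes_per_cell >= min_features

    n_cells = int(keep_cell.sum())
    if n_cells == 0:
        raise DataError(
            f"all cells removed (flag-removed: {int((~keep_flag).sum())}, "
            f"below min_features={min_features}: {int((~keep_cell).sum())})"
        )
    filtered = values[keep_gene][:, keep_cell]
    cell_ids = [c for c, k in zip(np.array(counts.cell_ids)[keep_flag], keep_cell) if k]
    gene_ids = [g for g, k in zip(counts.gene_ids, keep_gene) if k]
    return CountMatrix(filtered, gene_ids, list(cell_ids))


def log_normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> np.ndarray:
    """Library-size normalization: ln(count / cell_total * scale_factor + 1).

    Natural log, matching the LogNormalize convention; base-2 logs are used
    only for response signatures.  Returns a dense genes x cells array; the
    input is not modified.
    """
    if scale_factor <= 0:
        raise DataError("scale_factor must be positive")
    dense = counts.dense().astype(float)
    totals = dense.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise DataError(f"cell(s) with zero total count: {[counts.cell_ids[i] for i in zero[:5]]}")
    return np.log1p(dense / totals[None, :] * scale_factor)


def build_tensor(
    expr: np.ndarray,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
    annotations: Sequence[CellAnnotation],
    group: str,
    drugs: Sequence[str],
    zeros_are_missing: bool = True,
) -> tuple[ExpressionTensor, WeightMask]:
    """Assemble the (drugs, genes, cells) tensor for one cell group.

    Entry (d, g, c) is observed only when cell c was treated with drug d.
    With ``zeros_are_missing`` (the default), zero values inside an observed
    profile — dropout — are also marked missing, so the mask records only
    informative measurements.  Missing entries hold a placeholder 0; every
    downstream computation must route through the mask, never the placeholder.
    """
    drugs = list(drugs)
    ann_by_cell = {a.cell_id: a for a in annotations}
    group_cells = [c for c in cell_ids if c in ann_by_cell and ann_by_cell[c].group == group]
    if not group_cells:
        raise DataError(f"group {group!r} has no cells")
    for c in group_cells:
        if ann_by_cell[c].drug not in drugs:
            raise DataError(f"cell {c} annotated with unknown drug {ann_by_cell[c].drug!r}")

    expr = np.asarray(expr, dtype=float)
    col_of = {c: j for j, c in enumerate(cell_ids)}
    n_d, n_g, n_c = len(drugs), len(gene_ids), len(group_cells)
    values = np.zeros((n_d, n_g, n_c))
    mask = np.zeros((n_d, n_g, n_c))
    drug_index = {d: i for i, d in enumerate(drugs)}
    for j, c in enumerate(group_cells):
        d = drug_index[ann_by_cell[c].drug]
        profile = expr[:, col_of[c]]
        values[d, :, j] = profile
        mask[d, :, j] = 1.0
        if zeros_are_missing:
            mask[d, profile == 0, j] = 0.0
    tensor = ExpressionTensor(values, drugs, list(gene_ids), group_cells)
    return tensor, WeightMask(mask)


def save_tensor(path: str | Path, tensor: ExpressionTensor, mask: WeightMask) -> None:
    """Persist tensor + mask as a compressed .npz with a JSON label sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), values=tensor.values, mask=mask.values)
    sidecar = {
        "drug_labels": tensor.drug_labels,
        "gene_labels": tensor.gene_labels,
        "cell_labels": tensor.cell_labels,
    }
    path.with_suffix(".labels.json").write_text(json.dumps(sidecar))


def load_tensor(path: str | Path) -> tuple[ExpressionTensor, WeightMask]:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    labels = json.loads(path.with_suffix(".labels.json").read_text())
    tensor = ExpressionTensor(
        arrays["values"], labels["drug_labels"], labels["gene_labels"], labels["cell_labels"]
    )
    return tensor, WeightMask(arrays["mask"])
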