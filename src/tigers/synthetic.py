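"""Synthetic drug x gene x cell datasets with planted low-rank structure.

The generator emulates the *structure* of drug-perturbation single-cell
experiments — a handful of drugs including a vehicle control, cell-type
blocks with marker genes, one drug per cell, and dropout — on top of an
exactly low-rank nonnegative ground truth, so that completion, signature,
enrichment and trajectory code can all be exercised and checked against a
known truth.  It does not attempt count-level distributional realism
(no negative-binomial library-size model); values live on the
log-normalized scale on which completion operates.

Construction: a CP model with one latent component per cell type plus one
drug-effect component.  Cells load on their own type's component, marker
genes load strongly on their type's component only, and the effect component
couples (effect drug) x (effect genes) x (affected cell type) with magnitude
``drug_effect_size``.  All factors are nonnegative, so the ground truth is a
nonnegative tensor of exact CP rank ``n_cell_types + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .completion import CPFactors, cp_reconstruct
from .errors import DataError
from .tensor_data import CellAnnotation, ExpressionTensor, WeightMask, save_tensor
from .enrichment import GeneSetCollection

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_planted_tensor",
    "generate_gene_sets",
    "islet_small",
    "lineage_small",
    "write_10x",
]

ISLET_TYPES = ["alpha", "beta", "gamma", "delta"]
ISLET_DRUGS = ["DMSO", "artemether", "FoxOi", "GABA"]


@dataclass
class SyntheticSpec:
    """Study conditions for one planted dataset."""

    n_drugs: int = 4
    n_genes: int = 80
    n_cells: int = 160
    n_cell_types: int = 4
    marker_genes_per_type: int = 2
    n_effect_genes: int = 8
    drug_effect_size: float = 2.0
    noise_sd: float = 0.05
    dropout_rate: float = 0.3
    seed: int = 0
    drug_names: list[str] | None = None
    type_names: list[str] | None = None
    group_by: str = "type"  # "type": groups are cell types; "line": arbitrary lines
    n_lines: int = 3

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_genes, self.n_cells, self.n_cell_types) < 1:
            raise DataError("all dimensions must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise DataError("dropout_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if self.n_cell_types * self.marker_genes_per_type + self.n_effect_genes > self.n_genes:
            raise DataError("marker + effect gene allocation exceeds n_genes")
        if self.drug_names is not None and len(self.drug_names) != self.n_drugs:
            raise DataError("drug_names length mismatch")

    @property
    def planted_rank(self) -> int:
        return self.n_cell_types + 1

    @property
    def drugs(self) -> list[str]:
        if self.drug_names:
            return list(self.drug_names)
        return ["DMSO"] + [f"drug{i}" for i in range(1, self.n_drugs)]

    @property
    def types(self) -> list[str]:
        if self.type_names:
            return list(self.type_names)
        return [f"type{t}" for t in range(self.n_cell_types)]


@dataclass
class SyntheticDataset:
    """A planted dataset plus the bookkeeping needed to check recovery."""

    spec: SyntheticSpec
    ground_truth: ExpressionTensor
    observed: ExpressionTensor
    mask: WeightMask
    annotations: list[CellAnnotation]
    marker_genes: dict[str, list[str]]  # cell type -> marker gene ids
    effect_genes: list[str]
    effect_drug: str
    affected_type: str
    cell_types: dict[str, str] = field(default_factory=dict)  # cell_id -> type

    @property
    def control_drug(self) -> str:
        return self.ground_truth.drug_labels[0]


def generate_planted_tensor(spec: SyntheticSpec) -> SyntheticDataset:
    """Build ground truth, noisy observations, mask and annotations for a spec.

    The mask encodes the one-drug-per-cell design; dropout additionally zeroes
    and unmasks entries of observed profiles at ``dropout_rate``.  Observation
    noise is Gaussian on the (log-scale) values, clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    n_d, n_g, n_c, n_t = spec.n_drugs, spec.n_genes, spec.n_cells, spec.n_cell_types
    R = spec.planted_rank
    drugs = spec.drugs
    types = spec.types
    gene_ids = [f"g{i:04d}" for i in range(n_g)]
    cell_ids = [f"cell{i:04d}" for i in range(n_c)]

    # disjoint marker and effect gene blocks at the front of the gene axis
    cursor = 0
    marker_genes: dict[str, list[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    for t in types:
        idx = np.arange(cursor, cursor + spec.marker_genes_per_type)
        marker_idx[t] = idx
        marker_genes[t] = [gene_ids[i] for i in idx]
        cursor += spec.marker_genes_per_type
    effect_idx = np.arange(cursor, cursor + spec.n_effect_genes)
    effect_genes = [gene_ids[i] for i in effect_idx]

    # balanced one-drug-per-cell and cell-type assignment, then shuffled
    type_of = np.array([types[i % n_t] for i in range(n_c)])
    rng.shuffle(type_of)
    drug_of = np.array([drugs[i % n_d] for i in range(n_c)])
    rng.shuffle(drug_of)

    effect_drug = drugs[1 % n_d]
    affected_type = types[0]

    # CP factors: component t is cell type t's block, component R-1 the drug effect
    A = np.zeros((n_d, R))  # drugs
    B = np.zeros((n_g, R))  # genes
    C = np.zeros((n_c, R))  # cells
    A[:, :n_t] = rng.uniform(0.8, 1.2, size=(n_d, n_t))
    B[:, :n_t] = rng.uniform(0.3, 1.0, size=(n_g, n_t))
    for t_i, t in enumerate(types):
        B[marker_idx[t], :n_t] = rng.uniform(0.0, 0.05, size=(len(marker_idx[t]), n_t))
        B[marker_idx[t], t_i] = rng.uniform(2.5, 3.5, size=len(marker_idx[t]))
        C[type_of == t, t_i] = rng.uniform(0.8, 1.2, size=int((type_of == t).sum()))
    if spec.drug_effect_size > 0:
        A[drugs.index(effect_drug), R - 1] = spec.drug_effect_size
        B[effect_idx, R - 1] = rng.uniform(0.8, 1.2, size=len(effect_idx))
        affected = type_of == affected_type
        C[affected, R - 1] = rng.uniform(0.8, 1.2, size=int(affected.sum()))

    truth_values = cp_reconstruct(CPFactors([A, B, C]))
    truth = ExpressionTensor(truth_values.copy(), drugs, gene_ids, cell_ids)

    mask = np.zeros((n_d, n_g, n_c))
    observed = np.zeros((n_d, n_g, n_c))
    drug_index = {d: i for i, d in enumerate(drugs)}
    for c in range(n_c):
        d = drug_index[drug_of[c]]
        profile = truth_values[d, :, c]
        if spec.noise_sd > 0:
            profile = np.clip(profile + rng.normal(0.0, spec.noise_sd, size=n_g), 0.0, None)
        keep = np.ones(n_g, dtype=bool)
        if spec.dropout_rate > 0:
            keep = rng.random(n_g) >= spec.dropout_rate
        observed[d, keep, c] = profile[keep]
        mask[d, keep, c] = 1.0

    if spec.group_by == "line":
        lines = [f"line{i}" for i in range(spec.n_lines)]
        group_of = {cell_ids[i]: lines[i % spec.n_lines] for i in range(n_c)}
    else:
        group_of = {cell_ids[i]: type_of[i] for i in range(n_c)}
    annotations = [
        CellAnnotation(cell_ids[i], drug_of[i], group_of[cell_ids[i]]) for i in range(n_c)
    ]
    return SyntheticDataset(
        spec=spec,
        ground_truth=truth,
        observed=ExpressionTensor(observed, drugs, gene_ids, cell_ids),
        mask=WeightMask(mask),
        annotations=annotations,
        marker_genes=marker_genes,
        effect_genes=effect_genes,
        effect_drug=effect_drug,
        affected_type=affected_type,
        cell_types={cell_ids[i]: type_of[i] for i in range(n_c)},
    )


def generate_gene_sets(
    dataset: SyntheticDataset,
    n_pathways: int = 50,
    genes_per_pathway: int = 8,
    planted_regulated_pathway: str = "planted",
    seed: int | None = None,
) -> GeneSetCollection:
    """Random pathway gene sets plus one planted set enriched for effect genes.

    The planted pathway is drawn preferentially from the genes carrying the
    drug effect, so an end-to-end enrichment run should recover it; the other
    pathways are uniform draws from the gene universe.  All sets have exactly
    ``genes_per_pathway`` genes; the universe is the full gene axis.
    """
    spec = dataset.spec
    genes = dataset.ground_truth.gene_labels
    if genes_per_pathway > len(genes):
        raise DataError("genes_per_pathway exceeds gene universe")
    if n_pathways < 1:
        raise DataError("need at least one pathway")
    rng = np.random.default_rng(spec.seed + 7919 if seed is None else seed)
    sets: dict[str, frozenset[str]] = {}
    planted = list(dataset.effect_genes[:genes_per_pathway])
    if len(planted) < genes_per_pathway:
        pool = [g for g in genes if g not in planted]
        extra = rng.choice(len(pool), size=genes_per_pathway - len(planted), replace=False)
        planted += [pool[i] for i in extra]
    sets[planted_regulated_pathway] = frozenset(planted)
    for i in range(n_pathways - 1):
        pick = rng.choice(len(genes), size=genes_per_pathway, replace=False)
        sets[f"pathway{i:03d}"] = frozenset(genes[j] for j in pick)
    return GeneSetCollection(sets, universe_size=len(genes))


def islet_small(seed: int = 0, **overrides) -> SyntheticDataset:
    """Small pancreatic-islet-like preset: 4 drugs incl. DMSO, 4 cell types
    with 2 markers each, moderate dropout."""
    params = dict(
        n_drugs=4,
        n_genes=80,
        n_cells=160,
        n_cell_types=4,
        marker_genes_per_type=2,
        n_effect_genes=8,
        drug_effect_size=2.0,
        noise_sd=0.05,
        dropout_rate=0.3,
        seed=seed,
        drug_names=ISLET_DRUGS,
        type_names=ISLET_TYPES,
    )
    params.update(overrides)
    return generate_planted_tensor(SyntheticSpec(**params))


def lineage_small(seed: int = 0, **overrides) -> SyntheticDataset:
    """Lineage preset: 3 cell lines sharing one latent factor model, so pooled
    (lineage-based) completion can be compared with per-line completion."""
    params = dict(
        n_drugs=4,
        n_genes=60,
        n_cells=180,
        n_cell_types=2,
        marker_genes_per_type=2,
        n_effect_genes=6,
        drug_effect_size=1.0,
        noise_sd=0.05,
        dropout_rate=0.2,
        seed=seed,
        group_by="line",
        n_lines=3,
    )
    params.update(overrides)
    return generate_planted_tensor(SyntheticSpec(**params))


def write_10x(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the observed data as MTX + feature/barcode/annotation TSVs plus
    ground-truth arrays, consumable by the build stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tensor = dataset.observed
    n_g = len(tensor.gene_labels)
    n_c = len(tensor.cell_labels)
    drug_index = {d: i for i, d in enumerate(tensor.drug_labels)}
    matrix = np.zeros((n_g, n_c))
    for j, ann in enumerate(dataset.annotations):
        matrix[:, j] = tensor.values[drug_index[ann.drug], :, j]
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(matrix))
    (out / "features.tsv").write_text("".join(f"{g}\t{g}\n" for g in tensor.gene_labels))
    (out / "barcodes.tsv").write_text("".join(f"{c}\n" for c in tensor.cell_labels))
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("cell_id\tdrug\tgroup\tflags\n")
        for ann in dataset.annotations:
            fh.write(f"{ann.cell_id}\t{ann.drug}\t{ann.group}\t\n")
    save_tensor(out / "truth", dataset.ground_truth, dataset.mask)
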