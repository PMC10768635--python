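"""Hypergeometric pathway over-representation with BH-FDR adjustment.

Up- and down-regulated gene sets (top/bottom fraction of a response
signature) are tested against each pathway gene set.  With a universe of l
genes, a pathway of k genes, a query of r genes and an overlap of z genes,
the upper-tail hypergeometric probability is

    P = sum_{i=z}^{min(k, r)}  C(k, i) C(l-k, r-i) / C(l, r).

P values are Benjamini-Hochberg adjusted separately within each direction
(activated from the up-set, inactivated from the down-set), and per-cell
pathway features are the -log10 of the adjusted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError, FormatError
from .signatures import ResponseSignature

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "CellPathwayFeatures",
    "read_gmt",
    "select_regulated_genes",
    "hypergeom_p",
    "bh_fdr",
    "enrich_signature",
    "cell_pathway_features",
]


@dataclass
class GeneSetCollection:
    """Named pathway gene sets plus the size l of the gene universe."""

    sets: dict[str, frozenset[str]]
    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise DataError("universe size must be positive")
        for name, genes in self.sets.items():
            if not genes:
                raise DataError(f"pathway {name!r} is empty")
            if len(genes) > self.universe_size:
                raise DataError(
                    f"pathway {name!r} has {len(genes)} genes, exceeding universe "
                    f"{self.universe_size}"
                )

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    """Per-pathway overlap counts, P values and BH q values for one direction."""

    table: pd.DataFrame  # columns: pathway, z, k, r, l, p, q, neglog10q
    direction: str  # "activated" | "inactivated"


@dataclass
class CellPathwayFeatures:
    """Per-cell -log10(q) feature vectors for activation and inhibition."""

    f_act: np.ndarray
    f_inh: np.ndarray
    cell_id: str
    drug: str
    pathway_ids: list[str]

    def __post_init__(self) -> None:
        self.f_act = np.asarray(self.f_act, dtype=float)
        self.f_inh = np.asarray(self.f_inh, dtype=float)
        if self.f_act.shape != self.f_inh.shape or self.f_act.ndim != 1:
            raise DataError("feature vectors must be 1-D and equally long")
        if (self.f_act < 0).any() or (self.f_inh < 0).any():
            raise DataError("features must be non-negative")


def read_gmt(path: str | Path, universe_size: int | None = None) -> GeneSetCollection:
    """Parse a GMT file (name, description, genes...), one pathway per line.

    Duplicate genes within a line are collapsed.  If ``universe_size`` is not
    given, the union of all listed genes defines the universe.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} lists no genes")
            sets[name] = genes
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    if universe_size is None:
        universe_size = len(frozenset.union(*sets.values()))
    return GeneSetCollection(sets, universe_size)


def select_regulated_genes(
    signature: ResponseSignature, gene_ids: Sequence[str], fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """Top/bottom ``fraction`` of genes by signature value.

    Both sets have floor(fraction * p) genes; ties at the boundary are broken
    by gene order (stable sort on value then index), and the sets are kept
    disjoint by construction.
    """
    if not 0 < fraction < 0.5:
        raise DataError(f"fraction must be in (0, 0.5), got {fraction}")
    values = signature.values
    p = len(values)
    if p != len(gene_ids):
        raise DataError(f"signature length {p} != {len(gene_ids)} gene ids")
    n = int(np.floor(fraction * p))
    if n == 0:
        raise DataError(f"fraction {fraction} of {p} genes selects zero genes")
    # stable ascending sort == lexicographic (value, gene index)
    order = np.argsort(values, kind="stable")
    down = [gene_ids[i] for i in order[:n]]
    up = [gene_ids[i] for i in order[-n:]]
    return up, down


def hypergeom_p(k: int, r: int, z: int, l: int) -> float:
    """Upper-tail hypergeometric probability of an overlap of at least z.

    Parameters are the pathway size k, the query size r, the observed overlap
    z and the universe size l.  Evaluated with the log-space survival
    function, so it stays accurate at l in the thousands.
    """
    if not (0 <= k <= l and 0 <= r <= l):
        raise DataError(f"need 0 <= k,r <= l, got k={k}, r={r}, l={l}")
    if not 0 <= z <= min(k, r):
        raise DataError(f"overlap z={z} outside [0, min(k,r)={min(k, r)}]")
    if r - z > l - k and z > min(k, r):
        raise DataError("impossible configuration")
    # P(Z >= z) with Z ~ Hypergeom(l, k, r)
    return float(hypergeom.sf(z - 1, l, k, r))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _enrich_direction(
    query: Sequence[str], collection: GeneSetCollection, direction: str
) -> EnrichmentResult:
    query_set = frozenset(query)
    r = len(query_set)
    l = collection.universe_size
    rows = []
    for name, genes in collection.sets.items():
        k = len(genes)
        z = len(query_set & genes)
        rows.append((name, z, k, r, l, hypergeom_p(k, r, z, l)))
    df = pd.DataFrame(rows, columns=["pathway", "z", "k", "r", "l", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["neglog10q"] = -np.log10(df["q"])
    return EnrichmentResult(df, direction)


def enrich_signature(
    signature: ResponseSignature,
    gene_ids: Sequence[str],
    collection: GeneSetCollection,
    fraction: float = 0.05,
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Test the up-set (activated) and down-set (inactivated) of one signature.

    Each direction is FDR-adjusted across the collection's pathways
    separately.
    """
    up, down = select_regulated_genes(signature, gene_ids, fraction)
    return (
        _enrich_direction(up, collection, "activated"),
        _enrich_direction(down, collection, "inactivated"),
    )


def cell_pathway_features(
    signature: ResponseSignature,
    gene_ids: Sequence[str],
    collection: GeneSetCollection,
    fraction: float = 0.05,
) -> CellPathwayFeatures:
    """-log10 of FDR-adjusted P values, one activation and one inhibition vector."""
    act, inh = enrich_signature(signature, gene_ids, collection, fraction)
    return CellPathwayFeatures(
        f_act=-np.log10(act.table["q"].to_numpy()),
        f_inh=-np.log10(inh.table["q"].to_numpy()),
        cell_id=signature.cell_id,
        drug=signature.drug,
        pathway_ids=collection.pathway_ids,
    )
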