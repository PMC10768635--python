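"""Pathway-trajectory analysis on a cell-state graph.

A trajectory is an undirected graph G = (v, e) whose vertexes live in the
same 2-D embedding as the cells (in the source workflow the graph comes from
an external principal-graph learner over a UMAP embedding; it is consumed
here as input).  Each cell is attached to its Euclidean-nearest vertex, and
the per-cell pathway feature vectors are averaged within each vertex, giving
vertex x pathway matrices F_act and F_inh that describe transient pathway
activity along the trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .enrichment import CellPathwayFeatures
from .errors import DataError, FormatError

__all__ = [
    "TrajectoryGraph",
    "PathwayTrajectoryMatrices",
    "assign_cells_to_vertexes",
    "vertex_pathway_matrices",
    "build_simple_trajectory",
    "read_trajectory",
]


@dataclass
class TrajectoryGraph:
    """Vertexes with 2-D coordinates, undirected edges, and the cell embedding."""

    vertex_ids: list[str]
    vertex_coords: np.ndarray  # |v| x 2
    edges: list[tuple[str, str]]
    cell_ids: list[str]
    cell_embedding: np.ndarray  # cells x 2
    vertex_kind: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.cell_embedding = np.asarray(self.cell_embedding, dtype=float)
        if len(self.vertex_ids) == 0:
            raise DataError("trajectory needs at least one vertex")
        if self.vertex_coords.shape != (len(self.vertex_ids), 2):
            raise DataError("vertex coordinate table must be |v| x 2")
        if self.cell_embedding.shape != (len(self.cell_ids), 2):
            raise DataError("cell embedding must be cells x 2")
        known = set(self.vertex_ids)
        for a, b in self.edges:
            if a not in known or b not in known:
                raise DataError(f"edge ({a}, {b}) references unknown vertex")
        if not self.vertex_kind:
            self.vertex_kind = self._classify()

    def _classify(self) -> dict[str, str]:
        degree = {v: 0 for v in self.vertex_ids}
        for a, b in self.edges:
            degree[a] += 1
            degree[b] += 1
        kinds = {}
        for v, d in degree.items():
            kinds[v] = "leaf" if d <= 1 else ("branch" if d >= 3 else "internal")
        return kinds


@dataclass
class PathwayTrajectoryMatrices:
    """Vertex x pathway activation/inhibition matrices with the cell assignment."""

    F_act: np.ndarray
    F_inh: np.ndarray
    vertex_ids: list[str]
    pathway_ids: list[str]
    assignment: dict[str, str]  # cell_id -> vertex_id
    empty_vertexes: list[str]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        act = pd.DataFrame(self.F_act, index=self.vertex_ids, columns=self.pathway_ids)
        inh = pd.DataFrame(self.F_inh, index=self.vertex_ids, columns=self.pathway_ids)
        return act, inh


def assign_cells_to_vertexes(graph: TrajectoryGraph) -> dict[str, str]:
    """Map each cell to its Euclidean-nearest vertex; ties to the lowest vertex id.

    "Lowest" is positional: the earliest vertex in the graph's vertex order.
    """
    if not np.isfinite(graph.cell_embedding).all():
        bad = [c for c, xy in zip(graph.cell_ids, graph.cell_embedding) if not np.isfinite(xy).all()]
        raise DataError(f"non-finite embedding coordinates for cells {bad[:5]}")
    dists = cdist(graph.cell_embedding, graph.vertex_coords)
    nearest = np.argmin(dists, axis=1)  # argmin returns the first (lowest) index on ties
    return {c: graph.vertex_ids[j] for c, j in zip(graph.cell_ids, nearest)}


def vertex_pathway_matrices(
    features: list[CellPathwayFeatures],
    assignment: dict[str, str],
    graph: TrajectoryGraph,
) -> PathwayTrajectoryMatrices:
    """Average per-cell pathway features within each vertex.

    Row j of F_act (resp. F_inh) is the arithmetic mean of f_act (f_inh) over
    the cells assigned to vertex j.  Vertexes with no assigned cells keep an
    all-zero row and are listed in ``empty_vertexes`` so graph rows and matrix
    rows stay in one-to-one correspondence.
    """
    by_cell = {f.cell_id: f for f in features}
    missing = [c for c in assignment if c not in by_cell]
    if missing:
        raise DataError(f"cells without features: {missing[:5]}")
    pathway_ids = features[0].pathway_ids if features else []
    d_path = len(pathway_ids)
    for f in features:
        if len(f.f_act) != d_path:
            raise DataError(
                f"feature length mismatch for cell {f.cell_id}: {len(f.f_act)} != {d_path}"
            )
    n_v = len(graph.vertex_ids)
    F_act = np.zeros((n_v, d_path))
    F_inh = np.zeros((n_v, d_path))
    row_of = {v: j for j, v in enumerate(graph.vertex_ids)}
    counts = np.zeros(n_v, dtype=int)
    for cell, vertex in assignment.items():
        j = row_of[vertex]
        f = by_cell[cell]
        F_act[j] += f.f_act
        F_inh[j] += f.f_inh
        counts[j] += 1
    nonempty = counts > 0
    F_act[nonempty] /= counts[nonempty, None]
    F_inh[nonempty] /= counts[nonempty, None]
    empty = [v for v, j in row_of.items() if counts[j] == 0]
    return PathwayTrajectoryMatrices(
        F_act, F_inh, list(graph.vertex_ids), list(pathway_ids), dict(assignment), empty
    )


def build_simple_trajectory(
    embedding: np.ndarray,
    cell_ids: list[str],
    n_vertexes: int,
    seed: int = 0,
) -> TrajectoryGraph:
    """Minimal stand-in trajectory: k-means centroids joined by their MST.

    This is plumbing so the full pipeline runs without an external
    graph-learning tool; real analyses should ingest an externally inferred
    trajectory via :func:`read_trajectory`.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2 or embedding.shape[1] != 2:
        raise DataError("embedding must be cells x 2")
    if not 1 <= n_vertexes <= embedding.shape[0]:
        raise DataError(f"n_vertexes must be in [1, {embedding.shape[0]}]")
    if n_vertexes > 1 and np.allclose(embedding, embedding[0]):
        raise DataError("degenerate embedding: all cells identical")
    if n_vertexes == 1:
        coords = embedding.mean(axis=0, keepdims=True)
        return TrajectoryGraph(["v0"], coords, [], list(cell_ids), embedding)
    km = KMeans(n_clusters=n_vertexes, random_state=seed, n_init=10)
    km.fit(embedding)
    coords = km.cluster_centers_
    dist = cdist(coords, coords)
    mst = minimum_spanning_tree(dist).tocoo()
    ids = [f"v{j}" for j in range(n_vertexes)]
    edges = [(ids[min(a, b)], ids[max(a, b)]) for a, b in zip(mst.row, mst.col)]
    return TrajectoryGraph(ids, coords, sorted(edges), list(cell_ids), embedding)


def read_trajectory(path: str | Path) -> TrajectoryGraph:
    """Load a trajectory from TSVs: vertices.tsv, edges.tsv, embedding.tsv.

    ``vertices.tsv``: columns id, x, y.  ``edges.tsv``: columns id_a, id_b
    (may be empty: disconnected trajectories are valid).  ``embedding.tsv``:
    columns cell_id, x, y.  Duplicate edges are collapsed with a warning.
    """
    directory = Path(path)
    vfile, efile, cfile = (directory / n for n in ("vertices.tsv", "edges.tsv", "embedding.tsv"))
    for f in (vfile, efile, cfile):
        if not f.exists():
            raise FormatError(f"missing trajectory file {f}")
    vdf = pd.read_csv(vfile, sep="\t", dtype={"id": str})
    edf = pd.read_csv(efile, sep="\t", dtype=str)
    cdf = pd.read_csv(cfile, sep="\t", dtype={"cell_id": str})
    vertex_ids = vdf["id"].tolist()
    known = set(vertex_ids)
    seen: set[tuple[str, str]] = set()
    edges = []
    for row in edf.itertuples(index=False):
        a, b = str(row.id_a), str(row.id_b)
        if a not in known or b not in known:
            raise FormatError(f"edge ({a}, {b}) references unknown vertex")
        key = (min(a, b), max(a, b))
        if key in seen:
            warnings.warn(f"duplicate edge {key} collapsed", stacklevel=2)
            continue
        seen.add(key)
        edges.append(key)
    return TrajectoryGraph(
        vertex_ids,
        vdf[["x", "y"]].to_numpy(dtype=float),
        edges,
        cdf["cell_id"].tolist(),
        cdf[["x", "y"]].to_numpy(dtype=float),
    )
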