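"""Similarity graph over bag-of-features histograms.

All pairwise Euclidean distances between BoFs vectors are computed and
pruned to an unweighted k-nearest-neighbour graph: an edge is kept when
either endpoint ranks the other among its k_nn closest (union
symmetrisation).  A seeded Fruchterman-Reingold force-directed layout
places the nodes in the unit square so similar images land close
together; graphs are exported as GraphML or node-link JSON for
downstream viewers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .codebook import BoFsHistogram
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "DistanceMatrix",
    "SimilarityGraph",
    "pairwise_distances",
    "build_knn_graph",
    "layout_force_directed",
    "layout_energy",
    "export_graph",
    "read_graph",
    "save_distance_matrix",
    "load_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """Symmetric n x n Euclidean distance matrix over image ids."""

    ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.float64)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise InvalidInputError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(self.D)):
            raise InvalidInputError("distances must be finite")
        if np.any(np.abs(self.D - self.D.T) > 1e-9):
            raise InvalidInputError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.D)) > 1e-12):
            raise InvalidInputError("distance matrix diagonal must be zero")


@dataclass
class SimilarityGraph:
    """Unweighted k-NN graph over image ids.

    ``graph`` is an undirected networkx Graph (no self loops); ``coords``
    optionally maps each id to a 2-D layout position; ``word_subset``
    records the visual-word indices the distances were computed on
    (None means all words).
    """

    graph: nx.Graph
    k_nn: int
    coords: dict[str, tuple[float, float]] | None = None
    word_subset: list[int] | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


def pairwise_distances(histograms: list[BoFsHistogram]) -> DistanceMatrix:
    """Euclidean distances between all pairs of BoFs vectors."""
    if len(histograms) < 2:
        raise InvalidInputError("need at least 2 histograms")
    k = histograms[0].k_words
    if any(h.k_words != k for h in histograms):
        raise InvalidInputError("histograms have differing lengths")
    X = np.vstack([h.freqs for h in histograms])
    D = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(ids=[h.image_id for h in histograms], D=D)


def build_knn_graph(D: DistanceMatrix, k_nn: int = 3) -> SimilarityGraph:
    """Unweighted k-NN graph with union symmetrisation.

    Every node is connected to its ``k_nn`` nearest other nodes; because
    either endpoint can contribute an edge, node degrees are >= k_nn.
    Distance ties are broken by ascending node index for
    reproducibility.
    """
    n = len(D.ids)
    if not 1 <= k_nn <= n - 1:
        raise InvalidParameterError(f"k_nn must lie in [1, {n - 1}], got {k_nn}")
    g = nx.Graph()
    g.add_nodes_from(D.ids)
    for i in range(n):
        order = np.argsort(D.D[i], kind="stable")  # ties -> lower index first
        neighbours = [j for j in order if j != i][:k_nn]
        for j in neighbours:
            g.add_edge(D.ids[i], D.ids[j])
    return SimilarityGraph(graph=g, k_nn=k_nn)


# ---------------------------------------------------------------------------
# layout


def _fr_forces(pos: np.ndarray, edge_idx: np.ndarray, k: float) -> np.ndarray:
    delta = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(delta, axis=2)
    np.fill_diagonal(dist, 1.0)
    dist = np.maximum(dist, 1e-9)
    # repulsion k^2/d between all pairs
    disp = (delta / dist[:, :, None]) * (k**2 / dist)[:, :, None]
    np.einsum("iik->ik", disp)[:] = 0.0
    disp = disp.sum(axis=1)
    # attraction d^2/k along edges
    if len(edge_idx):
        i, j = edge_idx[:, 0], edge_idx[:, 1]
        dvec = pos[i] - pos[j]
        d = np.maximum(np.linalg.norm(dvec, axis=1, keepdims=True), 1e-9)
        f = dvec / d * (d**2 / k)
        np.add.at(disp, i, -f)
        np.add.at(disp, j, f)
    return disp


def layout_force_directed(
    g: SimilarityGraph, seed: int = 7, n_iter: int = 300
) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold layout in the unit square.

    Nodes start on a jittered circle around (0.5, 0.5) and move under
    pairwise repulsion (k^2/d) and per-edge attraction (d^2/k), with the
    spring length k = sqrt(area/n) for unit area.  Step sizes are capped
    by a geometrically cooled temperature, so the result is
    deterministic for a fixed seed.  The final configuration is
    recentred on (0.5, 0.5) and uniformly rescaled only if it overflows
    the unit square, preserving relative distances otherwise.  A single
    node sits at the centre; isolated nodes are pushed outward by
    repulsion alone.
    """
    ids = list(g.graph.nodes)
    n = len(ids)
    if n == 0:
        raise InvalidInputError("cannot lay out an empty graph")
    if n == 1:
        return {ids[0]: (0.5, 0.5)}

    rng = np.random.default_rng(seed)
    angles = 2 * np.pi * np.arange(n) / n
    pos = 0.25 * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    pos += rng.normal(scale=0.01, size=pos.shape)

    index = {v: i for i, v in enumerate(ids)}
    edge_idx = np.array(
        [[index[a], index[b]] for a, b in g.graph.edges], dtype=np.intp
    ).reshape(-1, 2)
    k = np.sqrt(1.0 / n)

    t = 0.1
    for _ in range(n_iter):
        disp = _fr_forces(pos, edge_idx, k)
        length = np.maximum(np.linalg.norm(disp, axis=1, keepdims=True), 1e-12)
        pos = pos + disp / length * np.minimum(length, t)
        t *= 0.95

    pos = pos - pos.mean(axis=0)
    extent = np.abs(pos).max()
    if extent > 0.5:
        pos = pos * (0.5 / extent)
    pos = pos + 0.5
    return {v: (float(x), float(y)) for v, (x, y) in zip(ids, pos)}


def layout_energy(
    g: SimilarityGraph, coords: dict[str, tuple[float, float]]
) -> float:
    """Fruchterman-Reingold potential of a configuration: sum of
    attractive terms d^3/(3k) over edges minus k^2 log d over all pairs.
    Useful for checking that the layout actually descends."""
    ids = list(g.graph.nodes)
    n = len(ids)
    pos = np.array([coords[v] for v in ids])
    k = np.sqrt(1.0 / n)
    dist = squareform(pdist(pos))
    iu = np.triu_indices(n, 1)
    rep = -(k**2) * np.sum(np.log(np.maximum(dist[iu], 1e-9)))
    att = 0.0
    for a, b in g.graph.edges:
        d = np.linalg.norm(pos[ids.index(a)] - pos[ids.index(b)])
        att += d**3 / (3 * k)
    return float(att + rep)


# ---------------------------------------------------------------------------
# export / import


def _graph_with_attributes(g: SimilarityGraph, annotations=None) -> nx.Graph:
    out = nx.Graph()
    out.graph["k_nn"] = g.k_nn
    if g.word_subset is not None:
        out.graph["word_subset"] = ",".join(map(str, g.word_subset))
    out.add_nodes_from(g.graph.nodes)
    out.add_edges_from(g.graph.edges)
    if g.coords:
        for v, (x, y) in g.coords.items():
            out.nodes[v]["x"] = float(x)
            out.nodes[v]["y"] = float(y)
    if annotations is not None:
        for img_id, rec in annotations.records.items():
            if img_id not in out.nodes:
                warnings.warn(
                    f"annotation id {img_id!r} not in graph; attribute omitted",
                    stacklevel=3,
                )
                continue
            if rec.score is not None:
                out.nodes[img_id]["score"] = int(rec.score)
            if rec.label is not None:
                out.nodes[img_id]["label"] = rec.label
    return out


def export_graph(
    g: SimilarityGraph,
    path: str | Path,
    annotations=None,
    format: str = "graphml",
) -> None:
    """Write the graph with node attributes (id, score, label, x, y) as
    GraphML or node-link JSON; both round-trip through :func:`read_graph`."""
    path = Path(path)
    gx = _graph_with_attributes(g, annotations)
    if format == "graphml":
        nx.write_graphml(gx, path)
    elif format == "nodelink_json":
        data = {
            "k_nn": g.k_nn,
            "word_subset": g.word_subset,
            "nodes": [{"id": v, **gx.nodes[v]} for v in gx.nodes],
            "links": [{"source": a, "target": b} for a, b in gx.edges],
        }
        path.write_text(json.dumps(data, indent=1))
    else:
        raise InvalidParameterError(f"unknown export format {format!r}")


def read_graph(path: str | Path, format: str = "graphml") -> SimilarityGraph:
    """Re-import a graph written by :func:`export_graph`, restoring node
    set, edge set, coordinates and annotation attributes."""
    path = Path(path)
    if format == "graphml":
        gx = nx.read_graphml(path)
        k_nn = int(gx.graph.get("k_nn", 1))
        subset = gx.graph.get("word_subset")
        word_subset = (
            [int(s) for s in str(subset).split(",")] if subset not in (None, "") else None
        )
    elif format == "nodelink_json":
        data = json.loads(path.read_text())
        gx = nx.Graph()
        for node in data["nodes"]:
            attrs = {kk: v for kk, v in node.items() if kk != "id"}
            gx.add_node(node["id"], **attrs)
        gx.add_edges_from((l["source"], l["target"]) for l in data["links"])
        k_nn = int(data.get("k_nn", 1))
        word_subset = data.get("word_subset")
    else:
        raise InvalidParameterError(f"unknown export format {format!r}")

    coords = None
    if all("x" in gx.nodes[v] and "y" in gx.nodes[v] for v in gx.nodes) and len(gx):
        coords = {
            v: (float(gx.nodes[v]["x"]), float(gx.nodes[v]["y"])) for v in gx.nodes
        }
    return SimilarityGraph(graph=gx, k_nn=k_nn, coords=coords, word_subset=word_subset)


def save_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(D.D, index=D.ids, columns=D.ids).to_csv(
        path, float_format="%.17g"
    )


def load_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(ids=[str(c) for c in df.columns], D=df.to_numpy())
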