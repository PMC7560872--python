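"""Mapper graph construction over a distance matrix.

Filter values are the per-sample ranks of the first two principal
coordinates (classical MDS); samples are binned by an overlapping 2D
cover of rank space; each bin is clustered by single linkage with the
first-empty-histogram-bin cutoff; the nerve of the resulting clusters is
the Mapper graph (vertices = local clusters, edges = shared samples).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from topostates.data import DistanceMatrix


@dataclass(frozen=True)
class MapperConfig:
    """Hyperparameters of the Mapper construction.

    ``n_intervals`` is the number of cover intervals per filter
    dimension, ``overlap_pct`` the percent overlap between consecutive
    intervals, and ``n_hist_bins`` the number of bins in the
    merge-height histogram used for the local clustering cutoff.
    ``seed`` only affects graph layout, never the graph itself.
    """

    n_intervals: tuple[int, int] = (10, 10)
    overlap_pct: float = 50.0
    n_hist_bins: int = 10
    metric: str = "js"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_intervals) != 2 or any(k < 1 for k in self.n_intervals):
            raise ValueError("n_intervals must be two integers >= 1")
        if not 0 < self.overlap_pct < 100:
            raise ValueError("overlap_pct must lie in (0, 100)")
        if self.n_hist_bins < 2:
            raise ValueError("n_hist_bins must be >= 2")

    def to_dict(self) -> dict:
        return {
            "n_intervals_1": self.n_intervals[0],
            "n_intervals_2": self.n_intervals[1],
            "overlap_pct": self.overlap_pct,
            "n_hist_bins": self.n_hist_bins,
            "metric": self.metric,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MapperConfig":
        return cls(
            n_intervals=(int(d["n_intervals_1"]), int(d["n_intervals_2"])),
            overlap_pct=float(d["overlap_pct"]),
            n_hist_bins=int(d.get("n_hist_bins", 10)),
            metric=str(d.get("metric", "js")),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class CoverBin:
    """One 2D bin of the cover: rank intervals and member sample indices."""

    bin_id: tuple[int, int]
    interval1: tuple[float, float]
    interval2: tuple[float, float]
    members: tuple[int, ...]


@dataclass
class MapperGraph:
    """Undirected nerve graph.

    Vertices are consecutive integers; each carries ``members`` (sorted
    tuple of sample indices) and ``bin`` (cover bin of origin). An edge
    joins two vertices iff their member sets intersect.
    """

    graph: nx.Graph
    n_samples: int
    config: MapperConfig | None = field(default=None)

    def members(self, v: int) -> tuple[int, ...]:
        return self.graph.nodes[v]["members"]

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def vertices(self) -> list[int]:
        return list(self.graph.nodes)

    def sample_vertices(self) -> dict[int, list[int]]:
        """Map each sample index to the vertices containing it."""
        out: dict[int, list[int]] = {}
        for v in self.graph.nodes:
            for i in self.graph.nodes[v]["members"]:
                out.setdefault(i, []).append(v)
        return out

    def largest_vertex_size(self) -> int:
        return max(len(self.graph.nodes[v]["members"]) for v in self.graph.nodes)

    def to_graphml(self, path: str | Path, sample_ids: list[str] | None = None) -> None:
        g = nx.Graph()
        for k, v in (self.config.to_dict() if self.config else {}).items():
            g.graph[k] = v
        g.graph["n_samples"] = self.n_samples
        for v in self.graph.nodes:
            members = self.graph.nodes[v]["members"]
            names = (
                [sample_ids[i] for i in members] if sample_ids else [str(i) for i in members]
            )
            g.add_node(
                v,
                members=";".join(names),
                size=len(members),
                bin=str(self.graph.nodes[v].get("bin", "")),
            )
        g.add_edges_from(self.graph.edges)
        nx.write_graphml(g, path)

    def to_json(self, path: str | Path, sample_ids: list[str] | None = None) -> None:
        payload = {
            "config": self.config.to_dict() if self.config else None,
            "n_samples": self.n_samples,
            "vertices": [
                {
                    "id": int(v),
                    "members": [
                        sample_ids[i] if sample_ids else int(i)
                        for i in self.graph.nodes[v]["members"]
                    ],
                    "bin": list(self.graph.nodes[v].get("bin", ())),
                }
                for v in self.graph.nodes
            ],
            "edges": [[int(u), int(v)] for u, v in self.graph.edges],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def pcoa_filter(dm: DistanceMatrix, n_components: int = 2) -> np.ndarray:
    """Classical MDS (PCoA) embedding of a distance matrix.

    Double-centers -d^2/2, eigendecomposes, and returns the top
    ``n_components`` eigenvectors scaled by the square roots of their
    (positive) eigenvalues, ordered by descending eigenvalue. Negative
    eigenvalues (possible for non-Euclidean metrics) are discarded; if
    fewer positive eigenvalues than requested exist, the available
    components are returned with a warning. Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    n = dm.n
    if n < 3:
        raise ValueError(f"PCoA needs at least 3 samples, got {n}")
    d2 = dm.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = 0.5 * (b + b.T)
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * abs(vals[0])) if vals.size else 0.0
    n_pos = int(np.sum(vals > tol))
    if n_pos < n_components:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} components",
            stacklevel=2,
        )
    k = min(n_components, n_pos)
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for c in range(k):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return coords


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Ordinal ranks 1..n with ties broken by input order."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite filter values")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def interval_starts(lo: float, hi: float, n_intervals: int, overlap_pct: float
                    ) -> tuple[np.ndarray, float]:
    """Equal-length closed cover intervals spanning [lo, hi].

    The first interval starts at ``lo``, the last ends at ``hi``, and
    consecutive starts are spaced L * (1 - overlap_pct/100); solving for
    the common length gives L = span / ((n-1)(1 - g) + 1). Consecutive
    intervals overlap by exactly overlap_pct percent of L, and their
    union is the whole span.
    """
    span = hi - lo
    if n_intervals == 1 or span == 0:
        return np.array([lo]), span
    g = overlap_pct / 100.0
    length = span / ((n_intervals - 1) * (1.0 - g) + 1.0)
    starts = lo + np.arange(n_intervals) * length * (1.0 - g)
    return starts, length


def make_cover(filters: np.ndarray, config: MapperConfig) -> list[CoverBin]:
    """Overlapping 2D cover of rank-filter space.

    Each dimension gets ``n_intervals`` closed intervals (see
    :func:`interval_starts`); 2D bins are their Cartesian product. A
    sample joins every bin whose intervals both contain its rank pair;
    empty bins are dropped. The union of bins covers all samples.
    """
    filters = np.asarray(filters, dtype=float)
    if filters.ndim != 2 or filters.shape[1] != 2:
        raise ValueError("filters must be an (n, 2) array")
    bins: list[CoverBin] = []
    per_dim = []
    for dim in range(2):
        lo, hi = filters[:, dim].min(), filters[:, dim].max()
        starts, length = interval_starts(lo, hi, config.n_intervals[dim], config.overlap_pct)
        intervals = [(s, s + length) for s in starts]
        # guard the span endpoints against floating-point round-off
        intervals[0] = (lo, intervals[0][1])
        intervals[-1] = (intervals[-1][0], hi)
        per_dim.append(intervals)
    for a, (lo1, hi1) in enumerate(per_dim[0]):
        in1 = (filters[:, 0] >= lo1) & (filters[:, 0] <= hi1)
        for b, (lo2, hi2) in enumerate(per_dim[1]):
            in2 = (filters[:, 1] >= lo2) & (filters[:, 1] <= hi2)
            members = np.flatnonzero(in1 & in2)
            if members.size:
                bins.append(
                    CoverBin(
                        bin_id=(a, b),
                        interval1=(lo1, hi1),
                        interval2=(lo2, hi2),
                        members=tuple(int(i) for i in members),
                    )
                )
    return bins


def local_cluster(
    bin_members: tuple[int, ...] | list[int],
    dm: DistanceMatrix,
    n_hist_bins: int = 10,
) -> list[tuple[int, ...]]:
    """Single-linkage clustering of one bin with the first-empty-bin cutoff.

    Merge heights of the single-linkage dendrogram, together with the
    bin diameter (max within-bin pairwise distance), are histogrammed in
    ``n_hist_bins`` equal-width bins over their own range; the cutoff is
    the lower edge of the first empty histogram bin (a gap separating
    the within-cluster length scale from the between-cluster one) and
    clusters are the single-linkage components below it. With no empty
    bin -- no separation of length scales -- the whole bin is one
    cluster; so are bins of fewer than three members.
    """
    members = np.asarray(sorted(bin_members), dtype=int)
    m = members.size
    if m == 0:
        raise ValueError("empty bin")
    if m <= 2:
        return [tuple(members)]
    sub = dm.d[np.ix_(members, members)]
    dmax = sub.max()
    if dmax == 0:
        return [tuple(members)]
    condensed = squareform(sub, checks=False)
    z = linkage(condensed, method="single")
    heights = np.append(z[:, 2], dmax)
    lo, hi = heights.min(), heights.max()
    if hi == lo:
        return [tuple(members)]
    counts, edges = np.histogram(heights, bins=n_hist_bins, range=(lo, hi))
    empty = np.flatnonzero(counts == 0)
    if empty.size == 0:
        return [tuple(members)]
    cutoff = edges[empty[0]]
    labels = fcluster(z, t=cutoff, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        clusters.append(tuple(int(i) for i in members[labels == lab]))
    return clusters


def build_nerve(clusters_per_bin: list[tuple[tuple[int, int], list[tuple[int, ...]]]],
                n_samples: int,
                config: MapperConfig | None = None) -> MapperGraph:
    """Nerve graph: one vertex per local cluster, edges for shared samples."""
    g = nx.Graph()
    vid = 0
    sample_to_vertices: dict[int, list[int]] = {}
    for bin_id, clusters in clusters_per_bin:
        for cluster in clusters:
            members = tuple(sorted(int(i) for i in cluster))
            g.add_node(vid, members=members, bin=bin_id)
            for i in members:
                sample_to_vertices.setdefault(i, []).append(vid)
            vid += 1
    for verts in sample_to_vertices.values():
        for u, v in combinations(verts, 2):
            g.add_edge(u, v)
    return MapperGraph(graph=g, n_samples=n_samples, config=config)


def run_mapper(dm: DistanceMatrix, config: MapperConfig) -> MapperGraph:
    """Full Mapper construction: PCoA ranks -> cover -> local clustering -> nerve.

    Deterministic given the distance matrix and configuration.
    """
    coords = pcoa_filter(dm, n_components=2)
    if coords.shape[1] < 2:
        # degenerate geometry: duplicate the single available filter
        coords = np.column_stack([coords[:, 0], coords[:, 0]])
    filters = np.column_stack(
        [rank_transform(coords[:, 0]), rank_transform(coords[:, 1])]
    )
    bins = make_cover(filters, config)
    clusters_per_bin = [
        (b.bin_id, local_cluster(b.members, dm, config.n_hist_bins)) for b in bins
    ]
    return MapperGraph(
        graph=build_nerve(clusters_per_bin, dm.n, config).graph,
        n_samples=dm.n,
        config=config,
    )


@dataclass(frozen=True)
class HyperparameterReport:
    largest_vertex_size: int
    largest_vertex_fraction: float
    n_singleton_components: int
    passed: bool


def check_hyperparameters(g: MapperGraph, n_samples: int) -> HyperparameterReport:
    """Heuristic hyperparameter check.

    Passes iff the largest vertex holds at most ceil(10% of samples);
    the count of connected components containing a single sample is
    reported for the user to minimize.
    """
    largest = g.largest_vertex_size()
    limit = int(np.ceil(0.10 * n_samples))
    singles = 0
    for comp in nx.connected_components(g.graph):
        members = set()
        for v in comp:
            members.update(g.graph.nodes[v]["members"])
        if len(members) == 1:
            singles += 1
    return HyperparameterReport(
        largest_vertex_size=largest,
        largest_vertex_fraction=largest / n_samples,
        n_singleton_components=singles,
        passed=largest <= limit,
    )
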