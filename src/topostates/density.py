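"""Vertex density estimation and metastable state assignment.

Per-sample kNN distances give a per-vertex inverse density
D_inv(V) = (sum over members of kNN(i, k)) / n^2 and density
D(V) = 1 / D_inv. Local maxima of D seed states; every other vertex is
assigned to the state whose maxima it reaches by a uniquely shortest
directed (density-ascending) path, or left unassigned on ties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from topostates.data import DistanceMatrix
from topostates.mapper import MapperGraph

logger = logging.getLogger(__name__)

#: Label for vertices equidistant to several states or unreachable from
#: any maximum (unstable / transition regions).
UNASSIGNED = -1


def default_k(n_samples: int) -> int:
    """Default kNN neighborhood: 10% of samples, rounded, at least 1."""
    return max(1, int(round(0.10 * n_samples)))


def knn_distance(dm: DistanceMatrix, i: int, k: int) -> float:
    """Mean distance from sample i to its k nearest other samples.

    Ties at the k-th neighbor are broken by lower sample index.
    """
    n = dm.n
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    d = np.delete(dm.d[i], i)
    order = np.argsort(d, kind="stable")
    return float(d[order[:k]].mean())


def knn_distances(dm: DistanceMatrix, k: int) -> np.ndarray:
    """kNN distance of every sample (vectorized over rows)."""
    n = dm.n
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    out = np.empty(n)
    for i in range(n):
        d = np.delete(dm.d[i], i)
        order = np.argsort(d, kind="stable")
        out[i] = d[order[:k]].mean()
    return out


@dataclass(frozen=True)
class VertexDensity:
    """Density of one vertex: member count n, inverse density, density."""

    n: int
    d_inv: float
    density: float


def vertex_density(members: tuple[int, ...], dm: DistanceMatrix, k: int,
                   knn: np.ndarray | None = None) -> VertexDensity:
    """Density estimate of a single vertex.

    D_inv = sum of member kNN distances / n^2; the n^2 denominator
    compensates for differing vertex sizes. All-duplicate members give
    D_inv = 0 and density +inf (flagged in the log).
    """
    if not members:
        raise ValueError("empty vertex")
    if knn is None:
        knn = knn_distances(dm, k)
    n = len(members)
    d_inv = float(knn[list(members)].sum()) / n**2
    if d_inv == 0.0:
        logger.warning("vertex with zero inverse density (duplicate samples)")
        return VertexDensity(n=n, d_inv=0.0, density=math.inf)
    return VertexDensity(n=n, d_inv=d_inv, density=1.0 / d_inv)


def compute_vertex_densities(g: MapperGraph, dm: DistanceMatrix,
                             k: int | None = None) -> dict[int, VertexDensity]:
    """Density of every Mapper vertex (kNN distances computed once)."""
    if k is None:
        k = default_k(dm.n)
    knn = knn_distances(dm, k)
    return {v: vertex_density(g.members(v), dm, k, knn=knn) for v in g.vertices()}


def find_local_maxima(g: MapperGraph, dens: dict[int, VertexDensity]) -> set[int]:
    """Vertices that are local maxima of density.

    A vertex whose density exceeds all neighbors is a maximum; connected
    vertices tied at a common density are each maxima provided no vertex
    of the tied plateau has a strictly denser neighbor. Isolated
    vertices are maxima.
    """
    graph = g.graph
    d = {v: dens[v].density for v in graph.nodes}
    weak = {v for v in graph.nodes if all(d[v] >= d[u] for u in graph.neighbors(v))}
    # plateaus: components of the subgraph of equal-density edges
    eq = nx.Graph()
    eq.add_nodes_from(graph.nodes)
    eq.add_edges_from((u, v) for u, v in graph.edges if d[u] == d[v])
    maxima: set[int] = set()
    for plateau in nx.connected_components(eq):
        if plateau <= weak:
            maxima.update(plateau)
    return maxima


def orient_graph(g: MapperGraph, dens: dict[int, VertexDensity]) -> nx.DiGraph:
    """Directed version of the graph with arcs toward higher density.

    Equal-density edges become arcs in both directions so that tied
    plateaus stay mutually reachable.
    """
    dg = nx.DiGraph()
    dg.add_nodes_from(g.graph.nodes)
    n_ties = 0
    for u, v in g.graph.edges:
        du, dv = dens[u].density, dens[v].density
        if du < dv:
            dg.add_edge(u, v)
        elif dv < du:
            dg.add_edge(v, u)
        else:
            dg.add_edge(u, v)
            dg.add_edge(v, u)
            n_ties += 1
    if n_ties:
        logger.info("%d equal-density edges made bidirectional", n_ties)
    return dg


@dataclass
class StatePartition:
    """Partition of Mapper vertices into metastable states.

    ``state_of`` maps every vertex to a consecutive integer state label
    or :data:`UNASSIGNED`; ``maxima`` is the set of local-maximum
    vertices; ``distances`` holds, per state, the directed hop distance
    from each vertex to that state's maxima set.
    """

    maxima: set[int]
    state_of: dict[int, int]
    n_states: int
    distances: dict[int, dict[int, int]] = field(default_factory=dict)

    def states(self) -> list[int]:
        return list(range(self.n_states))

    def vertices_of(self, state: int) -> list[int]:
        return sorted(v for v, s in self.state_of.items() if s == state)

    def n_unassigned(self) -> int:
        return sum(1 for s in self.state_of.values() if s == UNASSIGNED)


def assign_states(dg: nx.DiGraph, maxima: set[int],
                  undirected: nx.Graph | None = None) -> StatePartition:
    """Partition vertices into basins of attraction of density maxima.

    Maxima connected through maxima-only undirected paths share one
    state (labels are consecutive integers ordered by smallest member
    vertex). Each non-maximum vertex is assigned to the state whose
    maxima set it reaches by a strictly shortest directed hop distance;
    vertices equidistant to several states, or unreachable from every
    maximum, are :data:`UNASSIGNED`.
    """
    if not maxima:
        raise ValueError("no maxima given")
    und = undirected if undirected is not None else dg.to_undirected()
    groups = [sorted(c) for c in nx.connected_components(und.subgraph(maxima))]
    groups.sort(key=lambda c: c[0])
    n_states = len(groups)

    # distance from v to a state's maxima = BFS on the reversed digraph
    rev = dg.reverse(copy=False)
    distances: dict[int, dict[int, int]] = {}
    for label, group in enumerate(groups):
        dist: dict[int, int] = {}
        frontier = list(group)
        for v in frontier:
            dist[v] = 0
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for v in frontier:
                for u in rev.neighbors(v):
                    if u not in dist:
                        dist[u] = depth
                        nxt.append(u)
            frontier = nxt
        distances[label] = dist

    state_of: dict[int, int] = {}
    for label, group in enumerate(groups):
        for v in group:
            state_of[v] = label
    n_unreachable = 0
    for v in dg.nodes:
        if v in state_of:
            continue
        dists = [(distances[x].get(v), x) for x in range(n_states)]
        reachable = [(d, x) for d, x in dists if d is not None]
        if not reachable:
            state_of[v] = UNASSIGNED
            n_unreachable += 1
            continue
        best = min(d for d, _ in reachable)
        winners = [x for d, x in reachable if d == best]
        state_of[v] = winners[0] if len(winners) == 1 else UNASSIGNED
    if n_unreachable:
        logger.info("%d vertices unreachable from any maximum", n_unreachable)
    return StatePartition(
        maxima=set(maxima),
        state_of=state_of,
        n_states=n_states,
        distances=distances,
    )


def partition_graph(g: MapperGraph, dens: dict[int, VertexDensity]) -> StatePartition:
    """Maxima -> orientation -> basin assignment in one call."""
    maxima = find_local_maxima(g, dens)
    dg = orient_graph(g, dens)
    return assign_states(dg, maxima, undirected=g.graph)


def sample_states(g: MapperGraph, part: StatePartition) -> dict[int, frozenset[int]]:
    """Per-sample state label sets (union over containing vertices).

    A sample inherits the label of every vertex that contains it;
    :data:`UNASSIGNED` counts as one distinct label. Never empty.
    """
    out: dict[int, set[int]] = {}
    for v in g.vertices():
        lab = part.state_of[v]
        for i in g.members(v):
            out.setdefault(i, set()).add(lab)
    return {i: frozenset(s) for i, s in out.items()}


def majority_sample_state(g: MapperGraph, part: StatePartition) -> dict[int, int]:
    """Single per-sample label: the state of most containing vertices.

    Assigned states outrank UNASSIGNED; ties go to the smallest label.
    """
    counts: dict[int, dict[int, int]] = {}
    for v in g.vertices():
        lab = part.state_of[v]
        for i in g.members(v):
            counts.setdefault(i, {})[lab] = counts.setdefault(i, {}).get(lab, 0) + 1
    out = {}
    for i, c in counts.items():
        assigned = {lab: n for lab, n in c.items() if lab != UNASSIGNED}
        pool = assigned if assigned else c
        out[i] = min(lab for lab, n in pool.items() if n == max(pool.values()))
    return out


def partition_to_tsv(path: str | Path, g: MapperGraph, dens: dict[int, VertexDensity],
                     part: StatePartition) -> None:
    """Vertex-level TSV: vertex_id, n_members, density, is_maximum, state."""
    lines = ["vertex_id\tn_members\tdensity\tis_maximum\tstate"]
    for v in sorted(g.vertices()):
        state = part.state_of[v]
        lines.append(
            f"{v}\t{dens[v].n}\t{dens[v].density:.10g}\t"
            f"{int(v in part.maxima)}\t{state if state != UNASSIGNED else 'unassigned'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def sample_states_to_tsv(path: str | Path, labels: dict[int, frozenset[int]],
                         sample_ids: list[str]) -> None:
    """Sample-level TSV: sample_id, semicolon-joined state labels."""
    lines = ["sample_id\tstates"]
    for i, sid in enumerate(sample_ids):
        labs = sorted(labels.get(i, frozenset()))
        txt = ";".join("unassigned" if lab == UNASSIGNED else str(lab) for lab in labs)
        lines.append(f"{sid}\t{txt}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sample_states_tsv(path: str | Path) -> dict[str, frozenset[int]]:
    """Inverse of :func:`sample_states_to_tsv` (validating reader)."""
    out: dict[str, frozenset[int]] = {}
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "sample_id\tstates":
        raise ValueError(f"{path}: not a sample-states TSV")
    for line in lines[1:]:
        sid, txt = line.split("\t")
        labs = frozenset(
            UNASSIGNED if tok == "unassigned" else int(tok)
            for tok in txt.split(";") if tok
        )
        if not labs:
            raise ValueError(f"{path}: sample {sid} has no state labels")
        out[sid] = labs
    return out
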