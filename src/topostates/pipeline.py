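"""High-level pipeline: distances -> Mapper -> density -> states."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from topostates.data import AbundanceTable, DistanceMatrix, pairwise_distances, to_relative_abundance
from topostates.density import (
    StatePartition,
    VertexDensity,
    compute_vertex_densities,
    default_k,
    majority_sample_state,
    partition_graph,
    sample_states,
)
from topostates.mapper import (
    HyperparameterReport,
    MapperConfig,
    MapperGraph,
    check_hyperparameters,
    run_mapper,
)


@dataclass
class PipelineResult:
    table: AbundanceTable
    distances: DistanceMatrix
    graph: MapperGraph
    densities: dict[int, VertexDensity]
    partition: StatePartition
    sample_labels: dict[int, frozenset[int]]
    report: HyperparameterReport
    k: int

    def majority_labels(self) -> dict[int, int]:
        return majority_sample_state(self.graph, self.partition)

    def majority_label_array(self) -> np.ndarray:
        maj = self.majority_labels()
        return np.array([maj[i] for i in range(len(self.table.samples))])


def run_pipeline(
    table: AbundanceTable,
    config: MapperConfig | None = None,
    k: int | None = None,
    pseudocount: float | None = None,
) -> PipelineResult:
    """Run the full analysis on an abundance table.

    The table is normalized if needed, pairwise distances are computed
    with the configured metric, the Mapper graph is built, vertex
    densities estimated (k defaults to 10% of samples, rounded), and
    vertices partitioned into metastable states.
    """
    config = config or MapperConfig()
    if not table.is_normalized():
        table = to_relative_abundance(table)
    dm = pairwise_distances(table, metric=config.metric, pseudocount=pseudocount)
    graph = run_mapper(dm, config)
    if k is None:
        k = default_k(dm.n)
    densities = compute_vertex_densities(graph, dm, k)
    partition = partition_graph(graph, densities)
    labels = sample_states(graph, partition)
    report = check_hyperparameters(graph, dm.n)
    return PipelineResult(
        table=table,
        distances=dm,
        graph=graph,
        densities=densities,
        partition=partition,
        sample_labels=labels,
        report=report,
        k=k,
    )
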