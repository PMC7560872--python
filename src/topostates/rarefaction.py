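"""Rarefaction robustness of the Mapper phase-space structure.

Mapper is re-run on random subsamples of the data (default 90%, 50% and
10%, ten replicates each) with unchanged hyperparameters; distances are
subset, never recomputed. Each replicate graph is summarized by vertex
feature homogeneity and by within- versus between-group edge densities,
where a vertex's group is its dominant metadata feature class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from topostates.data import AbundanceTable, DistanceMatrix, pairwise_distances
from topostates.mapper import MapperConfig, MapperGraph, run_mapper


@dataclass(frozen=True)
class RarefactionPlan:
    fractions: tuple[float, ...] = (0.9, 0.5, 0.1)
    replicates: int = 10
    config: MapperConfig = field(default_factory=MapperConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def rarefy(samples: list[str], fraction: float, seed: int) -> list[str]:
    """Uniform subsample without replacement of round(fraction * n) IDs.

    The retained IDs keep their original order; same seed, same subset.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(samples)
    m = _round_half_away(fraction * n)
    if m < 3:
        raise ValueError(f"rarefied size {m} < 3 (n={n}, fraction={fraction})")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=m, replace=False))
    return [samples[i] for i in keep]


def _feature_groups(meta: pd.DataFrame, feature: str, n_bins: int = 4) -> pd.Series:
    """Categorical grouping of a metadata feature; numeric features are
    binned into quartiles."""
    if feature not in meta.columns:
        raise KeyError(f"feature {feature!r} not in metadata")
    col = meta[feature]
    if col.isna().any():
        raise ValueError(f"feature {feature!r} missing for some samples")
    if pd.api.types.is_numeric_dtype(col) and col.nunique() > n_bins:
        binned = pd.qcut(col, q=n_bins, duplicates="drop")
        return binned.astype(str)
    return col.astype(str)


def _vertex_group_stats(g: MapperGraph, sample_group: list[str]
                        ) -> tuple[list[str], np.ndarray]:
    """Dominant feature class and its share for every vertex."""
    groups, fracs = [], []
    for v in sorted(g.vertices()):
        classes = [sample_group[i] for i in g.members(v)]
        uniq, counts = np.unique(classes, return_counts=True)
        top = counts.max()
        # deterministic tie-break: lexicographically smallest class
        groups.append(sorted(u for u, c in zip(uniq, counts) if c == top)[0])
        fracs.append(top / len(classes))
    return groups, np.asarray(fracs)


def edge_densities(g: MapperGraph, vertex_group: list[str]
                   ) -> tuple[float, float]:
    """Pooled within-group and between-group edge densities.

    Density = observed edges / possible vertex pairs, pooled over all
    within-group pairs and over all between-group pairs respectively.
    NaN where no pairs exist (e.g. a single group).
    """
    verts = sorted(g.vertices())
    group_of = dict(zip(verts, vertex_group))
    sizes = pd.Series(vertex_group).value_counts()
    within_possible = float(sum(s * (s - 1) / 2 for s in sizes))
    total_pairs = len(verts) * (len(verts) - 1) / 2
    between_possible = float(total_pairs - within_possible)
    within_obs = between_obs = 0
    for u, v in g.graph.edges:
        if group_of[u] == group_of[v]:
            within_obs += 1
        else:
            between_obs += 1
    within = within_obs / within_possible if within_possible else np.nan
    between = between_obs / between_possible if between_possible else np.nan
    return within, between


def robustness_run(
    table: AbundanceTable,
    plan: RarefactionPlan,
    feature: str,
    distances: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Rarefaction summary over all (fraction, replicate) combinations.

    Returns one row per run: fraction, replicate, n_samples, n_vertices,
    n_edges, mean_dominant_fraction, within_density, between_density.
    Per-replicate seeds derive deterministically from the plan's master
    seed via a spawn key (fraction index, replicate index).
    """
    if table.meta is None:
        raise ValueError("table has no metadata")
    if distances is None:
        distances = pairwise_distances(table, metric=plan.config.metric)
    sample_group = list(_feature_groups(table.meta, feature))
    rows = []
    for fi, fraction in enumerate(plan.fractions):
        for rep in range(plan.replicates):
            rng_seed = int(
                np.random.SeedSequence(plan.seed, spawn_key=(fi, rep))
                .generate_state(1)[0]
            )
            kept = rarefy(table.samples, fraction, rng_seed)
            sub_dm = distances.subset(kept)
            g = run_mapper(sub_dm, plan.config)
            idx = {s: i for i, s in enumerate(table.samples)}
            kept_groups = [sample_group[idx[s]] for s in kept]
            vgroups, fracs = _vertex_group_stats(g, kept_groups)
            within, between = edge_densities(g, vgroups)
            rows.append(
                {
                    "fraction": fraction,
                    "replicate": rep,
                    "n_samples": len(kept),
                    "n_vertices": g.n_vertices,
                    "n_edges": g.n_edges,
                    "mean_dominant_fraction": float(fracs.mean()),
                    "within_density": within,
                    "between_density": between,
                }
            )
    return pd.DataFrame(rows)
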