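"""Synthetic community generators with known ground truth.

Two generators: an antagonistic two-species toy whose phase-space
density is bimodal (X-dominant vs Y-dominant modes separated by a
sparsely-sampled ridge), and a Markov-switching community in which each
subject hops between Dirichlet-distributed compositional states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from topostates.data import AbundanceTable, js_distance


@dataclass(frozen=True)
class AntagonisticToyConfig:
    """Two mutually antagonistic focal taxa X and Y plus bystanders.

    Each sample is an independent realization of a discrete-time
    competitive process on the X/Y log-ratio with multiplicative noise:
    positive ``antagonism`` pushes the ratio toward saturation at one of
    two modes, zero antagonism leaves a diffusive null.
    """

    n_timepoints: int = 200
    bystander_baseline: tuple[float, ...] = (0.05, 0.05, 0.05, 0.05)
    antagonism: float = 1.0
    noise: float = 0.3
    n_burnin: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 1 or self.n_burnin < 1:
            raise ValueError("n_timepoints and n_burnin must be >= 1")
        if any(b < 0 for b in self.bystander_baseline):
            raise ValueError("bystander baselines must be non-negative")
        if sum(self.bystander_baseline) >= 1:
            raise ValueError("bystander baselines must sum to < 1")
        if self.antagonism < 0 or self.noise < 0:
            raise ValueError("antagonism and noise must be non-negative")


def simulate_antagonistic(config: AntagonisticToyConfig
                          ) -> tuple[AbundanceTable, pd.Series]:
    """Sample the antagonistic toy ecosystem.

    Returns a normalized abundance table (taxa X, Y, B1..Bk) and the
    ground-truth dominant-taxon label ('X' or 'Y') per sample. With
    strong antagonism samples concentrate near the two modes where one
    focal taxon dominates; intermediate compositions are rare.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_timepoints
    z = rng.normal(0.0, 1.0, size=n)
    for _ in range(config.n_burnin):
        z = z + config.antagonism * np.tanh(z) + rng.normal(0.0, config.noise, size=n)
    focal_mass = 1.0 - sum(config.bystander_baseline)
    share_x = 1.0 / (1.0 + np.exp(-z))
    baseline = np.asarray(config.bystander_baseline)
    bystanders = baseline * np.exp(
        rng.normal(0.0, config.noise, size=(n, baseline.size))
    )
    values = np.column_stack(
        [focal_mass * share_x, focal_mass * (1.0 - share_x), bystanders]
    )
    values /= values.sum(axis=1, keepdims=True)
    taxa = ["X", "Y"] + [f"B{i + 1}" for i in range(baseline.size)]
    samples = [f"t{i:04d}" for i in range(n)]
    meta = pd.DataFrame(
        {"subject": "toy", "time": np.arange(n, dtype=float)}, index=samples
    )
    table = AbundanceTable(samples=samples, taxa=taxa, values=values, meta=meta)
    labels = pd.Series(np.where(z > 0, "X", "Y"), index=samples, name="mode")
    return table, labels


def block_state_means(n_states: int, n_taxa: int, dominance: float = 0.8
                      ) -> np.ndarray:
    """Well-separated state mean compositions.

    State s places ``dominance`` of its mass uniformly on its own block
    of taxa and the rest uniformly elsewhere; with high dominance the
    pairwise sqrt-JSD separation approaches 1.
    """
    if n_taxa < n_states:
        raise ValueError("need at least one taxon per state")
    means = np.full((n_states, n_taxa), np.nan)
    block = n_taxa // n_states
    for s in range(n_states):
        lo, hi = s * block, (s + 1) * block if s < n_states - 1 else n_taxa
        outside = n_taxa - (hi - lo)
        row = np.full(n_taxa, (1.0 - dominance) / outside if outside else 0.0)
        row[lo:hi] = (dominance if outside else 1.0) / (hi - lo)
        means[s] = row
    return means / means.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class MarkovCommunityConfig:
    """Markov-switching Dirichlet community.

    Each subject runs an S-state Markov chain; at every time point the
    composition is a Dirichlet draw around the current state's mean with
    the given concentration. State means must be separated by at least
    ``min_separation`` in sqrt-JSD.
    """

    state_means: np.ndarray = field(
        default_factory=lambda: block_state_means(3, 15)
    )
    transition: np.ndarray = field(
        default_factory=lambda: np.full((3, 3), 0.05) + np.eye(3) * 0.85
    )
    concentration: float = 50.0
    n_subjects: int = 3
    n_timepoints: int = 100
    min_separation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.state_means, dtype=float)
        trans = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "state_means", means)
        object.__setattr__(self, "transition", trans)
        s = means.shape[0]
        if trans.shape != (s, s):
            raise ValueError("transition matrix shape must match number of states")
        if not np.allclose(trans.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if np.any(trans < 0):
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(means.sum(axis=1), 1.0):
            raise ValueError("state means must be compositions")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.n_subjects < 1 or self.n_timepoints < 1:
            raise ValueError("n_subjects and n_timepoints must be >= 1")
        for a in range(s):
            for b in range(a + 1, s):
                sep = js_distance(means[a], means[b])
                if sep < self.min_separation:
                    raise ValueError(
                        f"states {a} and {b} separated by {sep:.3f} "
                        f"< min_separation {self.min_separation}"
                    )

    @property
    def n_states(self) -> int:
        return self.state_means.shape[0]


def simulate_markov_community(config: MarkovCommunityConfig
                              ) -> tuple[AbundanceTable, pd.Series]:
    """Sample the Markov-switching community.

    Returns a normalized table with per-sample subject and integer time
    metadata, and the ground-truth state label per sample. Randomness
    splits from the master seed into one stream per subject.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_subjects)
    s = config.n_states
    samples, values, subjects, times, truth = [], [], [], [], []
    for si in range(config.n_subjects):
        rng = np.random.default_rng(streams[si])
        state = int(rng.integers(s))
        for t in range(config.n_timepoints):
            alpha = config.concentration * config.state_means[state]
            comp = rng.dirichlet(alpha)
            sid = f"S{si}_t{t:04d}"
            samples.append(sid)
            values.append(comp)
            subjects.append(f"S{si}")
            times.append(float(t))
            truth.append(state)
            state = int(rng.choice(s, p=config.transition[state]))
    taxa = [f"taxon{j}" for j in range(config.state_means.shape[1])]
    meta = pd.DataFrame({"subject": subjects, "time": times}, index=samples)
    table = AbundanceTable(
        samples=samples, taxa=taxa, values=np.asarray(values), meta=meta
    )
    return table, pd.Series(truth, index=samples, name="state")
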