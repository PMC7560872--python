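"""Temporal correlation functions of state membership.

For a subject in state x at time t, the correlation corr_x(tau) is the
mean association with x over all sampled intervals of length tau that
start in x. A sample associated with p distinct states (the unassigned
label counting as one) contributes weight f' = 1/p to each, so raw
values lie in {0} union {1, 1/2, 1/3, ...}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from topostates.density import UNASSIGNED


@dataclass
class StateMembershipSeries:
    """Time-ordered state memberships of one subject.

    ``labels[t]`` is the set of state labels at time ``times[t]``;
    ``p[t] = len(labels[t])`` and each present label has weight 1/p.
    """

    subject: str
    times: np.ndarray
    labels: list[frozenset[int]]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.labels):
            raise ValueError("times and labels length mismatch")
        if len(self.times) < 2:
            raise ValueError("need at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if any(len(s) == 0 for s in self.labels):
            raise ValueError("empty label set")

    @property
    def p(self) -> np.ndarray:
        return np.array([len(s) for s in self.labels])

    def f_prime(self, x: int) -> np.ndarray:
        """Weighted association f'_x(t) = [x in labels(t)] / p(t)."""
        return np.array(
            [1.0 / len(s) if x in s else 0.0 for s in self.labels]
        )

    def visited_states(self) -> set[int]:
        out: set[int] = set()
        for s in self.labels:
            out |= s
        return out


def membership_series(
    sample_labels: dict[str, frozenset[int]],
    meta: pd.DataFrame,
    subject: str,
    window: tuple[float, float] | None = None,
) -> StateMembershipSeries:
    """Build the membership series of one subject from per-sample labels.

    ``meta`` is indexed by sample ID with ``subject`` and ``time``
    columns; samples outside ``window`` (closed interval) are dropped.
    Samples of one subject sharing a time point are merged by label-set
    union.
    """
    rows = meta[meta["subject"].astype(str) == str(subject)]
    if window is not None:
        lo, hi = window
        rows = rows[(rows["time"] >= lo) & (rows["time"] <= hi)]
    per_time: dict[float, set[int]] = {}
    for sid, row in rows.iterrows():
        if str(sid) not in sample_labels:
            continue
        per_time.setdefault(float(row["time"]), set()).update(sample_labels[str(sid)])
    if len(per_time) < 2:
        raise ValueError(
            f"subject {subject!r}: fewer than 2 labeled time points in window"
        )
    times = np.array(sorted(per_time))
    labels = [frozenset(per_time[t]) for t in times]
    return StateMembershipSeries(subject=str(subject), times=times, labels=labels)


@dataclass
class CorrelationSeries:
    """corr_x(tau) for one (subject, state): raw pairs and per-tau stats.

    ``raw`` holds every (tau, f'_x) pair; ``taus``/``means``/``sems``/
    ``counts`` aggregate by exact empirical tau (no gridding). SEM is
    NaN where only one pair exists.
    """

    subject: str
    state: int
    raw: np.ndarray  # shape (n_pairs, 2): tau, f'
    taus: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "state": "unassigned" if self.state == UNASSIGNED else self.state,
                "tau": self.taus,
                "n_pairs": self.counts,
                "mean": self.means,
                "sem": self.sems,
            }
        )


def temporal_correlation(series: StateMembershipSeries, x: int) -> CorrelationSeries:
    """Correlation function of state ``x`` over a membership series.

    Every ordered pair of observed times (t, t + tau), tau >= 0, with
    x in labels(t) contributes the raw value f'_x(t + tau); values are
    averaged per distinct empirical tau. Raises if x is never visited.
    """
    if x not in series.visited_states():
        raise ValueError(f"state {x} never visited by subject {series.subject!r}")
    fp = series.f_prime(x)
    starts = [i for i, s in enumerate(series.labels) if x in s]
    pairs = []
    n = len(series.times)
    for i in starts:
        for j in range(i, n):
            pairs.append((series.times[j] - series.times[i], fp[j]))
    raw = np.array(pairs)
    taus = np.unique(raw[:, 0])
    means = np.empty(taus.size)
    sems = np.empty(taus.size)
    counts = np.empty(taus.size, dtype=int)
    for idx, tau in enumerate(taus):
        vals = raw[raw[:, 0] == tau, 1]
        counts[idx] = vals.size
        means[idx] = vals.mean()
        sems[idx] = (
            vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        )
    return CorrelationSeries(
        subject=series.subject, state=x, raw=raw,
        taus=taus, means=means, sems=sems, counts=counts,
    )


def smooth_correlation(c: CorrelationSeries, bandwidth: float) -> np.ndarray:
    """Moving-average smoothing of the per-tau means.

    At each observed tau the smoothed value is the unweighted mean of
    means at taus within bandwidth/2. Raw pairs are never modified.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if c.taus.size < 2:
        raise ValueError("need at least 2 distinct tau values")
    half = bandwidth / 2.0
    out = np.empty_like(c.means)
    for i, t in enumerate(c.taus):
        mask = np.abs(c.taus - t) <= half
        out[i] = c.means[mask].mean()
    return out


def monotonicity_index(c: CorrelationSeries) -> float:
    """Spearman rank correlation of mean corr_x(tau) against tau.

    Values near -1 indicate monotone decay (transient state occupancy);
    non-negative values indicate recurrence.
    """
    if c.taus.size < 3:
        raise ValueError("need at least 3 distinct tau values")
    rho = spearmanr(c.taus, c.means).statistic
    return float(rho)


def correlation_table(series_list: list[CorrelationSeries]) -> pd.DataFrame:
    """Long-format table (subject, state, tau, n_pairs, mean, sem)."""
    return pd.concat([c.to_frame() for c in series_list], ignore_index=True)
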