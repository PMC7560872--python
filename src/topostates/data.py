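"""Abundance tables, compositions, and the phase-space distance matrix.

Samples are points in compositional phase space; the metric between them
is the square root of the Jensen-Shannon divergence (base-2 logarithms,
so distances lie in [0, 1]). The Aitchison distance (Euclidean distance
between centered-log-ratio transforms) is available as an alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input table violates a contract."""


@dataclass
class AbundanceTable:
    """Sample x taxon abundance matrix with per-sample metadata.

    Parameters
    ----------
    samples : list of str
        Ordered, unique sample identifiers (rows).
    taxa : list of str
        Ordered taxon identifiers (columns).
    values : ndarray of shape (n_samples, n_taxa)
        Non-negative abundances (counts or relative abundances).
    meta : pandas.DataFrame, optional
        Indexed by sample ID; must cover every sample when present.
        Conventional columns: ``subject`` (str) and ``time`` (float, in
        the dataset's native units -- never converted).
    """

    samples: list[str]
    taxa: list[str]
    values: np.ndarray
    meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.taxa)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.taxa)} taxa"
            )
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite abundance values")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.samples[i]!r}, "
                f"taxon {self.taxa[j]!r}"
            )
        zero = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero.size:
            raise ValidationError(
                f"all-zero samples: {[self.samples[i] for i in zero]}"
            )
        if self.meta is not None:
            missing = set(self.samples) - set(map(str, self.meta.index))
            if missing:
                raise ValidationError(f"metadata missing samples: {sorted(missing)}")
            self.meta = self.meta.loc[self.samples]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def is_normalized(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.values.sum(axis=1), 1.0, atol=tol))

    def drop_empty_taxa(self) -> "AbundanceTable":
        """Drop taxa absent from every sample (no effect on JS distances)."""
        keep = np.flatnonzero(self.values.sum(axis=0) > 0)
        if keep.size == self.n_taxa:
            return self
        return AbundanceTable(
            samples=list(self.samples),
            taxa=[self.taxa[j] for j in keep],
            values=self.values[:, keep],
            meta=self.meta,
        )

    def subset(self, samples: Sequence[str]) -> "AbundanceTable":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in samples]
        return AbundanceTable(
            samples=list(samples),
            taxa=list(self.taxa),
            values=self.values[rows],
            meta=self.meta.loc[list(samples)] if self.meta is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.taxa)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between samples.

    Invariants: zero diagonal, symmetry, non-negativity; for the JS
    metric all entries are <= 1.
    """

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal not zero")
        if np.any(self.d < 0):
            raise ValidationError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = np.array([index[s] for s in ids])
        return DistanceMatrix(ids=list(ids), d=self.d[np.ix_(rows, rows)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(s) for s in df.index], d=df.to_numpy(dtype=float))


def read_abundance_table(
    path: str | Path,
    format: str = "tsv",
    orientation: str = "samples_as_rows",
    metadata: pd.DataFrame | None = None,
) -> AbundanceTable:
    """Read an abundance table from a delimited text file.

    Zero-sum samples are dropped with a logged warning; duplicate sample
    IDs or negative/unparseable cells raise :class:`ValidationError`.
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'csv')")
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "\t" if format == "tsv" else ","
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
        df = df.apply(pd.to_numeric)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValidationError(f"malformed abundance table {path}: {exc}") from exc
    if orientation == "taxa_as_rows":
        df = df.T
    samples = [str(s) for s in df.index]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"duplicate sample IDs in {path}: {dupes}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError(f"negative abundance values in {path}")
    sums = values.sum(axis=1)
    if np.any(sums == 0):
        dropped = [samples[i] for i in np.flatnonzero(sums == 0)]
        logger.warning("dropping %d zero-sum samples: %s", len(dropped), dropped)
        warnings.warn(f"dropping zero-sum samples: {dropped}", stacklevel=2)
        keep = sums > 0
        values = values[keep]
        samples = [s for s, k in zip(samples, keep) if k]
    return AbundanceTable(
        samples=samples,
        taxa=[str(t) for t in df.columns],
        values=values,
        meta=metadata,
    )


def read_metadata(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read sample metadata; requires ``sample_id``, ``subject``, ``time``."""
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "subject", "time"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    df = df.set_index("sample_id")
    df["subject"] = df["subject"].astype(str)
    df["time"] = df["time"].astype(float)
    return df


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Normalize each sample to a composition (rows sum to one).

    Idempotent; zero cells stay zero. Each sample is normalized
    independently.
    """
    sums = table.values.sum(axis=1)
    if np.any(sums <= 0):
        bad = table.samples[int(np.argmax(sums <= 0))]
        raise ValidationError(f"sample {bad!r} has non-positive total abundance")
    return AbundanceTable(
        samples=list(table.samples),
        taxa=list(table.taxa),
        values=table.values / sums[:, None],
        meta=table.meta,
    )


def _check_composition(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"{name} does not sum to 1 (sum={p.sum():.6g})")
    return p


def _entropy2(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in bits, with the 0*log(0) = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=axis)


def js_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Square root of the Jensen-Shannon divergence between compositions.

    Base-2 logarithms, so the result lies in [0, 1]; it is a proper
    metric (symmetric, zero iff p == q, triangle inequality).
    """
    p = _check_composition(p, "p")
    q = _check_composition(q, "q")
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {q.shape[0]}")
    m = 0.5 * (p + q)
    jsd = _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))
    return float(np.sqrt(max(jsd, 0.0)))


def _clr(x: np.ndarray) -> np.ndarray:
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def _multiplicative_pseudocount(values: np.ndarray, delta: float) -> np.ndarray:
    """Replace zeros by delta, shrinking nonzero entries multiplicatively
    so each row keeps its sum."""
    out = values.copy()
    for i in range(out.shape[0]):
        zeros = out[i] == 0
        nz = zeros.sum()
        if nz:
            total = out[i].sum()
            out[i, ~zeros] *= (total - nz * delta) / total
            out[i, zeros] = delta
    return out


def pairwise_distances(
    table: AbundanceTable,
    metric: str = "js",
    pseudocount: float | None = None,
) -> DistanceMatrix:
    """Full pairwise distance matrix over a normalized table.

    ``metric='js'`` gives sqrt-JSD (base 2); ``metric='aitchison'`` gives
    the Euclidean distance between centered-log-ratio transforms and
    requires strictly positive entries unless ``pseudocount`` is given
    (pass ``pseudocount=0`` to use 0.5x the smallest nonzero relative
    abundance).
    """
    if not table.is_normalized():
        raise ValidationError("table must be normalized (rows summing to 1)")
    table = table.drop_empty_taxa()
    x = table.values
    n = x.shape[0]
    if metric == "js":
        d = np.zeros((n, n))
        h = _entropy2(x)
        for i in range(n - 1):
            m = 0.5 * (x[i] + x[i + 1 :])
            jsd = _entropy2(m) - 0.5 * (h[i] + h[i + 1 :])
            d[i, i + 1 :] = np.sqrt(np.maximum(jsd, 0.0))
        d = d + d.T
    elif metric == "aitchison":
        if np.any(x == 0):
            if pseudocount is None:
                raise ValidationError(
                    "aitchison distance requires strictly positive entries; "
                    "pass a pseudocount to enable multiplicative replacement"
                )
            delta = pseudocount if pseudocount > 0 else 0.5 * x[x > 0].min()
            x = _multiplicative_pseudocount(x, delta)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(_clr(x), metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(ids=list(table.samples), d=d)
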