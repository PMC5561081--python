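"""Gene expression matrix (GEM) I/O and preprocessing.

A GEM is a transcripts x samples matrix of expression values with explicit
missing values. The preprocessing chain applied before network construction
is: log2 transform, a Kolmogorov-Smirnov screen for samples with abnormal
density distributions, and quantile normalization so every sample shares the
same value distribution.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GEM",
    "PreprocessReport",
    "Transform",
    "read_gem",
    "write_gem",
    "log2_transform",
    "ks_outlier_screen",
    "quantile_normalize",
]

MISSING = "NA"


class Transform(str, Enum):
    NONE = "none"
    LOG2 = "log2"


@dataclass
class GEM:
    """Expression matrix with explicit missing values (NaN)."""

    transcript_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_transcripts, n_samples), float64, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != len(self.transcript_ids) or m != len(self.sample_ids):
            raise ValueError("matrix dimensions do not match id list lengths")
        if len(set(self.transcript_ids)) != n:
            raise ValueError("duplicate transcript ids")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicate sample ids")

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.transcript_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GEM":
        return cls(
            transcript_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def row(self, transcript_id: str) -> np.ndarray:
        return self.values[self.transcript_ids.index(transcript_id)]


@dataclass
class PreprocessReport:
    """Per-sample KS outlier statistics and the preprocessing state."""

    statistics: list[tuple[str, float]]  # (sample_id, D_N); NaN when undefined
    flagged_samples: list[tuple[str, float]] = field(default_factory=list)
    transform_applied: Transform = Transform.NONE
    normalized: bool = False


def read_gem(path) -> GEM:
    """Read a tab-separated GEM: header row of sample ids, first column of
    transcript ids, ``NA`` for missing values."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError("no data rows") from None
        sample_ids = [c for c in header[1:]]
        width = len(header)
        transcript_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != width:
                raise ValueError(
                    f"ragged row at line {lineno}: expected {width} fields, "
                    f"got {len(rec)}"
                )
            transcript_ids.append(rec[0])
            rows.append(
                [math.nan if v == MISSING else float(v) for v in rec[1:]]
            )
    if not rows:
        raise ValueError("no data rows")
    return GEM(transcript_ids, sample_ids, np.array(rows, dtype=float))


def write_gem(gem: GEM, path, digits: int = 6) -> None:
    """Write a GEM as UTF-8 TSV, ``NA`` for missing, %g formatting."""
    fmt = f"%.{digits}g"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(["transcript"] + gem.sample_ids) + "\n")
        for tid, row in zip(gem.transcript_ids, gem.values):
            cells = [MISSING if math.isnan(v) else fmt % v for v in row]
            fh.write("\t".join([tid] + cells) + "\n")


def log2_transform(gem: GEM) -> GEM:
    """log2 of positive values; non-positive and missing become missing."""
    out = np.full_like(gem.values, np.nan)
    pos = gem.values > 0
    out[pos] = np.log2(gem.values[pos])
    return GEM(list(gem.transcript_ids), list(gem.sample_ids), out)


def ks_outlier_screen(gem: GEM, cutoff: float = 0.15) -> PreprocessReport:
    """Two-sample KS screen for samples with abnormal density distributions.

    Each sample's non-missing values are compared against the pooled values of
    all other samples (leave-one-out); the statistic is the ECDF
    sup-difference D_N. Samples with D_N > ``cutoff`` are flagged but not
    removed. Samples with fewer than 2 non-missing values are flagged with a
    missing statistic.
    """
    stats_out: list[tuple[str, float]] = []
    flagged: list[tuple[str, float]] = []
    X = gem.values
    for j, sid in enumerate(gem.sample_ids):
        x = X[:, j]
        x = x[~np.isnan(x)]
        if x.size < 2:
            stats_out.append((sid, math.nan))
            flagged.append((sid, math.nan))
            continue
        others = np.delete(X, j, axis=1).ravel()
        others = others[~np.isnan(others)]
        d = float(stats.ks_2samp(x, others, method="asymp").statistic)
        stats_out.append((sid, d))
        if d > cutoff:
            flagged.append((sid, d))
    return PreprocessReport(
        statistics=stats_out,
        flagged_samples=flagged,
        transform_applied=Transform.NONE,
        normalized=False,
    )


def quantile_normalize(gem: GEM) -> GEM:
    """Classic quantile normalization across samples.

    The reference distribution is the across-sample mean of order statistics.
    Complete samples are mapped exactly onto it; samples with missing values
    rank within their non-missing values and interpolate the reference at
    proportional positions. Tied input values receive the average of their
    mapped reference quantiles, so the result is order-independent.
    """
    X = gem.values
    n = X.shape[0]
    grid = (np.arange(n) + 0.5) / n
    # reference = mean over samples of each sample's quantile function on grid
    cols = []
    for j in range(X.shape[1]):
        v = np.sort(X[:, j][~np.isnan(X[:, j])])
        if v.size == 0:
            continue
        pos = (np.arange(v.size) + 0.5) / v.size
        cols.append(np.interp(grid, pos, v))
    if not cols:
        return GEM(list(gem.transcript_ids), list(gem.sample_ids), X.copy())
    ref = np.mean(cols, axis=0)

    out = np.full_like(X, np.nan)
    for j in range(X.shape[1]):
        col = X[:, j]
        mask = ~np.isnan(col)
        v = col[mask]
        m = v.size
        if m == 0:
            continue
        order = np.argsort(v, kind="stable")
        mapped = np.empty(m)
        mapped[order] = np.interp((np.arange(m) + 0.5) / m, grid, ref)
        # average mapped quantiles over exactly tied input values
        uniq, inv = np.unique(v, return_inverse=True)
        if uniq.size < m:
            sums = np.bincount(inv, weights=mapped)
            counts = np.bincount(inv)
            mapped = (sums / counts)[inv]
        out[mask, j] = mapped
    return GEM(list(gem.transcript_ids), list(gem.sample_ids), out)
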