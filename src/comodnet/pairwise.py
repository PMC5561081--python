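"""Per-pair mode discovery and correlation with digit-coded sample strings.

For every transcript pair the pipeline assembles complete observations,
removes gross outliers, optionally decomposes the 2-D scatter into Gaussian
modes, and correlates each qualifying mode separately. Membership of every
sample in the outcome is recorded in a sample string, one digit per GEM
sample:

    1  in this cluster (used for the correlation)
    0  observed but not in this cluster
    9  missing expression in at least one of the two genes
    6  removed as a pre-clustering outlier
    8  removed as a within-cluster outlier

Clusters smaller than the power-analysis minimum, or spanning less
expression range than ``min_expression_range`` in either gene, are skipped
with a machine-readable reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .gem import GEM
from .gmm import DegenerateFitError, ModelFamily, select_components

__all__ = [
    "CorrelationMethod",
    "OutlierRule",
    "PairwiseConfig",
    "ClusterResult",
    "PairResult",
    "min_cluster_size_power",
    "assemble_pair",
    "flag_outliers_pre",
    "cluster_and_correlate",
    "count_pairs",
    "pair_from_index",
    "iter_pair_results",
    "write_pair_results",
    "read_pair_results",
]


class CorrelationMethod(str, Enum):
    SPEARMAN = "spearman"
    PEARSON = "pearson"


class OutlierRule(str, Enum):
    NONE = "none"
    IQR_1_5 = "iqr_1_5"


def min_cluster_size_power(alpha: float, beta: float, effect_size: float) -> int:
    """Minimum sample count to detect correlation ``effect_size`` at false
    positive rate alpha and false negative rate beta (Fisher-z power bound):

        n = ceil( ((z_{1-alpha/2} + z_{1-beta}) / atanh(r))^2 + 3 )
    """
    for name, v in (("alpha", alpha), ("beta", beta), ("effect_size", effect_size)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(1.0 - beta)
    return math.ceil((z / math.atanh(effect_size)) ** 2 + 3.0)


@dataclass
class PairwiseConfig:
    method: CorrelationMethod = CorrelationMethod.SPEARMAN
    use_gmm: bool = True
    min_cluster_size: int = 30
    min_expression_range: float = 0.1
    K_max: int = 5
    restarts: int = 3
    seed: int = 0
    outlier_rule: OutlierRule = OutlierRule.IQR_1_5
    family: ModelFamily = ModelFamily.FREE_FULL

    def __post_init__(self) -> None:
        if isinstance(self.method, str):
            self.method = CorrelationMethod(self.method)
        if isinstance(self.outlier_rule, str):
            self.outlier_rule = OutlierRule(self.outlier_rule)
        if isinstance(self.family, str):
            self.family = ModelFamily(self.family)
        if self.min_cluster_size < 3:
            raise ValueError("min_cluster_size must be >= 3")
        if self.min_expression_range < 0:
            raise ValueError("min_expression_range must be >= 0")


@dataclass
class ClusterResult:
    index: int
    size: int                      # surviving ('1') sample count
    rho: Optional[float]           # None when skipped
    sample_string: str
    reason: Optional[str] = None   # skip reason, None when correlated

    @property
    def skipped(self) -> bool:
        return self.reason is not None


@dataclass
class PairResult:
    gene_a: str
    gene_b: str
    clusters: list[ClusterResult] = field(default_factory=list)
    reason: Optional[str] = None   # pair-level failure, e.g. "insufficient data"


def assemble_pair(gem: GEM, i: str, j: str):
    """Complete observations for transcripts i, j in GEM column order.

    Returns ``(points, template, obs_idx)``: the N x 2 point matrix, the
    length-M digit template ('9' where either gene is missing, '0'
    elsewhere) and the sample indices of the points.
    """
    if i == j:
        raise ValueError("i and j must differ")
    xi = gem.row(i)
    xj = gem.row(j)
    ok = ~(np.isnan(xi) | np.isnan(xj))
    template = np.where(ok, "0", "9")
    points = np.column_stack([xi[ok], xj[ok]])
    return points, "".join(template), np.flatnonzero(ok)


# Fence multipliers for the two outlier-removal steps. Before clustering the
# cloud is intentionally multimodal, so only far-out gross artifacts may be
# removed (3 x IQR); inside a Gaussian cluster the classic 1.5 x IQR fence
# applies.
PRE_CLUSTER_FENCE = 3.0
WITHIN_CLUSTER_FENCE = 1.5


def flag_outliers_pre(
    points: np.ndarray,
    rule: OutlierRule = OutlierRule.IQR_1_5,
    fence: float = WITHIN_CLUSTER_FENCE,
) -> np.ndarray:
    """Boolean outlier flags: a point is flagged when either coordinate lies
    outside the ``fence`` x IQR fences of that coordinate. Fewer than 4
    points, or rule ``none``, flags nothing."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if rule is OutlierRule.NONE or n < 4:
        return np.zeros(n, dtype=bool)
    q1 = np.percentile(points, 25, axis=0)
    q3 = np.percentile(points, 75, axis=0)
    iqr = q3 - q1
    lo = q1 - fence * iqr
    hi = q3 + fence * iqr
    return np.any((points < lo) | (points > hi), axis=1)


def _correlate(points: np.ndarray, method: CorrelationMethod) -> float:
    if method is CorrelationMethod.SPEARMAN:
        return float(stats.spearmanr(points[:, 0], points[:, 1]).statistic)
    return float(stats.pearsonr(points[:, 0], points[:, 1]).statistic)


def _pair_seed(cfg_seed: int, i: str, j: str) -> int:
    """Deterministic per-pair seed, symmetric in gene order and independent
    of chunking."""
    a, b = sorted((i, j))
    h = np.frombuffer(f"{a}\t{b}".encode(), dtype=np.uint8)
    return int(
        np.random.SeedSequence([cfg_seed, *h.tolist()]).generate_state(1)[0]
    )


def cluster_and_correlate(
    gem: GEM, i: str, j: str, cfg: PairwiseConfig
) -> PairResult:
    """Full per-pair pipeline: assemble -> pre-clustering outliers (6) ->
    Gaussian mode discovery -> per-cluster outliers (8), size and range
    filters, correlation, sample string."""
    points, template, obs_idx = assemble_pair(gem, i, j)
    base = list(template)
    result = PairResult(gene_a=i, gene_b=j)
    if points.shape[0] < 2:
        result.reason = "insufficient data"
        return result

    pre_flags = flag_outliers_pre(points, cfg.outlier_rule, PRE_CLUSTER_FENCE)
    for pos in obs_idx[pre_flags]:
        base[pos] = "6"
    keep = ~pre_flags
    points = points[keep]
    obs_idx = obs_idx[keep]
    if points.shape[0] < 2:
        result.reason = "insufficient data"
        return result

    if cfg.use_gmm:
        try:
            fit = select_components(
                points,
                K_max=cfg.K_max,
                family=cfg.family,
                seed=_pair_seed(cfg.seed, i, j),
                restarts=cfg.restarts,
            )
        except DegenerateFitError:
            result.reason = "degenerate fit"
            return result
        labels = fit.labels
        n_clusters = fit.K
    else:
        labels = np.zeros(points.shape[0], dtype=int)
        n_clusters = 1

    for k in range(n_clusters):
        members = labels == k
        mem_points = points[members]
        mem_idx = obs_idx[members]
        in_flags = flag_outliers_pre(
            mem_points, cfg.outlier_rule, WITHIN_CLUSTER_FENCE
        )
        digits = list(base)
        for pos in mem_idx[in_flags]:
            digits[pos] = "8"
        surv_points = mem_points[~in_flags]
        surv_idx = mem_idx[~in_flags]
        for pos in surv_idx:
            digits[pos] = "1"
        size = surv_points.shape[0]
        reason = None
        rho = None
        if size < cfg.min_cluster_size:
            reason = "below min_cluster_size"
        else:
            ranges = surv_points.max(axis=0) - surv_points.min(axis=0)
            if np.any(ranges < cfg.min_expression_range):
                reason = "below range"
            else:
                rho = _correlate(surv_points, cfg.method)
        result.clusters.append(
            ClusterResult(
                index=k,
                size=size,
                rho=rho,
                sample_string="".join(digits),
                reason=reason,
            )
        )
    return result


def count_pairs(n: int) -> int:
    """Number of unordered transcript pairs, n(n-1)/2; 0 for n < 2."""
    if n < 2:
        return 0
    return n * (n - 1) // 2


def pair_from_index(idx: int, n: int) -> tuple[int, int]:
    """Map a row-major upper-triangle pair index to (i, j), i < j."""
    total = count_pairs(n)
    if not 0 <= idx < total:
        raise IndexError(f"pair index {idx} out of range for n={n}")
    # largest i with cum(i) <= idx, cum(i) = i*n - i(i+1)/2
    lo, hi = 0, n - 2
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if mid * n - mid * (mid + 1) // 2 <= idx:
            lo = mid
        else:
            hi = mid - 1
    i = lo
    j = i + 1 + (idx - (i * n - i * (i + 1) // 2))
    return i, j


def iter_pair_results(
    gem: GEM,
    cfg: PairwiseConfig,
    start: int = 0,
    end: Optional[int] = None,
) -> Iterator[PairResult]:
    """Yield PairResults for the pair-index window [start, end) of the
    row-major upper triangle. Chunked windows merge to the full run because
    per-pair seeds depend only on pair identity."""
    n = gem.n_transcripts
    total = count_pairs(n)
    if end is None:
        end = total
    for idx in range(start, min(end, total)):
        i, j = pair_from_index(idx, n)
        yield cluster_and_correlate(
            gem, gem.transcript_ids[i], gem.transcript_ids[j], cfg
        )


_COLUMNS = [
    "gene_a",
    "gene_b",
    "cluster_index",
    "num_clusters",
    "cluster_size",
    "method",
    "rho",
    "sample_string",
    "reason",
]


def write_pair_results(
    results: Iterable[PairResult], path, method: str = "spearman"
) -> None:
    """Write per-cluster correlation rows as TSV (the "correlation file")."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for res in results:
            for cl in res.clusters:
                rho = "NA" if cl.rho is None else "%.10g" % cl.rho
                fh.write(
                    "\t".join(
                        [
                            res.gene_a,
                            res.gene_b,
                            str(cl.index),
                            str(len(res.clusters)),
                            str(cl.size),
                            method,
                            rho,
                            cl.sample_string,
                            cl.reason or "",
                        ]
                    )
                    + "\n"
                )


def read_pair_results(paths) -> list[PairResult]:
    """Read one or more correlation TSVs back into PairResults."""
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    frames = [
        pd.read_csv(
            p, sep="\t", dtype={"sample_string": str, "reason": str},
            na_values=["NA"], keep_default_na=False,
        )
        for p in paths
    ]
    df = pd.concat(frames, ignore_index=True)
    out: dict[tuple[str, str], PairResult] = {}
    for row in df.itertuples(index=False):
        key = (row.gene_a, row.gene_b)
        if key not in out:
            out[key] = PairResult(gene_a=row.gene_a, gene_b=row.gene_b)
        rho = None if pd.isna(row.rho) else float(row.rho)
        reason = row.reason if isinstance(row.reason, str) and row.reason else None
        out[key].clusters.append(
            ClusterResult(
                index=int(row.cluster_index),
                size=int(row.cluster_size),
                rho=rho,
                sample_string=str(row.sample_string),
                reason=reason,
            )
        )
    return list(out.values())
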