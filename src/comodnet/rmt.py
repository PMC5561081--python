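"""Correlation-threshold selection by Random Matrix Theory.

The nearest-neighbour spacing distribution (NNSD) of the eigenvalues of a
correlation matrix dominated by correlated noise follows the Gaussian
Orthogonal Ensemble (Wigner-Dyson) law, while a matrix reduced to modular
(block) signal shows Poisson spacing statistics. Scanning the threshold
upward, the chosen cutoff is the first at which the NNSD of the unfolded
spectrum becomes consistent with Poisson, measured by a chi-square statistic
against exponential bin counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats
from scipy.interpolate import LSQUnivariateSpline

from .pairwise import PairResult

__all__ = [
    "RmtScan",
    "similarity_matrix_at",
    "unfold_spectrum",
    "nnsd_poisson_chi2",
    "find_threshold",
    "DEFAULT_CHI2_CRIT",
]

# chi-square 0.999 critical value for the default 60-bin histogram
DEFAULT_CHI2_CRIT = float(stats.chi2.ppf(0.999, 59))


@dataclass
class RmtScan:
    taus: list[float] = field(default_factory=list)
    chi2: list[float] = field(default_factory=list)
    sizes: list[int] = field(default_factory=list)
    chosen_tau: Optional[float] = None
    diagnostic: Optional[str] = None


def similarity_matrix_at(
    results: Iterable[PairResult], tau: float, reduction: str = "max_abs"
) -> tuple[np.ndarray, list[str]]:
    """Thresholded similarity matrix over the transcripts with at least one
    surviving entry.

    Per pair the entry is the maximum |rho| over that pair's non-skipped
    clusters; entries below ``tau`` are zeroed; the diagonal is 1. Returns
    ``(matrix, transcript_ids)``; an empty matrix signals no survivors.
    """
    if reduction != "max_abs":
        raise ValueError(f"unknown reduction {reduction!r}")
    entries: dict[tuple[str, str], float] = {}
    for res in results:
        rhos = [abs(c.rho) for c in res.clusters if not c.skipped]
        if not rhos:
            continue
        v = max(rhos)
        if v >= tau:
            a, b = sorted((res.gene_a, res.gene_b))
            entries[(a, b)] = max(v, entries.get((a, b), 0.0))
    ids = sorted({g for pair in entries for g in pair})
    pos = {g: k for k, g in enumerate(ids)}
    mat = np.eye(len(ids))
    for (a, b), v in entries.items():
        mat[pos[a], pos[b]] = v
        mat[pos[b], pos[a]] = v
    return mat, ids


def unfold_spectrum(
    eigenvalues: np.ndarray,
    degree: int = 3,
    n_knots: int = 10,
    min_count: int = 100,
    dedup_tol: float = 1e-6,
) -> np.ndarray:
    """Unfold a spectrum to unit mean level spacing.

    A smooth spline of the cumulative spectral density is fit over the
    (deduplicated) sorted eigenvalues; eigenvalues mapped through it yield
    successive spacings rescaled to mean 1. Near-duplicate eigenvalues are
    pruned at ``dedup_tol`` first, since exact degeneracies break the NNSD.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    keep = np.concatenate([[True], np.diff(ev) > dedup_tol])
    ev = ev[keep]
    n = ev.size
    if n < min_count:
        raise ValueError("matrix too small for NNSD")
    cdf = (np.arange(n) + 1.0) / n
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    knots = np.quantile(ev, qs)
    knots = knots[(knots > ev[degree]) & (knots < ev[-degree - 1])]
    knots = np.unique(knots)
    spline = LSQUnivariateSpline(ev, cdf, knots, k=degree)
    unfolded = n * spline(ev)
    spacings = np.clip(np.diff(unfolded), 0.0, None)
    mean = spacings.mean()
    if mean <= 0:
        raise ValueError("degenerate unfolded spectrum")
    return spacings / mean


def nnsd_poisson_chi2(
    spacings: np.ndarray, n_bins: int = 60, s_max: float = 3.0
) -> float:
    """Chi-square statistic of the spacing histogram against the Poisson
    (exponential) NNSD.

    Spacings are binned on ``[0, s_max]`` plus an overflow bin; the expected
    count in bin [a, b) is N (exp(-a) - exp(-b)). Low-expectation tail bins
    are merged rightward so every cell keeps an expected count >= 5.
    """
    s = np.asarray(spacings, dtype=float)
    if s.size < 60:
        raise ValueError("need at least 60 spacings")
    N = s.size
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs, _ = np.histogram(s, bins=edges)
    obs = np.append(obs, np.sum(s >= s_max))
    expect = N * -np.diff(np.exp(-edges))
    expect = np.append(expect, N * math.exp(-s_max))
    # merge low-expectation cells into their left neighbour, from the tail
    o: list[float] = list(obs)
    e: list[float] = list(expect)
    k = len(e) - 1
    while k > 0:
        if e[k] < 5.0:
            e[k - 1] += e[k]
            o[k - 1] += o[k]
            del e[k], o[k]
        k -= 1
    o_arr = np.array(o)
    e_arr = np.array(e)
    return float(((o_arr - e_arr) ** 2 / e_arr).sum())


def find_threshold(
    results: Iterable[PairResult],
    tau_start: float = 0.50,
    tau_step: float = 0.001,
    chi2_crit: float = DEFAULT_CHI2_CRIT,
    min_size: int = 100,
    n_bins: int = 60,
    s_max: float = 3.0,
) -> RmtScan:
    """Ascend the threshold from ``tau_start`` in steps of ``tau_step`` and
    stop at the first tau whose NNSD chi-square drops to ``chi2_crit`` or
    below (spacings consistent with Poisson)."""
    if not 0.0 < tau_start < 1.0:
        raise ValueError("tau_start must be in (0, 1)")
    if tau_step <= 0:
        raise ValueError("tau_step must be > 0")
    results = list(results)
    scan = RmtScan()
    tau = tau_start
    while tau < 1.0:
        mat, _ids = similarity_matrix_at(results, tau)
        if mat.shape[0] < min_size:
            scan.diagnostic = (
                f"matrix too small for NNSD at tau={tau:.4f} "
                f"(size {mat.shape[0]} < {min_size})"
            )
            break
        ev = np.linalg.eigvalsh(mat)
        try:
            spacings = unfold_spectrum(ev, min_count=min_size)
            chi2 = nnsd_poisson_chi2(spacings, n_bins=n_bins, s_max=s_max)
        except ValueError as err:
            scan.diagnostic = f"{err} at tau={tau:.4f}"
            break
        scan.taus.append(tau)
        scan.chi2.append(chi2)
        scan.sizes.append(mat.shape[0])
        if chi2 <= chi2_crit:
            scan.chosen_tau = tau
            break
        tau = round(tau + tau_step, 12)
    return scan
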