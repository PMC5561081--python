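"""Bivariate Gaussian mixture fitting by EM with ICL model selection.

Each gene pair's complete observations form a 2-D point cloud that may hold
several modes of expression (one per underlying biological condition). The
mixture density is f(x|theta) = sum_k p_k h(x|mu_k, Sigma_k). EM is run from
a random initialization in which each component mean is a distinct randomly
chosen data point, proportions are uniform 1/K and covariances start at the
pooled sample covariance. The number of components is chosen by minimizing
the Integrated Completed Likelihood (ICL), which adds an assignment-entropy
penalty to BIC and therefore favors well-separated modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "ModelFamily",
    "GmmFit",
    "DegenerateFitError",
    "fit_em",
    "score_bic",
    "score_icl",
    "n_free_parameters",
    "select_components",
]

_LOG_2PI = math.log(2.0 * math.pi)


class ModelFamily(str, Enum):
    """Covariance constraint applied at every M-step.

    ``free_full``: proportions and all 2x2 covariances free (6K-1 parameters).
    ``free_volume_common_shape``: per-component volume L_k, one shared
    shape/orientation matrix C with det(C)=1, Sigma_k = L_k * C
    (the "ellipsoidal Gaussian model with free proportions"; 4K+1 parameters).
    """

    FREE_FULL = "free_full"
    FREE_VOLUME_COMMON_SHAPE = "free_volume_common_shape"


class DegenerateFitError(RuntimeError):
    pass


@dataclass
class GmmFit:
    K: int
    proportions: np.ndarray          # (K,)
    means: np.ndarray                # (K, 2)
    covariances: np.ndarray          # (K, 2, 2)
    responsibilities: np.ndarray     # (N, K)
    labels: np.ndarray               # (N,) argmax responsibility
    log_likelihood: float
    bic: float = math.nan
    icl: float = math.nan
    family: ModelFamily = ModelFamily.FREE_FULL
    converged: bool = False
    n_iter: int = 0
    loglik_trace: list[float] = field(default_factory=list)


def n_free_parameters(family: ModelFamily, K: int, d: int = 2) -> int:
    if d != 2:
        raise ValueError("only bivariate mixtures are supported")
    if family is ModelFamily.FREE_FULL:
        return (K - 1) + 2 * K + 3 * K
    # K-1 proportions, 2K means, K volumes, d(d+1)/2 - 1 = 2 shared shape dof
    return (K - 1) + 2 * K + K + 2


def _log_gauss(points: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Component-wise bivariate Gaussian log densities, shape (N, K)."""
    a = covs[:, 0, 0]
    b = covs[:, 0, 1]
    c = covs[:, 1, 1]
    det = a * c - b * b
    if np.any(det <= 0):
        raise DegenerateFitError("degenerate fit")
    dx = points[:, 0:1] - means[:, 0][None, :]
    dy = points[:, 1:2] - means[:, 1][None, :]
    quad = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return -0.5 * (quad + np.log(det)[None, :]) - _LOG_2PI


def _pooled_cov(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    return centered.T @ centered / points.shape[0]


def _regularize(covs: np.ndarray, scale: float) -> np.ndarray:
    """Add a small diagonal ridge to near-singular covariances."""
    a = covs[:, 0, 0]
    c = covs[:, 1, 1]
    det = a * c - covs[:, 0, 1] ** 2
    bad = det < 1e-12
    if np.any(bad):
        covs = covs.copy()
        covs[bad, 0, 0] += 1e-6 * scale
        covs[bad, 1, 1] += 1e-6 * scale
    return covs


def _mstep(
    points: np.ndarray, resp: np.ndarray, family: ModelFamily, reg_scale: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    N, K = resp.shape
    nk = resp.sum(axis=0)
    if np.any(nk < 1e-10):
        raise DegenerateFitError("degenerate fit")
    props = nk / N
    means = (resp.T @ points) / nk[:, None]
    scatters = np.empty((K, 2, 2))
    for k in range(K):
        d = points - means[k]
        rd = resp[:, k][:, None] * d
        scatters[k] = rd.T @ d
    if family is ModelFamily.FREE_FULL:
        covs = scatters / nk[:, None, None]
    else:
        # Sigma_k = L_k * C, det(C) = 1; alternate closed-form updates
        L = np.empty(K)
        for k in range(K):
            det = scatters[k, 0, 0] * scatters[k, 1, 1] - scatters[k, 0, 1] ** 2
            L[k] = math.sqrt(max(det, 1e-300)) / nk[k]
        C = np.eye(2)
        for _ in range(5):
            Craw = np.tensordot(1.0 / np.maximum(L, 1e-300), scatters, axes=1)
            detC = Craw[0, 0] * Craw[1, 1] - Craw[0, 1] ** 2
            if detC <= 0:
                raise DegenerateFitError("degenerate fit")
            C = Craw / math.sqrt(detC)
            Cinv = np.array([[C[1, 1], -C[0, 1]], [-C[0, 1], C[0, 0]]])
            for k in range(K):
                L[k] = float(np.trace(Cinv @ scatters[k])) / (2.0 * nk[k])
        covs = L[:, None, None] * C[None, :, :]
    covs = _regularize(covs, reg_scale)
    return props, means, covs


@njit(cache=True, fastmath=True)
def _em_core_free(points, means, covs, props, resp, trace, max_iter, tol, ridge):
    """EM iterations for the free-covariance family, in place.

    Returns (status, n_iter, converged); status 1 signals a collapsed
    component. The covariance ridge mirrors the numpy path: a small diagonal
    addition whenever a determinant falls below 1e-12.
    """
    N = points.shape[0]
    K = means.shape[0]
    log2pi = 1.8378770664093453
    ia = np.empty(K)
    ib = np.empty(K)
    ic = np.empty(K)
    logdet = np.empty(K)
    logp = np.empty(K)
    prev = 0.0
    n_it = 0
    converged = False
    for it in range(max_iter):
        for k in range(K):
            a = covs[k, 0, 0]
            b = covs[k, 0, 1]
            c = covs[k, 1, 1]
            det = a * c - b * b
            if det < 1e-12:
                a += ridge
                c += ridge
                covs[k, 0, 0] = a
                covs[k, 1, 1] = c
                det = a * c - b * b
                if det <= 0.0:
                    return 1, n_it, False
            logdet[k] = math.log(det)
            ia[k] = c / det
            ib[k] = b / det
            ic[k] = a / det
            logp[k] = math.log(props[k])
        ll = 0.0
        for i in range(N):
            mx = -1e308
            for k in range(K):
                dx = points[i, 0] - means[k, 0]
                dy = points[i, 1] - means[k, 1]
                q = ia[k] * dx * dx - 2.0 * ib[k] * dx * dy + ic[k] * dy * dy
                lp = -0.5 * (q + logdet[k]) - log2pi + logp[k]
                resp[i, k] = lp
                if lp > mx:
                    mx = lp
            s = 0.0
            for k in range(K):
                w = math.exp(resp[i, k] - mx)
                resp[i, k] = w
                s += w
            ll += math.log(s) + mx
            for k in range(K):
                resp[i, k] /= s
        trace[it] = ll
        n_it = it + 1
        if it > 0 and abs(ll - prev) < tol * abs(prev):
            converged = True
            break
        prev = ll
        for k in range(K):
            nk = 0.0
            sx = 0.0
            sy = 0.0
            for i in range(N):
                r = resp[i, k]
                nk += r
                sx += r * points[i, 0]
                sy += r * points[i, 1]
            if nk < 1e-10:
                return 1, n_it, False
            mu_x = sx / nk
            mu_y = sy / nk
            sxx = 0.0
            sxy = 0.0
            syy = 0.0
            for i in range(N):
                r = resp[i, k]
                dx = points[i, 0] - mu_x
                dy = points[i, 1] - mu_y
                sxx += r * dx * dx
                sxy += r * dx * dy
                syy += r * dy * dy
            means[k, 0] = mu_x
            means[k, 1] = mu_y
            covs[k, 0, 0] = sxx / nk
            covs[k, 0, 1] = sxy / nk
            covs[k, 1, 0] = sxy / nk
            covs[k, 1, 1] = syy / nk
            props[k] = nk / N
    return 0, n_it, converged


def fit_em(
    points: np.ndarray,
    K: int,
    family: ModelFamily = ModelFamily.FREE_FULL,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    retries: int = 3,
    _pooled: np.ndarray | None = None,
) -> GmmFit:
    """Fit a K-component bivariate mixture by EM.

    Initialization: component means are K distinct randomly chosen data
    points, proportions uniform 1/K, covariances the pooled ML sample
    covariance. Convergence when the relative log-likelihood change drops
    below ``tol``. A collapsed (singular) component triggers a restart from a
    fresh seeded draw, up to ``retries`` times.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be N x 2")
    N = points.shape[0]
    if N < K:
        raise ValueError("need at least K points")
    if _pooled is None:
        _pooled = _pooled_cov(points)
    reg_scale = max(float(_pooled[0, 0] + _pooled[1, 1]) / 2.0, 1e-12)
    pooled = _regularize(_pooled[None], reg_scale)[0]
    last_err: Exception | None = None
    for attempt in range(retries + 1):
        rng = np.random.default_rng([seed, attempt, K])
        idx = rng.choice(N, size=K, replace=False)
        means = points[idx].copy()
        props = np.full(K, 1.0 / K)
        covs = np.repeat(pooled[None], K, axis=0)
        if family is ModelFamily.FREE_FULL and _HAVE_NUMBA:
            N = points.shape[0]
            resp = np.empty((N, K))
            trace_buf = np.empty(max_iter)
            status, n_it, converged = _em_core_free(
                points, means, covs, props, resp, trace_buf,
                max_iter, tol, 1e-6 * reg_scale,
            )
            if status != 0:
                last_err = DegenerateFitError("degenerate fit")
                continue
            trace = trace_buf[:n_it].tolist()
            fit = GmmFit(
                K=K,
                proportions=props,
                means=means,
                covariances=covs,
                responsibilities=resp,
                labels=np.argmax(resp, axis=1),
                log_likelihood=trace[-1],
                family=family,
                converged=converged,
                n_iter=n_it,
                loglik_trace=trace,
            )
            fit.bic = score_bic(fit, N)
            fit.icl = score_icl(fit, N)
            return fit
        try:
            return _run_em(
                points, props, means, covs, family, max_iter, tol, reg_scale
            )
        except DegenerateFitError as err:
            last_err = err
    raise DegenerateFitError("degenerate fit") from last_err


def _run_em(points, props, means, covs, family, max_iter, tol, reg_scale) -> GmmFit:
    N = points.shape[0]
    trace: list[float] = []
    prev_ll = None
    resp = None
    converged = False
    for it in range(1, max_iter + 1):
        log_dens = _log_gauss(points, means, covs) + np.log(props)[None, :]
        mx = log_dens.max(axis=1, keepdims=True)
        w = np.exp(log_dens - mx)
        s = w.sum(axis=1, keepdims=True)
        ll = float((np.log(s) + mx).sum())
        resp = w / s
        trace.append(ll)
        if prev_ll is not None and abs(ll - prev_ll) < tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
        props, means, covs = _mstep(points, resp, family, reg_scale)
    fit = GmmFit(
        K=len(props),
        proportions=props,
        means=means,
        covariances=covs,
        responsibilities=resp,
        labels=np.argmax(resp, axis=1),
        log_likelihood=trace[-1],
        family=family,
        converged=converged,
        n_iter=len(trace),
        loglik_trace=trace,
    )
    fit.bic = score_bic(fit, N)
    fit.icl = score_icl(fit, N)
    return fit


def score_bic(fit: GmmFit, N: int) -> float:
    """BIC = -2 log L + nu log N (lower is better)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    nu = n_free_parameters(fit.family, fit.K)
    return -2.0 * fit.log_likelihood + nu * math.log(N)


def score_icl(fit: GmmFit, N: int) -> float:
    """ICL = BIC + 2 * ENT, ENT = -sum_ik t_ik log t_ik (0 log 0 := 0)."""
    t = fit.responsibilities
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t), 0.0)
    ent = -float(terms.sum())
    return score_bic(fit, N) + 2.0 * ent


def select_components(
    points: np.ndarray,
    K_max: int = 5,
    family: ModelFamily = ModelFamily.FREE_FULL,
    seed: int = 0,
    restarts: int = 3,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> GmmFit:
    """Fit K = 1..min(K_max, N-1); per K keep the best log-likelihood over
    ``restarts`` seeded EM runs; return the fit minimizing ICL (ties to the
    smaller K)."""
    points = np.asarray(points, dtype=float)
    N = points.shape[0]
    if N < 2:
        raise ValueError("need at least 2 points")
    k_top = min(K_max, max(1, N - 1))
    pooled = _pooled_cov(points)
    best: GmmFit | None = None
    for K in range(1, k_top + 1):
        best_k: GmmFit | None = None
        for r in range(restarts):
            sub = int(np.random.SeedSequence([seed, K, r]).generate_state(1)[0])
            try:
                fit = fit_em(
                    points, K, family=family, seed=sub,
                    max_iter=max_iter, tol=tol, _pooled=pooled,
                )
            except DegenerateFitError:
                continue
            if best_k is None or fit.log_likelihood > best_k.log_likelihood:
                best_k = fit
        if best_k is None:
            continue
        if best is None or best_k.icl < best.icl:
            best = best_k
    if best is None:
        raise DegenerateFitError("no valid model")
    return best
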