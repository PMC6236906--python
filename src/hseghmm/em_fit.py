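"""EM estimation of chain and global parameters, standard errors, AIC/BIC.

The E-step is the scaled forward-backward pass; the M-step updates the
initial and transition probabilities in closed form and the global
parameters (purity, ploidy, scales, degrees of freedom) by box-constrained
quasi-Newton ascent of their expected complete-data term.  Because the
global M-step only improves (not exactly maximizes) that term, the whole
procedure is a generalized EM and the observed-data log-likelihood is
non-decreasing across iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .emission import (
    GlobalParams,
    LocusObservation,
    ObservationArrays,
    emission_log_matrix,
)
from .hmm_core import (
    ChainParams,
    PosteriorResult,
    decode_map,
    forward_scaled,
    posteriors,
)
from .state_space import StateSpace

__all__ = [
    "FitResult",
    "DEFAULT_BOUNDS",
    "m_step_chain",
    "q_theta",
    "m_step_global",
    "fit",
    "standard_errors",
    "information_criteria",
]

logger = logging.getLogger(__name__)

#: Box constraints for the global M-step.  Purity stays off the boundaries so
#: every expectation is finite; df > 2 keeps the t variance finite.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "purity": (0.01, 0.99),
    "ploidy": (0.5, 8.0),
    "logR_scale2": (1e-6, 100.0),
    "logOR_scale2": (1e-6, 100.0),
    "df": (2.1, 100.0),
}

_PARAM_NAMES_T = ("purity", "ploidy", "logR_scale2", "logOR_scale2", "df")
_PARAM_NAMES_NORM = ("purity", "ploidy", "logR_scale2", "logOR_scale2")


def _param_names(family: str) -> tuple[str, ...]:
    return _PARAM_NAMES_T if family == "t" else _PARAM_NAMES_NORM


def _pack(params: GlobalParams) -> np.ndarray:
    return np.array([getattr(params, n) for n in _param_names(params.family)])


def _unpack(x: np.ndarray, family: str) -> GlobalParams:
    kw = dict(zip(_param_names(family), (float(v) for v in x)))
    return GlobalParams(family=family, **kw)


@dataclass
class FitResult:
    """Everything produced by one converged (or exhausted) EM fit."""

    globals: GlobalParams
    chain: ChainParams
    posterior: PosteriorResult
    decoded: np.ndarray            # (N,) posterior-mode state indices
    loglik_trace: np.ndarray       # per-iteration observed-data log-likelihoods
    aic: float
    bic: float
    n_params: int
    converged: bool
    space: StateSpace
    se: Optional[dict[str, Optional[float]]] = None

    @property
    def loglik(self) -> float:
        return self.posterior.loglik

    @property
    def decoded_labels(self) -> list[str]:
        return [self.space[j].label for j in self.decoded]

    @property
    def decoded_total_cn(self) -> np.ndarray:
        return np.array([self.space[j].total_cn for j in self.decoded])

    @property
    def decoded_major_cn(self) -> np.ndarray:
        return np.array([self.space[j].major_cn for j in self.decoded])

    @property
    def decoded_minor_cn(self) -> np.ndarray:
        return np.array([self.space[j].minor_cn for j in self.decoded])


def m_step_chain(posterior: PosteriorResult, resets=None) -> ChainParams:
    """Closed-form maximizer of the chain terms of the expected log-likelihood.

    The initial distribution is the first smoothed posterior row; each
    transition row is the corresponding row of the summed pairwise
    posteriors, normalized.  A state with no expected visits gets a uniform
    transition row (regularization; its row has zero weight in the
    objective).
    """
    rows = np.unique(np.concatenate([[0], np.asarray(resets, dtype=int)])) if resets is not None else np.array([0])
    gamma1 = posterior.gamma[rows].mean(axis=0)
    init = gamma1 / gamma1.sum()

    pair = posterior.pair_sums
    J = pair.shape[0]
    row_mass = pair.sum(axis=1)
    trans = np.empty_like(pair)
    for i in range(J):
        if row_mass[i] > 0.0:
            trans[i] = pair[i] / row_mass[i]
        else:
            trans[i] = 1.0 / J
    return ChainParams(init=init, trans=trans)


def q_theta(
    params: GlobalParams,
    gamma: np.ndarray,
    loci: Sequence[LocusObservation] | ObservationArrays,
    space: StateSpace,
) -> float:
    """Expected complete-data log emission term: sum_k sum_j gamma_kj log p_kj."""
    log_em = emission_log_matrix(loci, space, params)
    return float(np.sum(gamma * log_em))


def m_step_global(
    gamma: np.ndarray,
    loci: Sequence[LocusObservation] | ObservationArrays,
    space: StateSpace,
    start: GlobalParams,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    maxiter: int = 60,
) -> GlobalParams:
    """Box-constrained quasi-Newton ascent of the global emission term.

    Returns parameters whose objective is no worse than the starting point
    (generalized-EM contract); if the optimizer fails to improve, the start
    is returned unchanged and EM simply proceeds.
    """
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    names = _param_names(start.family)
    box = [bounds[n] for n in names]
    x0 = np.clip(_pack(start), [lo for lo, _ in box], [hi for _, hi in box])
    arrays = (
        loci if isinstance(loci, ObservationArrays) else ObservationArrays.from_loci(loci)
    )

    def neg_q(x: np.ndarray) -> float:
        return -q_theta(_unpack(x, start.family), gamma, arrays, space)

    res = minimize(
        neg_q, x0, method="L-BFGS-B", bounds=box,
        options={"maxiter": maxiter, "ftol": 1e-10},
    )
    q0 = -neg_q(x0)
    if not np.isfinite(res.fun) or -res.fun < q0 - 1e-9:
        logger.warning("global M-step failed to improve (%s); keeping start", res.message)
        return _unpack(x0, start.family)
    return _unpack(res.x, start.family)


def information_criteria(
    loglik: float, n_params: int, n_obs: float
) -> tuple[float, float]:
    """AIC and BIC from a log-likelihood, parameter count, and sample size."""
    if n_params < 1 or n_obs < 1:
        raise ValueError("n_params and n_obs must be >= 1")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + np.log(n_obs) * n_params
    return aic, bic


def count_parameters(n_states: int, family: str) -> int:
    """Free parameters: (J-1) initial + J(J-1) transition + global set."""
    n_global = 5 if family == "t" else 4
    return (n_states - 1) + n_states * (n_states - 1) + n_global


def _moment_start(
    arrays: ObservationArrays, family: str, purity: float, ploidy: float, df: float
) -> GlobalParams:
    """Initial scales from robust moments of the observations."""
    w = arrays.logR
    mad = np.median(np.abs(w - np.median(w)))
    s2 = float(np.clip((1.4826 * mad) ** 2, 1e-3, 50.0))
    if family == "t":
        s2 *= (df - 2.0) / df  # kappa^2 such that the t variance matches s2
    if arrays.logOR_sq_het.size:
        tau2 = float(np.clip(np.median(arrays.logOR_sq_het), 0.01, 10.0))
    else:
        tau2 = 0.25
    return GlobalParams(
        purity=purity, ploidy=ploidy, logR_scale2=s2, logOR_scale2=tau2,
        df=df, family=family,
    )


def _default_grid(
    arrays: ObservationArrays, family: str, df: float = 5.0
) -> list[GlobalParams]:
    return [
        _moment_start(arrays, family, purity, ploidy, df)
        for ploidy in (1.5, 2.0, 3.0, 4.0)
        for purity in (0.3, 0.6, 0.9)
    ]


def _em_iterate(
    arrays: ObservationArrays,
    space: StateSpace,
    params: GlobalParams,
    chain: ChainParams,
    n_iter: int,
    tol: float,
    bounds: Optional[dict[str, tuple[float, float]]],
    m_step_maxiter: int,
    trace: list[float],
    resets=None,
) -> tuple[GlobalParams, ChainParams, bool]:
    """Run up to ``n_iter`` EM iterations, appending logliks to ``trace``."""
    converged = False
    for _ in range(n_iter):
        log_em = emission_log_matrix(arrays, space, params)
        post = posteriors(log_em, chain, resets)
        if not np.isfinite(post.loglik):
            raise FloatingPointError(
                f"non-finite log-likelihood at EM iteration {len(trace)}"
            )
        if trace and post.loglik < trace[-1] - 1e-6 * (1.0 + abs(trace[-1])):
            logger.warning(
                "log-likelihood decreased at iteration %d: %.10g -> %.10g",
                len(trace), trace[-1], post.loglik,
            )
        if trace and abs(post.loglik - trace[-1]) < tol * (1.0 + abs(trace[-1])):
            trace.append(post.loglik)
            converged = True
            break
        trace.append(post.loglik)
        chain = m_step_chain(post, resets)
        params = m_step_global(
            post.gamma, arrays, space, params, bounds=bounds, maxiter=m_step_maxiter
        )
    return params, chain, converged


def fit(
    loci: Sequence[LocusObservation] | ObservationArrays,
    space: StateSpace,
    family: str = "t",
    init: Optional[GlobalParams] = None,
    init_grid: Optional[Sequence[GlobalParams]] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    self_prob: float = 0.99,
    n_screen: int = 3,
    screen_iters: int = 5,
    compute_se: bool = False,
    resets=None,
) -> FitResult:
    """Fit the model by generalized EM with best-of-restarts initialization.

    When ``init`` is given it is the single starting point.  Otherwise a
    coarse purity x ploidy grid (or ``init_grid``) is ranked by initial
    log-likelihood, the top ``n_screen`` candidates get ``screen_iters``
    warm-up EM iterations each, and the best of those is run to convergence.
    Convergence is a relative log-likelihood change below ``tol``.
    """
    arrays = (
        loci if isinstance(loci, ObservationArrays) else ObservationArrays.from_loci(loci)
    )
    if len(arrays) < 2:
        raise ValueError("need at least 2 loci to fit a chain")
    chain0 = ChainParams.uniform_sticky(len(space), self_prob)

    if init is not None:
        params, chain, trace = init, chain0, []
    else:
        candidates = list(init_grid) if init_grid is not None else _default_grid(arrays, family)
        if len(candidates) > n_screen:
            scores = []
            for p in candidates:
                log_em = emission_log_matrix(arrays, space, p)
                _, _, ll = forward_scaled(log_em, chain0)
                scores.append(ll)
            order = np.argsort(scores)[::-1][:n_screen]
            candidates = [candidates[i] for i in order]
        warm = []
        for p in candidates:
            tr: list[float] = []
            pp, cc, _ = _em_iterate(
                arrays, space, p, chain0, screen_iters, tol, bounds,
                m_step_maxiter=20, trace=tr, resets=resets,
            )
            warm.append((tr[-1], pp, cc, tr))
        warm.sort(key=lambda t: t[0], reverse=True)
        _, best_p, best_c, best_tr = warm[0]
        params, chain, trace = best_p, best_c, list(best_tr)

    params, chain, converged = _em_iterate(
        arrays, space, params, chain, max_iter - len(trace), tol, bounds,
        m_step_maxiter=60, trace=trace, resets=resets,
    )

    # Final E-step under the final parameters so posteriors match `globals`.
    log_em = emission_log_matrix(arrays, space, params)
    post = posteriors(log_em, chain, resets)
    decoded = decode_map(post.gamma)
    n_params = count_parameters(len(space), family)
    aic, bic = information_criteria(post.loglik, n_params, len(arrays))
    result = FitResult(
        globals=params, chain=chain, posterior=post, decoded=decoded,
        loglik_trace=np.asarray(trace + [post.loglik]), aic=aic, bic=bic,
        n_params=n_params, converged=converged, space=space,
    )
    if compute_se:
        result.se = standard_errors(result, arrays, space)
    return result


def standard_errors(
    fit_result: FitResult,
    loci: Sequence[LocusObservation] | ObservationArrays,
    space: StateSpace,
    free: Optional[Sequence[str]] = None,
    step: Optional[float] = None,
) -> dict[str, Optional[float]]:
    """Hessian-based asymptotic SEs of the global parameters.

    The numeric Hessian of the negative observed-data log-likelihood is taken
    with respect to the free global parameters, with the chain parameters
    held fixed at their estimates.  A singular (or non-positive-definite)
    Hessian yields ``None`` entries rather than fabricated values.
    """
    from statsmodels.tools.numdiff import approx_hess

    arrays = (
        loci if isinstance(loci, ObservationArrays) else ObservationArrays.from_loci(loci)
    )
    params = fit_result.globals
    names = list(free) if free is not None else list(_param_names(params.family))
    chain = fit_result.chain

    def negll(x: np.ndarray) -> float:
        kw = {n: float(v) for n, v in zip(names, x)}
        p = replace(params, **kw)
        log_em = emission_log_matrix(arrays, space, p)
        _, _, ll = forward_scaled(log_em, chain)
        return -ll

    x0 = np.array([getattr(params, n) for n in names], dtype=float)
    out: dict[str, Optional[float]] = {n: None for n in names}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess(x0, negll, epsilon=step)
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        for n, v in zip(names, diag):
            out[n] = float(np.sqrt(v)) if v > 0.0 else None
    except np.linalg.LinAlgError:
        logger.warning("Hessian not invertible; standard errors unavailable")
    return out
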