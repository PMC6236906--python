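"""Scaled forward-backward recursions, smoothed posteriors, and decoding.

Forward and backward variables are renormalized at every step (the standard
scaled HMM), which keeps the arithmetic in double precision for sequences of
hundreds of thousands of loci.  Emissions arrive in log space; each row is
exponentiated after subtracting its own maximum, and the subtracted shift is
folded back into the per-step scale factor so the log-likelihood is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChainParams",
    "PosteriorResult",
    "forward_scaled",
    "backward_scaled",
    "posteriors",
    "decode_map",
    "decode_viterbi",
]


@dataclass(frozen=True)
class ChainParams:
    """Initial distribution and row-stochastic transition matrix."""

    init: np.ndarray   # (J,)
    trans: np.ndarray  # (J, J)

    def __post_init__(self) -> None:
        init = np.asarray(self.init, dtype=float)
        trans = np.asarray(self.trans, dtype=float)
        object.__setattr__(self, "init", init)
        object.__setattr__(self, "trans", trans)
        J = init.shape[0]
        if trans.shape != (J, J):
            raise ValueError(f"trans must be ({J}, {J}), got {trans.shape}")
        if np.any(init < 0) or np.any(trans < 0):
            raise ValueError("chain probabilities must be nonnegative")
        if not np.isclose(init.sum(), 1.0, atol=1e-8):
            raise ValueError(f"init must sum to 1, sums to {init.sum()}")
        if not np.allclose(trans.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each transition row must sum to 1")

    @property
    def n_states(self) -> int:
        return self.init.shape[0]

    @staticmethod
    def uniform_sticky(n_states: int, self_prob: float = 0.99) -> "ChainParams":
        """Uniform initial distribution with a sticky transition matrix."""
        if n_states == 1:
            return ChainParams(np.ones(1), np.ones((1, 1)))
        off = (1.0 - self_prob) / (n_states - 1)
        trans = np.full((n_states, n_states), off)
        np.fill_diagonal(trans, self_prob)
        return ChainParams(np.full(n_states, 1.0 / n_states), trans)


@dataclass(frozen=True)
class PosteriorResult:
    """Smoothed posteriors and the sufficient statistics of one E-step.

    Attributes
    ----------
    gamma : (N, J) array
        Smoothed per-locus state posteriors; each row sums to 1.
    pair_sums : (J, J) array
        Sum over k >= 2 of the pairwise posteriors P(Z_{k-1}=i, Z_k=j | data);
        total mass N - 1.
    loglik : float
        Observed-data log-likelihood.
    """

    gamma: np.ndarray
    pair_sums: np.ndarray
    loglik: float


def _scaled_emissions(log_emis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-shifted linear emissions and the per-row log shifts."""
    shifts = log_emis.max(axis=1)
    return np.exp(log_emis - shifts[:, None]), shifts


def _normalize_resets(resets, n: int) -> np.ndarray:
    """Validated sorted array of chain-restart indices, always containing 0."""
    if resets is None:
        return np.array([0], dtype=int)
    r = np.unique(np.concatenate([[0], np.asarray(resets, dtype=int)]))
    if r[0] < 0 or (len(r) and r[-1] >= n):
        raise ValueError(f"reset indices must lie in [0, {n})")
    return r


def forward_scaled(
    log_emis: np.ndarray, chain: ChainParams, resets=None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Run the scaled forward recursion.

    ``resets`` lists indices (e.g. chromosome starts) where the chain
    restarts from its initial distribution; by default the whole sequence is
    one chain.

    Returns
    -------
    alpha_hat : (N, J) array
        Per-step normalized forward variables.
    log_scale : (N,) array
        Log of the per-step normalizers; their sum is the log-likelihood.
    loglik : float
    """
    log_emis = np.asarray(log_emis, dtype=float)
    N, J = log_emis.shape
    if chain.n_states != J:
        raise ValueError(f"chain has {chain.n_states} states, emissions have {J}")
    reset_set = set(_normalize_resets(resets, N).tolist())
    emis, shifts = _scaled_emissions(log_emis)

    alpha_hat = np.empty((N, J))
    log_scale = np.empty(N)
    trans = chain.trans
    for k in range(N):
        if k in reset_set:
            a = chain.init * emis[k]
        else:
            a = (alpha_hat[k - 1] @ trans) * emis[k]
        mass = a.sum()
        if mass <= 0.0:
            raise FloatingPointError(
                f"zero forward mass at locus {k} (impossible emissions)"
            )
        alpha_hat[k] = a / mass
        log_scale[k] = np.log(mass) + shifts[k]
    return alpha_hat, log_scale, float(log_scale.sum())


def backward_scaled(
    log_emis: np.ndarray, chain: ChainParams, log_scale: np.ndarray, resets=None
) -> np.ndarray:
    """Run the scaled backward recursion with the forward pass's scale factors.

    The returned variables satisfy ``gamma = alpha_hat * beta_hat`` with rows
    already normalized; the base case (last locus of each chain segment) is a
    row of ones.
    """
    log_emis = np.asarray(log_emis, dtype=float)
    N, J = log_emis.shape
    reset_set = set(_normalize_resets(resets, N).tolist())
    emis, shifts = _scaled_emissions(log_emis)
    scale = np.exp(np.asarray(log_scale, dtype=float) - shifts)

    beta_hat = np.empty((N, J))
    beta_hat[N - 1] = 1.0
    trans = chain.trans
    for k in range(N - 2, -1, -1):
        if (k + 1) in reset_set:
            beta_hat[k] = 1.0
        else:
            b = trans @ (emis[k + 1] * beta_hat[k + 1])
            beta_hat[k] = b / scale[k + 1]
    return beta_hat


def posteriors(
    log_emis: np.ndarray, chain: ChainParams, resets=None
) -> PosteriorResult:
    """Smoothed state posteriors, summed pairwise posteriors, log-likelihood."""
    log_emis = np.asarray(log_emis, dtype=float)
    N, J = log_emis.shape
    reset_set = set(_normalize_resets(resets, N).tolist())
    alpha_hat, log_scale, loglik = forward_scaled(log_emis, chain, resets)
    beta_hat = backward_scaled(log_emis, chain, log_scale, resets)

    gamma = alpha_hat * beta_hat
    gamma /= gamma.sum(axis=1, keepdims=True)

    pair_sums = np.zeros((J, J))
    if N > 1:
        emis, shifts = _scaled_emissions(log_emis)
        scale = np.exp(log_scale - shifts)
        trans = chain.trans
        for k in range(1, N):
            if k in reset_set:
                continue
            # eta_k[i, j] = alpha_hat[k-1, i] * P[i, j] * e_k[j] * beta_hat[k, j] / c_k
            eta = (
                alpha_hat[k - 1][:, None]
                * trans
                * (emis[k] * beta_hat[k])[None, :]
                / scale[k]
            )
            pair_sums += eta
    return PosteriorResult(gamma=gamma, pair_sums=pair_sums, loglik=loglik)


def decode_map(gamma: np.ndarray) -> np.ndarray:
    """Posterior-mode decoding: per-locus argmax of the smoothed posterior.

    Ties break toward the lowest state index.
    """
    gamma = np.asarray(gamma, dtype=float)
    return gamma.argmax(axis=1)


def decode_viterbi(log_emis: np.ndarray, chain: ChainParams) -> np.ndarray:
    """Most probable joint state path (secondary decoder)."""
    log_emis = np.asarray(log_emis, dtype=float)
    N, J = log_emis.shape
    with np.errstate(divide="ignore"):
        log_init = np.log(chain.init)
        log_trans = np.log(chain.trans)
    score = log_init + log_emis[0]
    back = np.empty((N, J), dtype=int)
    for k in range(1, N):
        cand = score[:, None] + log_trans  # (from, to)
        back[k] = cand.argmax(axis=0)
        score = cand.max(axis=0) + log_emis[k]
    path = np.empty(N, dtype=int)
    path[N - 1] = int(score.argmax())
    for k in range(N - 1, 0, -1):
        path[k - 1] = back[k, path[k]]
    return path
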