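"""Synthetic data generators with known ground truth.

Three designs are provided, all driven by a Markov chain over a small set of
true genotype states:

* ``t_logR`` — logR noise is t-distributed (heavy tails), logOR noise normal;
* ``mixnorm_logR`` — logR noise is a zero-mean two-component normal mixture;
* ``read_counts`` — paired tumor/normal allele counts and depths are drawn
  directly (uniform or skewed-beta coverage) and logR/logOR are computed
  from the counts, so neither emission family is trivially correct.

Every generator is deterministic given its seed and returns the generating
config alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .emission import LocusObservation
from .state_space import (
    StateSpace,
    build_state_space,
    expected_logOR_vector,
    expected_logR_vector,
)

__all__ = [
    "SimConfig",
    "SimDataset",
    "simulate_genotype_chain",
    "simulate_scenario_t",
    "simulate_scenario_mixnorm",
    "simulate_read_counts",
    "simulate",
    "probability_of_identification",
]

#: Default sticky self-transition probability; yields long segments.
DEFAULT_SELF_PROB = 0.995

#: Default segment lengths (per genotype A, AB, AA) for the read-count design.
DEFAULT_SEGMENT_LENGTHS = (1600, 1800, 1542)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated dataset.

    Only the fields relevant to the chosen scenario are used: ``df`` for
    ``t_logR``, ``mixnorm`` for ``mixnorm_logR``, the depth settings for
    ``read_counts``.
    """

    scenario: str = "t_logR"  # t_logR | mixnorm_logR | read_counts
    n_loci: int = 10_000
    states_true: tuple[str, ...] = ("A", "AA", "AAAB", "AAAAB")
    trans_true: Optional[tuple[tuple[float, ...], ...]] = None  # sticky default
    self_prob: float = DEFAULT_SELF_PROB
    purity: float = 0.9
    ploidy: float = 1.6
    logR_scale2: float = 0.3
    df: float = 4.0
    logOR_err_var: float = 0.5
    frac_homozygous: float = 0.9
    # (pi1, pi2, mu1, mu2, var1, var2): 70% N(0, .5) + 30% N(0, .5 * 3^2),
    # total noise variance 0.7*0.5 + 0.3*4.5 = 1.7
    mixnorm: tuple[float, float, float, float, float, float] = (
        0.7, 0.3, 0.0, 0.0, 0.5, 4.5,
    )
    # read-count design
    normal_depth: int = 40
    tumor_depth: int = 160
    segment_lengths: tuple[int, ...] = DEFAULT_SEGMENT_LENGTHS
    skewed_coverage: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        pi1, pi2, mu1, mu2, v1, v2 = self.mixnorm
        if not np.isclose(pi1 + pi2, 1.0):
            raise ValueError("mixture proportions must sum to 1")
        if not np.isclose(pi1 * mu1 + pi2 * mu2, 0.0):
            raise ValueError("mixture means must satisfy E(noise) = 0")
        if not 0.0 <= self.frac_homozygous <= 1.0:
            raise ValueError("frac_homozygous must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimDataset:
    """Observations, per-locus true state indices, and the generating config."""

    loci: tuple[LocusObservation, ...]
    truth: np.ndarray
    config: SimConfig
    space_true: StateSpace
    counts: Optional["np.ndarray"] = None  # (N, 8) count table for read_counts

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.truth):
            raise ValueError("truth length must equal locus count")

    @property
    def truth_labels(self) -> list[str]:
        return [self.space_true[j].label for j in self.truth]


def simulate_genotype_chain(
    states: Sequence[str] | StateSpace,
    trans: np.ndarray,
    n: int,
    seed_or_rng,
) -> np.ndarray:
    """Sample a state-index sequence of length ``n`` from a Markov chain.

    The initial state is drawn from the chain's uniform distribution over
    states.  ``seed_or_rng`` is an int seed or a numpy Generator.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    trans = np.asarray(trans, dtype=float)
    J = len(states)
    if trans.shape != (J, J) or np.any(trans < 0) or not np.allclose(
        trans.sum(axis=1), 1.0, atol=1e-8
    ):
        raise ValueError("trans must be a row-stochastic matrix over the states")
    seq = np.empty(n, dtype=int)
    cum = np.cumsum(trans, axis=1)
    u = rng.random(n)
    seq[0] = rng.integers(J)
    for k in range(1, n):
        seq[k] = np.searchsorted(cum[seq[k - 1]], u[k])
    return seq


def _sticky_trans(J: int, self_prob: float) -> np.ndarray:
    if J == 1:
        return np.ones((1, 1))
    trans = np.full((J, J), (1.0 - self_prob) / (J - 1))
    np.fill_diagonal(trans, self_prob)
    return trans


def _true_chain(config: SimConfig, rng) -> tuple[StateSpace, np.ndarray]:
    space = build_state_space(config.states_true)
    trans = (
        np.asarray(config.trans_true, dtype=float)
        if config.trans_true is not None
        else _sticky_trans(len(space), config.self_prob)
    )
    truth = simulate_genotype_chain(space, trans, config.n_loci, rng)
    return space, truth


def _make_loci(
    w: np.ndarray, x: np.ndarray, het: np.ndarray
) -> tuple[LocusObservation, ...]:
    return tuple(
        LocusObservation(
            chrom="1", pos=k + 1, logR=float(w[k]),
            logOR=float(x[k]) if het[k] else None,
        )
        for k in range(w.shape[0])
    )


def _add_logOR(
    zeta_true: np.ndarray, config: SimConfig, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Heterozygosity mask and observed logOR (zeta + normal noise)."""
    n = zeta_true.shape[0]
    het = rng.random(n) >= config.frac_homozygous
    x = np.zeros(n)
    x[het] = zeta_true[het] + rng.normal(
        0.0, np.sqrt(config.logOR_err_var), het.sum()
    )
    return het, x


def simulate_scenario_t(config: SimConfig) -> SimDataset:
    """logR = state mean + scaled t noise; logOR = state mean + normal noise."""
    if config.scenario != "t_logR":
        raise ValueError(f"config.scenario is {config.scenario!r}, expected 't_logR'")
    rng = np.random.default_rng(config.seed)
    space, truth = _true_chain(config, rng)
    mu = np.asarray(expected_logR_vector(space, config.purity, config.ploidy))
    zeta = np.asarray(expected_logOR_vector(space, config.purity))
    w = mu[truth] + np.sqrt(config.logR_scale2) * rng.standard_t(config.df, config.n_loci)
    het, x = _add_logOR(zeta[truth], config, rng)
    return SimDataset(_make_loci(w, x, het), truth, config, space)


def simulate_scenario_mixnorm(config: SimConfig) -> SimDataset:
    """logR noise from a zero-mean two-component normal mixture."""
    if config.scenario != "mixnorm_logR":
        raise ValueError(
            f"config.scenario is {config.scenario!r}, expected 'mixnorm_logR'"
        )
    rng = np.random.default_rng(config.seed)
    space, truth = _true_chain(config, rng)
    mu = np.asarray(expected_logR_vector(space, config.purity, config.ploidy))
    zeta = np.asarray(expected_logOR_vector(space, config.purity))
    pi1, _, mu1, mu2, v1, v2 = config.mixnorm
    comp2 = rng.random(config.n_loci) >= pi1
    eps = rng.normal(mu1, np.sqrt(v1), config.n_loci)
    eps[comp2] = rng.normal(mu2, np.sqrt(v2), comp2.sum())
    w = mu[truth] + eps
    het, x = _add_logOR(zeta[truth], config, rng)
    return SimDataset(_make_loci(w, x, het), truth, config, space)


_RC_GENOTYPES = ("A", "AB", "AA")


def _uniform_counts(center: float, halfwidth: float, size: int, rng) -> np.ndarray:
    return rng.uniform(center - halfwidth, center + halfwidth, size)


def simulate_read_counts(config: SimConfig) -> SimDataset:
    """Draw paired tumor/normal counts and depths, then derive logR/logOR.

    The true tumor profile cycles genotypes A, AB, AA in the configured
    segment lengths.  Germline zygosity is a per-locus attribute independent
    of the tumor genotype: a fraction ``1 - frac_homozygous`` of loci are
    heterozygous in the normal (count center depth/2), the rest homozygous
    (count == depth).  Tumor coverage centers depend on the tumor genotype
    (AB and AA: full nominal depth; A: half, the lost allele's reads are
    gone), and the tumor A-allele count is half the depth for AB at
    heterozygous loci and equal to the depth otherwise (AA has duplicated A,
    A has only A).

    Normal counts/depths are uniform draws (half-width 15 at AB/AA loci, 20
    at A loci, scaled to the nominal depth); tumor draws use a 70/30 mixture
    of half-widths 30 and 15.  Values are rounded to integers, depths below
    1 are clipped up to 1, counts are clipped into [0, depth].  With
    ``skewed_coverage`` the tumor depth is instead a beta(1, 6) draw
    rescaled to [1, 2 x nominal depth] with a binomial count at the
    genotype's allele fraction.
    """
    if config.scenario != "read_counts":
        raise ValueError(
            f"config.scenario is {config.scenario!r}, expected 'read_counts'"
        )
    rng = np.random.default_rng(config.seed)
    lengths = config.segment_lengths
    labels = [_RC_GENOTYPES[i % 3] for i in range(len(lengths))]
    space = build_state_space(_RC_GENOTYPES)
    idx_of = {lab: i for i, lab in enumerate(_RC_GENOTYPES)}
    truth = np.concatenate(
        [np.full(n, idx_of[lab], dtype=int) for lab, n in zip(labels, lengths)]
    )
    n = truth.shape[0]
    het = rng.random(n) >= config.frac_homozygous
    nd = float(config.normal_depth)
    td = float(config.tumor_depth)

    ncount = np.empty(n)
    ndepth = np.empty(n)
    tcount = np.empty(n)
    tdepth = np.empty(n)
    for lab, j in idx_of.items():
        sel = truth == j
        m = int(sel.sum())
        # normal: depth around the nominal; count half of it if germline het
        nhw = (nd / 2 if lab == "A" else 0.375 * nd)  # 20 or 15 at depth 40
        ndraw = _uniform_counts(nd, nhw, m, rng)
        ndepth[sel] = ndraw
        ncount[sel] = np.where(
            het[sel], _uniform_counts(nd / 2, nhw, m, rng), ndraw
        )
        # tumor: A lost an allele, so its coverage is halved
        tdep_c = td / 2 if lab == "A" else td
        # A-allele fraction of tumor reads: 1 unless the genotype keeps B
        tfrac = 0.5 if lab == "AB" else 1.0
        if config.skewed_coverage:
            depth = 1.0 + (2.0 * tdep_c - 1.0) * rng.beta(1.0, 6.0, m)
            counts = rng.binomial(np.round(depth).astype(int), tfrac).astype(float)
        else:
            wide = rng.random(m) < 0.7
            hw = np.where(wide, 30.0, 15.0) * (td / 160.0)
            depth = tdep_c + rng.uniform(-hw, hw)
            if tfrac == 1.0:
                counts = depth.copy()
            else:
                counts = tfrac * tdep_c + rng.uniform(-hw, hw)
        # germline-homozygous loci carry only the A allele in the tumor too
        counts = np.where(het[sel], counts, depth)
        tdepth[sel] = depth
        tcount[sel] = counts

    ndepth = np.maximum(np.round(ndepth), 1.0)
    tdepth = np.maximum(np.round(tdepth), 1.0)
    ncount = np.clip(np.round(ncount), 0.0, ndepth)
    tcount = np.clip(np.round(tcount), 0.0, tdepth)

    from .io_cli import compute_logOR_from_arrays, compute_logR_from_depths

    logr = compute_logR_from_depths(tdepth, ndepth)
    logor = compute_logOR_from_arrays(
        tcount, tdepth - tcount, ncount, ndepth - ncount
    )
    loci = _make_loci(logr, logor, het)
    counts = np.column_stack(
        [ncount, ndepth - ncount, ndepth, tcount, tdepth - tcount, tdepth]
    ).astype(int)
    return SimDataset(loci, truth, config, space, counts=counts)


def simulate(config: SimConfig) -> SimDataset:
    """Dispatch on ``config.scenario``."""
    dispatch = {
        "t_logR": simulate_scenario_t,
        "mixnorm_logR": simulate_scenario_mixnorm,
        "read_counts": simulate_read_counts,
    }
    try:
        return dispatch[config.scenario](config)
    except KeyError:
        raise ValueError(
            f"unknown scenario {config.scenario!r}; choose from {sorted(dispatch)}"
        ) from None


def probability_of_identification(
    decoded_replicates: Sequence[np.ndarray],
    truth_replicates: Sequence[np.ndarray],
) -> tuple[np.ndarray, dict[int, float]]:
    """Per-locus and per-genotype probability of correct identification.

    Parameters are replicate-aligned sequences of decoded and true state
    indices (same state coding).  Returns the per-locus mean of the 0/1
    correctness indicator across replicates, and the mean correctness
    aggregated over all loci whose true state is j, for each j observed.
    """
    decoded = np.asarray(decoded_replicates, dtype=int)
    truth = np.asarray(truth_replicates, dtype=int)
    if decoded.shape != truth.shape or decoded.ndim != 2:
        raise ValueError(
            f"replicate arrays must share shape (R, N); got {decoded.shape} "
            f"and {truth.shape}"
        )
    correct = decoded == truth
    per_locus = correct.mean(axis=0)
    per_state = {
        int(j): float(correct[truth == j].mean()) for j in np.unique(truth)
    }
    return per_locus, per_state
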