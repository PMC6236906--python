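"""Per-locus, per-state joint log emission densities for (logR, logOR^2).

Two logR families are supported: a location-scale Student-t (robust to the
outliers that drive hypersegmentation) and a normal.  The squared logOR at
heterozygous loci is modeled as tau^2 times a noncentral chi-square with one
degree of freedom and noncentrality zeta^2 / tau^2; at homozygous loci the
logOR term is absent.

The t density is the analytic closed form of a normal-gamma scale mixture
(the mixture integral itself is retained only as a test oracle).  The logOR^2
log-density includes the -log(tau^2) change-of-variable constant so that the
log-likelihood is a proper function of tau^2 and AIC/BIC comparisons across
fits are valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .state_space import (
    GenotypeState,
    StateSpace,
    expected_logOR_vector,
    expected_logR_vector,
)

__all__ = [
    "LocusObservation",
    "GlobalParams",
    "LOG_DENSITY_FLOOR",
    "log_density_logR_t",
    "log_density_logR_norm",
    "log_density_logOR_sq",
    "joint_log_emission",
    "emission_log_matrix",
]

#: Any log emission below this is clamped; exp(-745) is the smallest positive
#: normal double, so the floor keeps forward-backward arithmetic finite while
#: preserving the ordering of plausible states.
LOG_DENSITY_FLOOR: float = -745.0

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class LocusObservation:
    """One genomic position: logR always present, logOR only if heterozygous."""

    chrom: str
    pos: int
    logR: float
    logOR: Optional[float] = None

    @property
    def is_het(self) -> bool:
        return self.logOR is not None

    def __post_init__(self) -> None:
        if not np.isfinite(self.logR):
            raise ValueError(f"{self.chrom}:{self.pos}: logR must be finite")
        if self.logOR is not None and not np.isfinite(self.logOR):
            raise ValueError(
                f"{self.chrom}:{self.pos}: logOR must be finite or missing"
            )


@dataclass(frozen=True)
class GlobalParams:
    """Global (non-chain) parameters of the emission model.

    Attributes
    ----------
    purity : float
        Tumor cell fraction alpha, in (0, 1].
    ploidy : float
        Average tumor copy number psi, > 0.
    logR_scale2 : float
        Squared scale of the logR noise: kappa^2 for the t family (the t
        variance is ``logR_scale2 * df / (df - 2)``), sigma^2 for the normal.
    logOR_scale2 : float
        Variance tau^2 of the logOR noise at heterozygous loci.
    df : float
        Degrees of freedom v of the t family; ignored by the normal family.
    family : {"t", "normal"}
    """

    purity: float
    ploidy: float
    logR_scale2: float
    logOR_scale2: float
    df: float = 5.0
    family: Literal["t", "normal"] = "t"

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0.0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")
        if self.logR_scale2 <= 0.0 or self.logOR_scale2 <= 0.0:
            raise ValueError("variance components must be strictly positive")
        if self.family not in ("t", "normal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "t" and self.df <= 2.0:
            raise ValueError(
                f"t degrees of freedom must exceed 2 (finite variance), got {self.df}"
            )

    @property
    def n_global(self) -> int:
        """Number of free global parameters (5 for t, 4 for normal)."""
        return 5 if self.family == "t" else 4


def log_density_logR_t(w, mu, scale2: float, df: float):
    """Log density of a location-scale Student-t at ``w``.

    Closed form of the normal-gamma scale mixture: a N(mu, scale2/u) density
    with u ~ Gamma(df/2, rate df/2) integrated over u.
    """
    if scale2 <= 0.0:
        raise ValueError(f"scale2 must be positive, got {scale2}")
    if df <= 0.0:
        raise ValueError(f"df must be positive, got {df}")
    w = np.asarray(w, dtype=float)
    z2 = (w - mu) ** 2 / scale2
    return (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi * scale2)
        - 0.5 * (df + 1.0) * np.log1p(z2 / df)
    )


def log_density_logR_norm(w, mu, var: float):
    """Normal log density with mean ``mu`` and variance ``var``."""
    if var <= 0.0:
        raise ValueError(f"var must be positive, got {var}")
    w = np.asarray(w, dtype=float)
    return -_HALF_LOG_2PI - 0.5 * np.log(var) - 0.5 * (w - mu) ** 2 / var


def _log_cosh(z):
    # log(cosh(z)) without overflow for large z
    z = np.abs(z)
    return z + np.log1p(np.exp(-2.0 * z)) - np.log(2.0)


def log_density_logOR_sq(x2, zeta, tau2: float):
    """Log density of the observed squared logOR.

    Model: ``x2 / tau2`` follows a noncentral chi-square with 1 degree of
    freedom and noncentrality ``zeta**2 / tau2``; the returned value includes
    the ``-log(tau2)`` Jacobian of the rescaling, so it is the density of x2
    itself.  For df = 1 the noncentral chi-square density has the closed form
    ``exp(-(y + d)/2) * cosh(sqrt(d y)) / sqrt(2 pi y)`` which is smooth in
    the noncentrality d down to d = 0 (the central case).

    The density has an integrable singularity at x2 = 0; exact zeros (which
    occur with count-derived logOR) are evaluated at a small positive
    argument instead so the log-density stays finite.
    """
    if tau2 <= 0.0:
        raise ValueError(f"tau2 must be positive, got {tau2}")
    x2 = np.asarray(x2, dtype=float)
    if np.any(x2 < 0.0):
        raise ValueError("squared logOR must be nonnegative")
    y = np.maximum(x2 / tau2, 1e-10)
    delta = np.asarray(zeta, dtype=float) ** 2 / tau2
    logpdf_y = (
        -(y + delta) / 2.0
        + _log_cosh(np.sqrt(delta * y))
        - 0.5 * np.log(2.0 * np.pi * y)
    )
    return logpdf_y - np.log(tau2)


def joint_log_emission(
    obs: LocusObservation,
    state: GenotypeState,
    params: GlobalParams,
    space: StateSpace,
) -> float:
    """Joint log emission of one locus under one state.

    The logR term uses the family in ``params``; the logOR^2 term is added
    only when the locus is heterozygous.
    """
    from .state_space import expected_logOR, expected_logR

    mu = expected_logR(state, params.purity, params.ploidy, space.normal_cn)
    if params.family == "t":
        out = float(log_density_logR_t(obs.logR, mu, params.logR_scale2, params.df))
    else:
        out = float(log_density_logR_norm(obs.logR, mu, params.logR_scale2))
    if obs.is_het:
        zeta = expected_logOR(state, params.purity)
        out += float(
            log_density_logOR_sq(obs.logOR**2, zeta, params.logOR_scale2)
        )
    return out


def emission_log_matrix(
    loci: Sequence[LocusObservation] | "ObservationArrays",
    space: StateSpace,
    params: GlobalParams,
) -> np.ndarray:
    """N x J matrix of joint log emissions, floored at LOG_DENSITY_FLOOR.

    Accepts either a sequence of :class:`LocusObservation` or the packed
    :class:`ObservationArrays` used by the fitting loop.
    """
    arrays = (
        loci if isinstance(loci, ObservationArrays) else ObservationArrays.from_loci(loci)
    )
    w = arrays.logR[:, None]  # (N, 1)
    mu = np.asarray(
        expected_logR_vector(space, params.purity, params.ploidy), dtype=float
    )  # (J,)
    if params.family == "t":
        log_em = log_density_logR_t(w, mu, params.logR_scale2, params.df)
    else:
        log_em = log_density_logR_norm(w, mu, params.logR_scale2)

    if arrays.het_idx.size:
        zeta = np.asarray(expected_logOR_vector(space, params.purity), dtype=float)
        x2 = arrays.logOR_sq_het[:, None]  # (n_het, 1)
        log_em[arrays.het_idx] += log_density_logOR_sq(
            x2, zeta, params.logOR_scale2
        )
    return np.maximum(log_em, LOG_DENSITY_FLOOR)


@dataclass(frozen=True)
class ObservationArrays:
    """Column-packed observations for vectorized emission evaluation."""

    logR: np.ndarray          # (N,) float
    het_idx: np.ndarray       # indices of heterozygous loci, ascending
    logOR_sq_het: np.ndarray  # (n_het,) squared logOR at het_idx

    @classmethod
    def from_loci(cls, loci: Sequence[LocusObservation]) -> "ObservationArrays":
        logR = np.array([o.logR for o in loci], dtype=float)
        het_idx = np.array([k for k, o in enumerate(loci) if o.is_het], dtype=int)
        logOR_sq = np.array([loci[k].logOR ** 2 for k in het_idx], dtype=float)
        return cls(logR=logR, het_idx=het_idx, logOR_sq_het=logOR_sq)

    def __len__(self) -> int:
        return self.logR.shape[0]
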