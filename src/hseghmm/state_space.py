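"""Genotype hidden-state space and state-level expectations for logR and logOR.

A hidden state is an unordered allele-count pair (major, minor) written as a
string of A's and B's, e.g. ``"AAAB"`` for (3, 1); ``"0"`` denotes homozygous
deletion.  Because only the squared log odds ratio is observed, haplotype
phase is unrecoverable and labels are canonicalized so that the count of 'A'
is the larger allele count: (1, 3) and (3, 1) are the same state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenotypeState",
    "StateSpace",
    "DEFAULT_STATE_LABELS",
    "LOGR_FLOOR",
    "build_state_space",
    "expected_logR",
    "expected_logOR",
]

#: The default 12-state space, ordered by total copy number 0..5.
DEFAULT_STATE_LABELS: tuple[str, ...] = (
    "0", "A", "AA", "AB", "AAB", "AAA",
    "AAAB", "AABB", "AAAA", "AAAAB", "AAABB", "AAAAA",
)

#: Value returned by :func:`expected_logR` when the log argument is zero
#: (pure tumor, homozygous deletion); keeps downstream densities finite.
LOGR_FLOOR: float = -20.0


@dataclass(frozen=True)
class GenotypeState:
    """One hidden genotype state.

    Attributes
    ----------
    index : int
        0-based rank of the state within its :class:`StateSpace`.
    label : str
        Canonical genotype string over {A, B}, or "0" for homozygous deletion.
    total_cn : int
        Total tumor copy number of the state.
    major_cn : int
        Copy number of the more abundant allele.
    minor_cn : int
        Copy number of the less abundant allele (``major_cn >= minor_cn``).
    """

    index: int
    label: str
    total_cn: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValueError(
                f"state {self.label!r}: need major_cn >= minor_cn >= 0, "
                f"got ({self.major_cn}, {self.minor_cn})"
            )
        if self.total_cn != self.major_cn + self.minor_cn:
            raise ValueError(
                f"state {self.label!r}: total_cn {self.total_cn} != "
                f"major_cn + minor_cn = {self.major_cn + self.minor_cn}"
            )


@dataclass(frozen=True)
class StateSpace:
    """Ordered collection of genotype states plus the normal-cell copy number."""

    states: tuple[GenotypeState, ...]
    normal_cn: int = 2

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate state labels: {labels}")
        for i, s in enumerate(self.states):
            if s.index != i:
                raise ValueError("state indices must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def __getitem__(self, i: int) -> GenotypeState:
        return self.states[i]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    @property
    def total_cn(self) -> tuple[int, ...]:
        return tuple(s.total_cn for s in self.states)


def parse_genotype_label(label: str) -> tuple[int, int]:
    """Parse a genotype string into canonical (major, minor) allele counts.

    ``"0"`` parses to (0, 0).  Otherwise the label must be a non-empty string
    over {A, B}; the larger of the two letter counts is the major count.
    """
    if label == "0":
        return (0, 0)
    if not label or set(label) - {"A", "B"}:
        raise ValueError(
            f"unparseable genotype label {label!r}: expected a string over "
            "{'A','B'} or '0'"
        )
    n_a = label.count("A")
    n_b = label.count("B")
    return (max(n_a, n_b), min(n_a, n_b))


def _canonical_label(major: int, minor: int) -> str:
    return "A" * major + "B" * minor if major + minor else "0"


def build_state_space(
    labels: Iterable[str] = DEFAULT_STATE_LABELS, normal_cn: int = 2
) -> StateSpace:
    """Build a :class:`StateSpace` from genotype labels.

    Parameters
    ----------
    labels : iterable of str
        Genotype strings; defaults to the full 12-state space.
    normal_cn : int
        Copy number of contaminating normal cells (2 for autosomes).
    """
    states = []
    for i, lab in enumerate(labels):
        major, minor = parse_genotype_label(lab)
        states.append(
            GenotypeState(
                index=i,
                label=_canonical_label(major, minor),
                total_cn=major + minor,
                major_cn=major,
                minor_cn=minor,
            )
        )
    if not states:
        raise ValueError("state space must contain at least one state")
    return StateSpace(states=tuple(states), normal_cn=normal_cn)


def expected_logR(
    state: GenotypeState,
    purity: float,
    ploidy: float,
    normal_cn: int = 2,
) -> float:
    """Expected logR of a state: log2 of the purity-mixed copy number over ploidy.

    Returns ``log2(((1 - purity) * normal_cn + purity * total_cn) / ploidy)``.
    The argument of the log is zero only for a homozygous deletion in a 100%
    pure tumor; that case returns :data:`LOGR_FLOOR` instead of -inf.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if ploidy <= 0.0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    mixed = (1.0 - purity) * normal_cn + purity * state.total_cn
    if mixed <= 0.0:
        return LOGR_FLOOR
    return math.log2(mixed / ploidy)


def expected_logOR(state: GenotypeState, purity: float) -> float:
    """Expected logOR of a state: natural log of the purity-mixed allelic ratio.

    Returns ``log(((1 - purity) + purity * major) / ((1 - purity) + purity * minor))``,
    always >= 0 because major >= minor.  The 0/0 case (purity 1, total copy
    number 0) is defined as 0, the limit of the allele-balanced case.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    num = (1.0 - purity) + purity * state.major_cn
    den = (1.0 - purity) + purity * state.minor_cn
    if num == 0.0 and den == 0.0:
        return 0.0
    return math.log(num / den)


def expected_logR_vector(
    space: StateSpace, purity: float, ploidy: float
) -> "list[float]":
    """Expected logR for every state in a space (helper for vectorized code)."""
    return [expected_logR(s, purity, ploidy, space.normal_cn) for s in space]


def expected_logOR_vector(space: StateSpace, purity: float) -> "list[float]":
    """Expected logOR for every state in a space."""
    return [expected_logOR(s, purity) for s in space]
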