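"""Fixed-point combinatorics of random partner arrangements.

Pairing two families of ``M`` sequences amounts to choosing a permutation of
``M`` indices; the number of correct partners of an arrangement is the number
of fixed points of that permutation relative to the native pairing.  The
rencontres numbers ``D_{M,n}`` count permutations with exactly ``n`` fixed
points, so ``D_{M,n}/M!`` is the exact mixing weight of the ``n``-th component
of the partner-matching mixture model.  For large ``M`` these weights converge
to the Poisson distribution with unit rate.  The similar-partner reassessment
transfers weight from the correct-partner count ``n`` to the effective count
``n' = n + m`` through a binomial model in which each of the ``M - n``
mismatched sequences is independently "similar" to its assigned partner with
probability ``p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

__all__ = [
    "POISSON_CUTOVER_M",
    "RencontresTable",
    "WeightVector",
    "binomial_similarity_weight",
    "mixing_weights",
    "poisson_weight",
    "reassessed_weights",
    "rencontres_number",
    "similarity_transfer_matrix",
    "subfactorial",
]

#: Largest M for which exact rencontres weights are used by default.  Above
#: this the Poisson(1) limit is numerically indistinguishable and cheaper.
POISSON_CUTOVER_M = 50


def subfactorial(k: int) -> int:
    """Number of derangements of ``k`` elements, as an exact integer.

    Uses the recurrence ``!k = k * !(k-1) + (-1)^k`` with ``!0 = 1``.
    """
    if k < 0:
        raise ValueError(f"subfactorial undefined for negative k={k}")
    d = 1
    for i in range(1, k + 1):
        d = i * d + (-1) ** i
    return d


def rencontres_number(M: int, n: int) -> int:
    """Count of permutations of ``M`` elements with exactly ``n`` fixed points.

    ``D_{M,n} = C(M, n) * !(M - n)``: choose the fixed set, derange the rest.
    Exact (arbitrary-precision) integer arithmetic throughout; ``M!`` overflows
    64-bit integers already near ``M = 21``.
    """
    if M < 0 or n < 0:
        raise ValueError(f"M and n must be non-negative, got M={M}, n={n}")
    if n > M:
        raise ValueError(f"cannot have n={n} fixed points among M={M} elements")
    return math.comb(M, n) * subfactorial(M - n)


def poisson_weight(n: int) -> float:
    """Poisson(1) probability mass ``e^{-1} / n!``, the large-M limit of
    ``D_{M,n}/M!``."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return math.exp(-1.0) / math.factorial(n)


@dataclass(frozen=True)
class RencontresTable:
    """Exact table of rencontres numbers ``D_{M,n}`` for ``0 <= n <= M``."""

    M: int
    D: tuple[int, ...]

    @classmethod
    def build(cls, M: int) -> "RencontresTable":
        if M < 0:
            raise ValueError(f"M must be non-negative, got {M}")
        return cls(M=M, D=tuple(rencontres_number(M, n) for n in range(M + 1)))

    def __post_init__(self) -> None:
        if len(self.D) != self.M + 1:
            raise ValueError("table must have M + 1 entries")
        if sum(self.D) != math.factorial(self.M):
            raise ValueError("rencontres numbers must sum to M!")

    def weights(self) -> np.ndarray:
        """Exact mixing weights ``D_{M,n}/M!`` as floats."""
        fact = math.factorial(self.M)
        return np.array([Fraction(d, fact) for d in self.D], dtype=float)

    def mean_fixed_points(self) -> Fraction:
        """Expected number of fixed points of a uniform permutation, exactly.

        Equals 1 for every ``M >= 1``.
        """
        fact = math.factorial(self.M)
        return sum(Fraction(n * d, fact) for n, d in enumerate(self.D))


@dataclass
class WeightVector:
    """Normalized mixing weights indexed by the (effective) partner count.

    ``w[n]`` is the weight of the component with ``n`` correct partners (or
    ``n'`` effective partners in ``reassessed`` mode).
    """

    w: np.ndarray
    mode: str  # "exact-rencontres" | "poisson" | "reassessed"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1 or self.w.size < 1:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")
        total = self.w.sum()
        if total <= 0:
            raise ValueError("weights must have positive total mass")
        self.w = self.w / total

    @property
    def M(self) -> int:
        return self.w.size - 1

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"n": np.arange(self.w.size), "weight": self.w}).to_csv(
            path, sep="\t", index=False
        )


def mixing_weights(M: int, mode: str = "auto") -> WeightVector:
    """Mixing weights over the correct-partner count ``n = 0..M``.

    ``mode="auto"`` uses exact rencontres weights for ``M <= 50`` (which carry
    the true zero at ``n = M - 1``) and the Poisson(1) limit for larger ``M``.
    The Poisson weights are truncated at ``n = M`` and renormalized.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    if mode == "auto":
        mode = "exact-rencontres" if M <= POISSON_CUTOVER_M else "poisson"
    if mode == "exact-rencontres":
        return WeightVector(RencontresTable.build(M).weights(), mode)
    if mode == "poisson":
        w = np.array([poisson_weight(n) for n in range(M + 1)])
        return WeightVector(w, mode)
    raise ValueError(f"unknown weight mode {mode!r}")


def binomial_similarity_weight(m: int, M: int, n: int, p: float) -> float:
    """Probability that an arrangement with ``n`` correct partners carries
    exactly ``m`` similar partners among its ``M - n`` mismatches.

    Each mismatch is an independent Bernoulli trial with success probability
    ``p``: ``C(M-n, m) p^m (1-p)^{M-n-m}``.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if m < 0 or n < 0 or n > M:
        raise ValueError(f"invalid counts m={m}, n={n}, M={M}")
    if m > M - n:
        raise ValueError(f"m={m} similar partners exceed the M-n={M - n} mismatches")
    k = M - n
    # p**m with p == 0, m == 0 is 1.0 in float arithmetic, as required.
    return math.comb(k, m) * p**m * (1.0 - p) ** (k - m)


def similarity_transfer_matrix(M: int, p: float) -> np.ndarray:
    """Lower-triangular transfer matrix ``T[n', n] = B(n'-n; M-n, p)``.

    Applied to a weight vector over ``n`` it yields the reassessed weights over
    the effective count ``n' = n + m``; applied to component masses it spreads
    each component over the rows it contributes to.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    T = np.zeros((M + 1, M + 1))
    for n in range(M + 1):
        m = np.arange(M - n + 1)
        T[n:, n] = stats.binom.pmf(m, M - n, p)
    return T


def reassessed_weights(w: WeightVector, M: int | None = None, p: float = 0.2) -> WeightVector:
    """Reweight a mixing-weight vector by the similar-partner credit model.

    ``w'_{n'} = sum_{n + m = n'} w_n * B(m; M - n, p)``, normalized.  With
    ``p = 0`` this is the identity; with ``p = 1`` every mismatch is credited
    and all mass moves to ``n' = M``.
    """
    if M is None:
        M = w.M
    if M != w.M:
        raise ValueError(f"weight vector has M={w.M}, expected {M}")
    T = similarity_transfer_matrix(M, p)
    return WeightVector(T @ w.w, "reassessed")
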