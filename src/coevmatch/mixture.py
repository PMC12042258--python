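"""Joint mixture model of partner count and coevolutionary information.

The coevolutionary information ``I`` of an arrangement with ``n`` correct
partners is a sum of many column-pair contributions and is therefore modeled
as Gaussian, ``f_n(I) = N(I; I_n, sigma_n^2)``.  The joint density over
``{n, I}`` is the mixture ``f(n, I) = w_n f_n(I)`` with combinatorial mixing
weights ``w_n`` (rencontres / Poisson).  The component means and variances
interpolate between the scrambled ensemble (``n = 0``: mean ``I_0``, variance
``sigma_0^2``) and the native arrangement (``n = M``: mean ``I'``, variance
``0``) through the shape family

    I_n       = I_0 + alpha * (n / M)^a
    sigma_n^2 = sigma_0^2 * (1 - (n / M)^b)

with ``alpha = I' - I_0`` the information gap.  The similar-sequence
reassessment replaces the row index ``n`` by the effective count
``n' = n + m``; under the approximation ``theta_nm ~= theta_n`` each
reassessed component is the grouped finite Gaussian mixture

    w'_{n'} f_{n'}(I) = sum_{n + m = n'} w_n B(m; M - n, p) f_n(I | theta_n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .combinatorics import WeightVector, mixing_weights, similarity_transfer_matrix

__all__ = [
    "ComponentParams",
    "MixtureSpec",
    "ModelParams",
    "build_mixture",
    "component_density",
    "mean_information",
    "variance",
]

#: Shape exponents of the best fit of the input functions to the regularized
#: empirical curves of the benchmark protein families.
DEFAULT_A = 1.63
DEFAULT_B = 0.68
#: Native information content used as the fixed reference in parameter sweeps.
DEFAULT_I_PRIME = 50.0
#: Similarity probability implied by the 20th-percentile Hamming cutoff.
DEFAULT_P = 0.2


@dataclass(frozen=True)
class ModelParams:
    """Reduced parameter set ``{M, alpha, sigma0_sq, a, b, I', p}``.

    Parameters
    ----------
    M : int
        Total number of paired sequences.
    alpha : float
        Information gap ``alpha = I' - I_0`` in nats.
    sigma0_sq : float
        Variance of the scrambled (``n = 0``) ensemble in nats^2.
    a, b : float
        Shape exponents of the information and variance input functions.
    I_prime : float
        Information content of the native arrangement in nats.
    p : float
        Probability that a mismatched partner is similar to the correct one.
    """

    M: int
    alpha: float
    sigma0_sq: float
    a: float = DEFAULT_A
    b: float = DEFAULT_B
    I_prime: float = DEFAULT_I_PRIME
    p: float = DEFAULT_P

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError(f"M must be >= 2, got {self.M}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.sigma0_sq < 0:
            raise ValueError(f"sigma0_sq must be non-negative, got {self.sigma0_sq}")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("shape exponents a and b must be positive")
        if not 0 <= self.p <= 1:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")

    @property
    def I0(self) -> float:
        """Mean information of the scrambled ensemble, ``I' - alpha``."""
        return self.I_prime - self.alpha


@dataclass(frozen=True)
class ComponentParams:
    """``theta_n = {I_n, sigma_n^2}`` of the information density at fixed n."""

    n: int
    I_n: float
    sigma_n_sq: float

    def __post_init__(self) -> None:
        if self.sigma_n_sq < 0:
            raise ValueError(f"variance must be non-negative, got {self.sigma_n_sq}")


def mean_information(n: int, params: ModelParams) -> float:
    """Mean information ``I_n = I_0 + alpha (n/M)^a`` of the n-th component.

    Monotone non-decreasing in ``n`` with boundary values ``I_0`` and ``I'``.
    """
    if not 0 <= n <= params.M:
        raise ValueError(f"n={n} out of range 0..{params.M}")
    return params.I0 + params.alpha * (n / params.M) ** params.a


def variance(n: int, params: ModelParams) -> float:
    """Variance ``sigma_n^2 = sigma_0^2 (1 - (n/M)^b)`` of the n-th component.

    Non-negative, equal to ``sigma_0^2`` at ``n = 0`` and 0 at ``n = M``.
    """
    if not 0 <= n <= params.M:
        raise ValueError(f"n={n} out of range 0..{params.M}")
    return params.sigma0_sq * (1.0 - (n / params.M) ** params.b)


def component_density(I, theta: ComponentParams):
    """Gaussian density ``N(I; I_n, sigma_n^2)`` of a single component.

    Degenerate components (``sigma_n^2 = 0``) are point masses and contribute
    only through binned state masses; evaluating their density is an error.
    """
    if theta.sigma_n_sq < 0:
        raise ValueError("negative variance")
    if theta.sigma_n_sq == 0:
        raise ValueError(
            "degenerate component (sigma_n^2 = 0) has no density; "
            "its mass is assigned to the information bin containing I_n"
        )
    return stats.norm.pdf(I, loc=theta.I_n, scale=np.sqrt(theta.sigma_n_sq))


@dataclass
class MixtureSpec:
    """A fully specified ``{n, I}`` mixture, plain or reassessed.

    ``mixing[j, n]`` is the mass that the underlying Gaussian component
    ``theta_n`` contributes to row ``j`` of the model.  In the plain model
    ``mixing = diag(w)`` (row index = correct-partner count ``n``); in the
    reassessed model ``mixing[j, n] = w_n B(j - n; M - n, p)`` (row index =
    effective count ``n'``).  Row sums give the (reassessed) mixing weights.
    """

    params: ModelParams
    weights: WeightVector
    components: list[ComponentParams]
    reassessed: bool = False
    mixing: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        M = self.params.M
        if len(self.components) != M + 1:
            raise ValueError("mixture must have M + 1 components")
        if self.mixing is None:
            self.mixing = np.diag(self.weights.w)
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (M + 1, M + 1):
            raise ValueError("mixing matrix must be (M+1, M+1)")

    @property
    def M(self) -> int:
        return self.params.M

    def row_weights(self) -> np.ndarray:
        """Total weight per row index (``w_n`` or reassessed ``w_{n'}``)."""
        return self.mixing.sum(axis=1)

    def pdf(self, I) -> np.ndarray:
        """Total mixture density at information ``I``.

        Point-mass components (``sigma_n^2 = 0``) are omitted; their weight is
        only representable through binned masses.
        """
        I = np.asarray(I, dtype=float)
        out = np.zeros_like(I)
        col_weight = self.mixing.sum(axis=0)
        for theta, w in zip(self.components, col_weight):
            if w > 0 and theta.sigma_n_sq > 0:
                out = out + w * component_density(I, theta)
        return out


def build_mixture(
    params: ModelParams, reassess: bool = False, weight_mode: str = "auto"
) -> MixtureSpec:
    """Assemble the mixture model from the reduced parameter set.

    With ``reassess=True`` the mixing weights are redistributed along the
    effective-count axis by the binomial similar-partner model at the
    similarity probability ``params.p``; each reassessed row is the grouped
    Gaussian mixture implied by ``theta_nm ~= theta_n``.
    """
    w = mixing_weights(params.M, mode=weight_mode)
    components = [
        ComponentParams(n, mean_information(n, params), variance(n, params))
        for n in range(params.M + 1)
    ]
    if reassess:
        T = similarity_transfer_matrix(params.M, params.p)
        mixing = T * w.w[np.newaxis, :]
        mixing /= mixing.sum()
        weights = WeightVector(mixing.sum(axis=1), "reassessed")
    else:
        mixing = np.diag(w.w)
        weights = w
    return MixtureSpec(
        params=params,
        weights=weights,
        components=components,
        reassessed=reassess,
        mixing=mixing,
    )
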