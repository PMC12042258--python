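"""Parameter sweeps, sweet-spot maps and family classification.

Solving the model over a lattice of information gaps ``alpha`` and scrambled
variances ``sigma_0^2`` at fixed ``M`` yields a map of predicted true-positive
rates before and after the similar-sequence reassessment.  The "sweet spot" is
the region where the predicted TP rate reaches 0.5.  Real or synthetic
families are placed on the map through the estimates ``alpha* = I* - I_0``
(optimized minus scrambled information) and ``sigma_0^2``, and classified
against the trivial-error region ``{alpha >= 15, sigma_0^2 <= 0.5}`` in which
optimized solutions carrying only clade-level (similar-sequence) errors are
predicted to reside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .markov import Trajectory, build_grid, build_transitions, most_likely_trajectory
from .mixture import DEFAULT_A, DEFAULT_B, DEFAULT_I_PRIME, ModelParams, build_mixture

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_M_VALUES",
    "DEFAULT_SIGMA0_SQ_GRID",
    "FamilyEstimate",
    "SweepResult",
    "TP_THRESHOLD",
    "TRIVIAL_ERROR_REGION",
    "classify_family",
    "estimate_alpha_star",
    "solve_tp",
    "sweep",
]

#: TP rate counted as "significant"; boundary of the sweet spot.
TP_THRESHOLD = 0.5

#: Trivial-error region of the parameter space (boundary inclusive).
TRIVIAL_ERROR_REGION = {"alpha_min": 15.0, "sigma0_sq_max": 0.5}

#: Default sweep lattice spanning the model's parameter space at I' = 50.
DEFAULT_ALPHA_GRID = tuple(np.arange(5.0, 50.0 + 1e-9, 2.5))
DEFAULT_SIGMA0_SQ_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)
DEFAULT_M_VALUES = (10, 20, 30, 100)


def solve_tp(
    params: ModelParams,
    reassess: bool = False,
    k: int | None = None,
    floor: float | None = None,
    weight_mode: str = "auto",
) -> Trajectory:
    """Build the mixture, discretize, and solve the most likely trajectory."""
    mix = build_mixture(params, reassess=reassess, weight_mode=weight_mode)
    grid = build_grid(mix, k=k)
    tm = build_transitions(grid, floor=floor)
    return most_likely_trajectory(tm)


@dataclass
class SweepResult:
    """TP-rate surfaces over an ``(alpha, sigma_0^2)`` lattice at fixed M."""

    M: int
    alpha_grid: np.ndarray
    sigma0_sq_grid: np.ndarray
    tp: np.ndarray
    tp_reassessed: np.ndarray | None = None
    p: float = 0.2

    def __post_init__(self) -> None:
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        self.sigma0_sq_grid = np.asarray(self.sigma0_sq_grid, dtype=float)
        shape = (self.alpha_grid.size, self.sigma0_sq_grid.size)
        self.tp = np.asarray(self.tp, dtype=float)
        if self.tp.shape != shape:
            raise ValueError("tp surface does not match the lattice")
        if self.tp_reassessed is not None:
            self.tp_reassessed = np.asarray(self.tp_reassessed, dtype=float)
            if self.tp_reassessed.shape != shape:
                raise ValueError("reassessed surface does not match the lattice")

    @property
    def sweet_spot(self) -> np.ndarray:
        return self.tp >= TP_THRESHOLD

    @property
    def sweet_spot_reassessed(self) -> np.ndarray:
        if self.tp_reassessed is None:
            raise ValueError("sweep was run without reassessment")
        return self.tp_reassessed >= TP_THRESHOLD

    def to_dataframe(self):
        import pandas as pd

        A, S = np.meshgrid(self.alpha_grid, self.sigma0_sq_grid, indexing="ij")
        data = {
            "M": self.M,
            "alpha": A.ravel(),
            "sigma0_sq": S.ravel(),
            "tp": self.tp.ravel(),
        }
        if self.tp_reassessed is not None:
            data["tp_reassessed"] = self.tp_reassessed.ravel()
        return pd.DataFrame(data)


def sweep(
    M: int,
    alpha_grid=DEFAULT_ALPHA_GRID,
    sigma0_sq_grid=DEFAULT_SIGMA0_SQ_GRID,
    reassess: bool = False,
    p: float = 0.2,
    a: float = DEFAULT_A,
    b: float = DEFAULT_B,
    I_prime: float = DEFAULT_I_PRIME,
    k: int | None = None,
    floor: float | None = None,
    weight_mode: str = "auto",
) -> SweepResult:
    """Predict TP rates over the ``(alpha, sigma_0^2)`` lattice at fixed M.

    Every lattice point runs the full deterministic pipeline
    ``build_mixture -> build_grid -> build_transitions ->
    most_likely_trajectory``.  With ``reassess=True`` the reassessed surface
    is computed alongside the plain one.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    sigma0_sq_grid = np.asarray(sigma0_sq_grid, dtype=float)
    if alpha_grid.size == 0 or sigma0_sq_grid.size == 0:
        raise ValueError("sweep lattice must be non-empty")
    tp = np.zeros((alpha_grid.size, sigma0_sq_grid.size))
    tpr = np.zeros_like(tp) if reassess else None
    for i, alpha in enumerate(alpha_grid):
        for j, s0 in enumerate(sigma0_sq_grid):
            params = ModelParams(
                M=M, alpha=alpha, sigma0_sq=s0, a=a, b=b, I_prime=I_prime, p=p
            )
            tp[i, j] = solve_tp(
                params, reassess=False, k=k, floor=floor, weight_mode=weight_mode
            ).tp_rate
            if reassess:
                tpr[i, j] = solve_tp(
                    params, reassess=True, k=k, floor=floor, weight_mode=weight_mode
                ).tp_rate
    return SweepResult(
        M=M,
        alpha_grid=alpha_grid,
        sigma0_sq_grid=sigma0_sq_grid,
        tp=tp,
        tp_reassessed=tpr,
        p=p,
    )


def estimate_alpha_star(I_star: float, I0: float) -> float:
    """Observed information gap ``alpha* = I* - I_0`` from an optimized run.

    ``I*`` below ``I_0`` (optimization worse than scrambled) is clamped to a
    zero gap with a warning.
    """
    if I_star < I0:
        warnings.warn(
            f"optimized information I*={I_star} below scrambled mean I0={I0}; "
            "clamping alpha* to 0",
            stacklevel=2,
        )
        return 0.0
    return float(I_star - I0)


@dataclass(frozen=True)
class FamilyEstimate:
    """Placement of a family on the ``{alpha, sigma_0^2}`` map."""

    alpha_star: float
    sigma0_sq: float
    I0: float = float("nan")
    I_star: float = float("nan")

    def __post_init__(self) -> None:
        if self.alpha_star < 0:
            raise ValueError("alpha_star must be non-negative")
        if self.sigma0_sq < 0:
            raise ValueError("sigma0_sq must be non-negative")

    @classmethod
    def from_information(
        cls, I_star: float, I0: float, sigma0_sq: float
    ) -> "FamilyEstimate":
        return cls(
            alpha_star=estimate_alpha_star(I_star, I0),
            sigma0_sq=sigma0_sq,
            I0=I0,
            I_star=I_star,
        )


def classify_family(
    est: FamilyEstimate,
    alpha_min: float = TRIVIAL_ERROR_REGION["alpha_min"],
    sigma0_sq_max: float = TRIVIAL_ERROR_REGION["sigma0_sq_max"],
) -> str:
    """Classify a family against the trivial-error region.

    Returns ``"inside"`` iff ``alpha* >= 15`` and ``sigma_0^2 <= 0.5``
    (boundaries inclusive): families inside the region are predicted to have
    partners resolvable at the clade level once trivial errors are forgiven.
    """
    inside = est.alpha_star >= alpha_min and est.sigma0_sq <= sigma0_sq_max
    return "inside" if inside else "outside"
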