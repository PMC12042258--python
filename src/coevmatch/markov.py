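"""Discretized Markov dynamics of information maximization.

The information domain ``[I_0, I']`` is tiled into ``k`` bins (``k = M`` by
default), turning the ``{n, I}`` mixture into a finite set of states
``c = (n, bin)`` with masses ``P(c)`` obtained as CDF differences of the
weighted components across each bin.  An information-maximizing optimizer that
swaps two sequences per step induces transitions with strictly increasing
information and ``n`` changing by at most one; the transition probability into
an allowed successor is its state mass normalized over the successor set
(a right-stochastic, reducible matrix).  States whose successor set is empty
are absorbing.  The most likely trajectory from the maximum-mass initial state
maximizes the product of transition probabilities over the increasing-I DAG;
the model's predicted true-positive rate is ``n/M`` at its absorbing endpoint.

States with mass below a configurable floor are treated as unreachable.  The
default floor of zero makes double-precision arithmetic itself the resolution
limit: a state whose binned mass underflows to zero cannot receive a finite
transition probability, which is what confines the absorbing state of the
most likely trajectory at large ``M``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mixture import MixtureSpec

__all__ = [
    "StateGrid",
    "Trajectory",
    "TransitionModel",
    "build_grid",
    "build_transitions",
    "most_likely_trajectory",
    "tp_rate",
]

#: Default reachability floor: strictly positive double-precision mass.
DEFAULT_FLOOR = 0.0


@dataclass
class StateGrid:
    """Binned state masses ``P(n, bin)`` over the information domain.

    ``mass[j, b]`` is the probability of the state with partner-count index
    ``j`` (``n``, or ``n'`` for a reassessed mixture) and information bin
    ``b``.  Bins are half-open ``[edge_b, edge_{b+1})`` except the last, which
    is closed so the tiling covers ``[I_0, I']`` exactly.
    """

    edges: np.ndarray
    mass: np.ndarray
    reassessed: bool = False

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.edges.ndim != 1 or self.edges.size < 3:
            raise ValueError("grid needs at least 2 bins")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.mass.ndim != 2 or self.mass.shape[1] != self.edges.size - 1:
            raise ValueError("mass must be (rows, k) matching the bin edges")
        if np.any(self.mass < 0):
            raise ValueError("state masses must be non-negative")

    @property
    def k(self) -> int:
        return self.edges.size - 1

    @property
    def n_rows(self) -> int:
        return self.mass.shape[0]

    @property
    def delta_I(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows, cols = np.nonzero(np.ones_like(self.mass, dtype=bool))
        pd.DataFrame(
            {
                "n": rows,
                "I_bin_center": self.centers[cols],
                "mass": self.mass[rows, cols],
            }
        ).to_csv(path, sep="\t", index=False)


def build_grid(mix: MixtureSpec, k: int | None = None) -> StateGrid:
    """Discretize a mixture into state masses via CDF differences.

    The domain ``[I_0, I']`` is split into ``k`` equal bins (default
    ``k = M``).  Each Gaussian component contributes the difference of its CDF
    across every bin; degenerate components (``sigma_n^2 = 0``) put all their
    mass into the bin containing their mean.  The component masses are mixed
    through ``mix.mixing`` and the result is renormalized to unit total mass
    (tails of the component Gaussians extend beyond the information domain).
    """
    params = mix.params
    if k is None:
        k = params.M
    if k < 2:
        raise ValueError(f"need at least 2 information bins, got k={k}")
    edges = np.linspace(params.I0, params.I_prime, k + 1)
    M = params.M
    C = np.zeros((M + 1, k))
    for theta in mix.components:
        if theta.sigma_n_sq > 0:
            cdf = stats.norm.cdf(edges, loc=theta.I_n, scale=np.sqrt(theta.sigma_n_sq))
            C[theta.n] = np.diff(cdf)
        else:
            b = int(np.searchsorted(edges, theta.I_n, side="right") - 1)
            C[theta.n, min(max(b, 0), k - 1)] = 1.0
    mass = mix.mixing @ C
    total = mass.sum()
    if total <= 0:
        raise ValueError("grid received no probability mass")
    mass /= total
    return StateGrid(edges=edges, mass=mass, reassessed=mix.reassessed)


@dataclass
class TransitionModel:
    """Right-stochastic transition structure over a state grid.

    From state ``(j, b)`` the allowed successors are the states with a
    strictly higher information bin, row within ``j +- 1`` and mass above the
    floor; each receives probability proportional to its mass.  States with no
    allowed successor are absorbing.
    """

    grid: StateGrid
    floor: float
    reachable: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.floor < 0:
            raise ValueError("floor must be non-negative")
        self.reachable = self.grid.mass > self.floor

    def successors(self, j: int, b: int) -> list[tuple[tuple[int, int], float]]:
        """Allowed transitions out of state ``(j, b)`` with probabilities."""
        P = self.grid.mass
        rows = range(max(j - 1, 0), min(j + 1, self.grid.n_rows - 1) + 1)
        cand = [
            ((j2, b2), P[j2, b2])
            for j2 in rows
            for b2 in range(b + 1, self.grid.k)
            if self.reachable[j2, b2]
        ]
        total = sum(m for _, m in cand)
        if total <= 0:
            return []
        return [(state, m / total) for state, m in cand]

    def is_absorbing(self, j: int, b: int) -> bool:
        return len(self.successors(j, b)) == 0


def build_transitions(
    grid: StateGrid,
    floor: float | None = None,
) -> TransitionModel:
    """Build the transition model over a state grid.

    ``floor`` (default 0) sets the smallest state mass treated as reachable;
    the default admits every state whose mass does not underflow to zero, so
    double precision itself is the numerical-resolution limit.
    """
    if floor is None:
        floor = DEFAULT_FLOOR
    return TransitionModel(grid=grid, floor=floor)


@dataclass
class Trajectory:
    """Most likely optimization path through the state grid.

    ``states`` holds ``(row, bin)`` pairs from the initial state ``c_0`` to
    the absorbing endpoint; ``tp_rate`` is the fraction of correct (or, on a
    reassessed grid, effective) partners at the endpoint.
    """

    states: list[tuple[int, int]]
    log_prob: float
    tp_rate: float

    @property
    def n_final(self) -> int:
        return self.states[-1][0]

    def to_tsv(self, path, grid: StateGrid | None = None) -> None:
        import pandas as pd

        rows = [s[0] for s in self.states]
        bins = [s[1] for s in self.states]
        data = {"step": np.arange(len(rows)), "n": rows, "I_bin": bins}
        if grid is not None:
            data["I_bin_center"] = grid.centers[bins]
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def most_likely_trajectory(tm: TransitionModel) -> Trajectory:
    """Solve the most likely path from the maximum-mass state to absorption.

    Dynamic programming over the increasing-information DAG maximizes the
    product of transition probabilities.  Ties (in the choice of ``c_0`` and
    at every DP decision) are broken toward the smaller partner count, then
    the lower information bin, so the result is deterministic.
    """
    P = tm.grid.mass
    R, k = P.shape
    reach = tm.reachable
    with np.errstate(divide="ignore"):
        logP = np.where(reach, np.log(np.where(reach, P, 1.0)), -np.inf)

    V = np.zeros((R, k))
    nxt_row = np.full((R, k), -1, dtype=np.int64)
    nxt_bin = np.full((R, k), -1, dtype=np.int64)

    # Running aggregates over already-processed (higher) bins:
    #   ssum[j]  total reachable mass in row j
    #   bw[j]    best  log P + V  over reachable states in row j
    #   argb[j]  bin attaining bw[j] (lowest bin on ties)
    ssum = np.zeros(R)
    bw = np.full(R, -np.inf)
    argb = np.full(R, -1, dtype=np.int64)
    idx = np.arange(R)

    for b in range(k - 1, -1, -1):
        S = ssum.copy()
        S[1:] += ssum[:-1]
        S[:-1] += ssum[1:]

        cand = np.full((3, R), -np.inf)
        cand[0, 1:] = bw[:-1]  # row j - 1 (preferred on ties)
        cand[1] = bw
        cand[2, :-1] = bw[1:]  # row j + 1
        choice = np.argmax(cand, axis=0)  # first max -> smaller row wins ties
        best = cand[choice, idx]

        absorbing = S <= 0.0
        with np.errstate(divide="ignore"):
            V[:, b] = np.where(absorbing, 0.0, best - np.log(np.where(absorbing, 1.0, S)))
        tgt = np.clip(idx + choice - 1, 0, R - 1)
        nxt_row[:, b] = np.where(absorbing, -1, tgt)
        nxt_bin[:, b] = np.where(absorbing, -1, argb[tgt])

        upd = reach[:, b]
        ssum[upd] += P[upd, b]
        val = logP[:, b] + V[:, b]
        take = upd & (val >= bw)  # >= so the lower bin wins ties within a row
        bw[take] = val[take]
        argb[take] = b

    j0, b0 = np.unravel_index(int(np.argmax(P)), P.shape)
    states = [(int(j0), int(b0))]
    j, b = int(j0), int(b0)
    while nxt_row[j, b] >= 0:
        j, b = int(nxt_row[j, b]), int(nxt_bin[j, b])
        states.append((j, b))
    M = R - 1
    return Trajectory(
        states=states, log_prob=float(V[j0, b0]), tp_rate=states[-1][0] / M
    )


def tp_rate(traj: Trajectory, M: int) -> float:
    """True-positive rate ``n/M`` at the trajectory's absorbing state."""
    return traj.n_final / M
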