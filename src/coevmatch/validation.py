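"""Empirical checks of the similar-partner reassessment assumptions.

The reassessed mixture rests on two approximations: the information
distribution of arrangements with ``n`` correct and ``m`` similar partners is
close to that of all arrangements with ``n`` correct partners
(``theta_nm ~= theta_n``), and the number of similar partners at fixed ``n``
follows a binomial law ``B(m; M - n, p)``.  Both are tested here by
constrained scrambling of a (synthetic) paired family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import (
    PairedAlignment,
    SimilarityModel,
    count_effective,
    mutual_information,
    sample_arrangement,
)

__all__ = ["ThetaNMCell", "ThetaNMTable", "m_distribution_check", "theta_nm_study"]

#: Default upper bound on n: Poisson weights are negligible beyond this.
DEFAULT_N_MAX = 16
#: Cells sampled fewer times than this are flagged low-confidence.
LOW_CONFIDENCE_COUNT = 30


@dataclass
class ThetaNMCell:
    """Information statistics of arrangements with ``n`` correct and ``m``
    similar partners."""

    n: int
    m: int
    count: int
    mean: float
    var: float
    deviation: float  # cell mean minus the marginal theta_n mean

    @property
    def low_confidence(self) -> bool:
        return self.count < LOW_CONFIDENCE_COUNT


@dataclass
class ThetaNMTable:
    """Table of ``theta_nm`` cells plus the marginal ``theta_n`` statistics."""

    M: int
    cells: dict[tuple[int, int], ThetaNMCell]
    theta_n: dict[int, tuple[float, float]]  # n -> (mean, var)
    m_samples: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "n": c.n,
                    "m": c.m,
                    "count": c.count,
                    "mean": c.mean,
                    "variance": c.var,
                    "deviation": c.deviation,
                    "low_confidence": c.low_confidence,
                }
                for c in sorted(self.cells.values(), key=lambda c: (c.n, c.m))
            ]
        )


def theta_nm_study(
    pa: PairedAlignment,
    n_max: int = DEFAULT_N_MAX,
    n_samples: int = 10_000,
    seed: int = 0,
    sim: SimilarityModel | None = None,
    column_pairs: np.ndarray | None = None,
) -> ThetaNMTable:
    """Sample arrangements per ``n`` and bin them by similar-partner count.

    For every ``0 <= n <= n_max`` (skipping the impossible ``M - 1``) draws
    ``n_samples`` arrangements with exactly ``n`` correct partners, splits
    them by ``m = n' - n``, and records each cell's information mean and
    variance together with its deviation from the marginal ``theta_n``.
    Cells never sampled are absent from the table (missing, not zero).
    """
    if n_max > pa.M:
        raise ValueError(f"n_max={n_max} exceeds M={pa.M}")
    if sim is None:
        sim = SimilarityModel.from_alignment(pa)
    rng = np.random.default_rng(seed)
    cells: dict[tuple[int, int], ThetaNMCell] = {}
    theta_n: dict[int, tuple[float, float]] = {}
    m_samples: dict[int, np.ndarray] = {}
    for n in range(0, n_max + 1):
        if n == pa.M - 1:
            continue
        Is = np.empty(n_samples)
        ms = np.empty(n_samples, dtype=np.int64)
        for s in range(n_samples):
            arr = sample_arrangement(pa.M, n, rng)
            Is[s] = mutual_information(pa, arr, column_pairs)
            ms[s] = count_effective(arr, sim, pa) - n
        if np.any(ms > pa.M - n):
            raise AssertionError("similar-partner count exceeded M - n")
        theta_n[n] = (float(Is.mean()), float(Is.var()))
        m_samples[n] = ms
        for m in np.unique(ms):
            sel = ms == m
            cells[(n, int(m))] = ThetaNMCell(
                n=n,
                m=int(m),
                count=int(sel.sum()),
                mean=float(Is[sel].mean()),
                var=float(Is[sel].var()),
                deviation=float(Is[sel].mean() - Is.mean()),
            )
    return ThetaNMTable(M=pa.M, cells=cells, theta_n=theta_n, m_samples=m_samples)


def m_distribution_check(table: ThetaNMTable, p_hat: float):
    """Compare the sampled ``m`` distribution at each ``n`` with the binomial
    similar-partner model.

    Returns a DataFrame with one row per ``n`` holding the total-variation
    distance between the empirical distribution of ``m`` and
    ``Binomial(M - n, p_hat)``.
    """
    import pandas as pd

    if not table.m_samples:
        raise ValueError("table holds no m samples")
    rows = []
    for n, ms in sorted(table.m_samples.items()):
        k = table.M - n
        support = np.arange(k + 1)
        emp = np.bincount(ms, minlength=k + 1)[: k + 1] / ms.size
        model = stats.binom.pmf(support, k, p_hat)
        rows.append(
            {
                "n": n,
                "n_samples": ms.size,
                "tv_distance": 0.5 * float(np.abs(emp - model).sum()),
                "m_mean": float(ms.mean()),
                "m_mean_model": k * p_hat,
            }
        )
    return pd.DataFrame(rows)
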