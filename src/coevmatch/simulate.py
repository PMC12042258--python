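"""Synthetic paired alignments and the empirical partner-matching machinery.

This module provides everything the model is validated against: a generator
of paired multiple sequence alignments with planted inter-family column
couplings and cluster (similar-sequence) structure; plug-in Shannon mutual
information of an arrangement; uniform sampling of arrangements with a fixed
number of correct partners; empirical estimation of the per-``n`` information
mean and variance ``theta_n``; least-squares fitting of the model's input
functions; Hamming-percentile similarity; and the greedy swap optimizer that
maximizes the coevolutionary information from scrambled starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import xlogy

from .mixture import ModelParams, mean_information, variance
from .phase import FamilyEstimate

__all__ = [
    "AMINO_ACIDS",
    "Arrangement",
    "EmpiricalCurve",
    "FitResult",
    "OptimizationRun",
    "OptimizationResult",
    "PairedAlignment",
    "SimilarityModel",
    "count_effective",
    "empirical_theta",
    "estimate_family",
    "fit_input_functions",
    "generate_paired_msa",
    "mutual_information",
    "optimize_information",
    "sample_arrangement",
    "scrambled_ensemble",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP  # gap treated as a 21st symbol
N_SYMBOLS = len(ALPHABET)
_CODE = {c: i for i, c in enumerate(ALPHABET)}

#: Ensemble sizes used for the empirical curves and the scrambled ensemble.
DEFAULT_CURVE_SAMPLES = 10_000
DEFAULT_SCRAMBLE_SAMPLES = 5_000
#: Number of independent optimizer runs averaged for TP estimates.
DEFAULT_N_RUNS = 10


def _encode(seqs: list[str]) -> np.ndarray:
    try:
        return np.array([[_CODE[c] for c in s] for s in seqs], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"symbol {exc} not in the amino-acid alphabet") from exc


def _decode(codes: np.ndarray) -> list[str]:
    return ["".join(ALPHABET[c] for c in row) for row in codes]


@dataclass
class PairedAlignment:
    """Two row-aligned families of sequences with a native identity pairing.

    ``seqs_A`` and ``seqs_B`` are integer-coded ``(M, N)`` arrays over the
    20 amino acids plus gap.  Row ``i`` of A natively interacts with row ``i``
    of B; an :class:`Arrangement` re-pairs the rows.  ``coupled_pairs`` lists
    the planted ``(A column, B column)`` couplings of a synthetic family, when
    known.
    """

    seqs_A: np.ndarray
    seqs_B: np.ndarray
    ids_A: list[str] | None = None
    ids_B: list[str] | None = None
    coupled_pairs: np.ndarray | None = None
    label: str = "synthetic"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.seqs_A = np.asarray(self.seqs_A, dtype=np.uint8)
        self.seqs_B = np.asarray(self.seqs_B, dtype=np.uint8)
        if self.seqs_A.ndim != 2 or self.seqs_B.ndim != 2:
            raise ValueError("alignments must be 2-D (sequences x columns)")
        if self.seqs_A.shape[0] != self.seqs_B.shape[0]:
            raise ValueError("families A and B must have equal row counts")
        if self.seqs_A.shape[1] == 0 or self.seqs_B.shape[1] == 0:
            raise ValueError("alignments must not contain empty sequences")
        if self.seqs_A.max(initial=0) >= N_SYMBOLS or self.seqs_B.max(initial=0) >= N_SYMBOLS:
            raise ValueError("sequence codes exceed the 21-symbol alphabet")
        if self.ids_A is None:
            self.ids_A = [f"A_{i}" for i in range(self.M)]
        if self.ids_B is None:
            self.ids_B = [f"B_{i}" for i in range(self.M)]

    @property
    def M(self) -> int:
        return self.seqs_A.shape[0]

    @property
    def N_A(self) -> int:
        return self.seqs_A.shape[1]

    @property
    def N_B(self) -> int:
        return self.seqs_B.shape[1]

    # -- cached one-hot encodings and column entropies ----------------------

    def _onehot(self, which: str) -> np.ndarray:
        key = f"onehot_{which}"
        if key not in self._cache:
            codes = self.seqs_A if which == "A" else self.seqs_B
            M, N = codes.shape
            oh = np.zeros((M, N, N_SYMBOLS))
            oh[np.arange(M)[:, None], np.arange(N)[None, :], codes] = 1.0
            self._cache[key] = oh.reshape(M, N * N_SYMBOLS)
        return self._cache[key]

    def _column_entropies(self, which: str) -> np.ndarray:
        key = f"H_{which}"
        if key not in self._cache:
            codes = self.seqs_A if which == "A" else self.seqs_B
            M, N = codes.shape
            H = np.empty(N)
            for j in range(N):
                counts = np.bincount(codes[:, j], minlength=N_SYMBOLS)
                pj = counts / M
                H[j] = -xlogy(pj, pj).sum()
            self._cache[key] = H
        return self._cache[key]

    # -- FASTA / TSV round trip ---------------------------------------------

    def to_fasta(self, path_a, path_b) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        for path, ids, codes in (
            (path_a, self.ids_A, self.seqs_A),
            (path_b, self.ids_B, self.seqs_B),
        ):
            records = [
                SeqRecord(Seq(s), id=i, description="")
                for i, s in zip(ids, _decode(codes))
            ]
            SeqIO.write(records, str(path), "fasta")

    def mapping_frame(self):
        import pandas as pd

        return pd.DataFrame({"id_A": self.ids_A, "id_B": self.ids_B})

    @classmethod
    def from_fasta(cls, path_a, path_b, mapping=None, label: str | None = None):
        """Load a paired alignment; ``mapping`` (a TSV with columns ``id_A``,
        ``id_B``) reorders family B so the native pairing is the identity."""
        from Bio import SeqIO

        rec_a = list(SeqIO.parse(str(path_a), "fasta"))
        rec_b = list(SeqIO.parse(str(path_b), "fasta"))
        ids_a = [r.id for r in rec_a]
        ids_b = [r.id for r in rec_b]
        seqs_b = {r.id: str(r.seq).upper() for r in rec_b}
        if mapping is not None:
            import pandas as pd

            mp = pd.read_csv(mapping, sep="\t")
            pair = dict(zip(mp["id_A"], mp["id_B"]))
            order = [pair[i] for i in ids_a]
        else:
            order = ids_b
        return cls(
            seqs_A=_encode([str(r.seq).upper() for r in rec_a]),
            seqs_B=_encode([seqs_b[i] for i in order]),
            ids_A=ids_a,
            ids_B=order,
            label=label or Path(str(path_a)).stem,
        )


@dataclass
class Arrangement:
    """A pairing of the two families: row ``i`` of A with row ``perm[i]`` of B."""

    perm: np.ndarray
    I: float | None = None

    def __post_init__(self) -> None:
        self.perm = np.asarray(self.perm, dtype=np.int64)
        M = self.perm.size
        if not np.array_equal(np.sort(self.perm), np.arange(M)):
            raise ValueError("perm must be a permutation of 0..M-1")

    @property
    def M(self) -> int:
        return self.perm.size

    @property
    def n(self) -> int:
        """Number of correct partners (fixed points relative to the native
        identity pairing)."""
        return int(np.sum(self.perm == np.arange(self.M)))

    @classmethod
    def native(cls, M: int) -> "Arrangement":
        return cls(np.arange(M))


def generate_paired_msa(
    M: int,
    N: int,
    coupling: float = 0.9,
    n_clusters: int | None = None,
    noise: float = 0.3,
    seed: int = 0,
    n_coupled: int | None = None,
    column_alphabet: int = 6,
) -> PairedAlignment:
    """Generate a paired alignment with planted couplings and clusters.

    Family A consists of ``n_clusters`` uniform-random founder sequences
    copied to their members and mutated per position at rate ``noise``, so
    ``n_clusters = M`` yields independent uniform sequences while small
    ``n_clusters`` creates groups of mutually similar sequences whose sizes
    control the Hamming-percentile similarity probability.  For each coupled
    column pair ``(j, j)`` a fixed random bijection of the alphabet maps the
    A symbol to the B symbol with probability ``coupling``; otherwise the B
    symbol falls back to a per-cluster background founder (itself mutated at
    rate ``noise``), which preserves the cluster structure of family B at any
    coupling.  ``coupling = 1`` makes the native arrangement the information
    maximum; ``coupling = 0`` leaves B independent of A's row identity beyond
    cluster membership.

    Alignment columns of real families are conserved: only a handful of amino
    acids occur at each position.  ``column_alphabet`` sets the number of
    symbols active per column (drawn once per column from the 20 amino
    acids); founder symbols and mutations stay within that per-column
    alphabet.

    Deterministic for a fixed ``seed``; both families have length ``N`` and
    the first ``n_coupled`` (default: all) columns are coupled.
    """
    if M < 2 or N < 2:
        raise ValueError("need at least 2 sequences of length 2")
    if not 0 <= coupling <= 1:
        raise ValueError(f"coupling must lie in [0, 1], got {coupling}")
    if not 0 <= noise <= 1:
        raise ValueError(f"noise must lie in [0, 1], got {noise}")
    if n_clusters is None:
        n_clusters = M  # independent sequences unless clustering is requested
    if not 1 <= n_clusters <= M:
        raise ValueError(f"n_clusters must lie in 1..M, got {n_clusters}")
    if n_coupled is None:
        n_coupled = N
    if not 0 <= n_coupled <= N:
        raise ValueError(f"n_coupled must lie in 0..N, got {n_coupled}")

    n_aa = len(AMINO_ACIDS)
    if not 2 <= column_alphabet <= n_aa:
        raise ValueError(f"column_alphabet must lie in 2..{n_aa}, got {column_alphabet}")
    rng = np.random.default_rng(seed)
    cluster = (np.arange(M) * n_clusters) // M  # contiguous, near-equal blocks

    # Per-column restricted alphabets (column conservation of real MSAs).
    col_symbols = np.array(
        [rng.choice(n_aa, size=column_alphabet, replace=False) for _ in range(N)]
    ).T  # (column_alphabet, N)

    def draw_symbols(shape):
        """Sample symbols column-wise from the restricted alphabets."""
        picks = rng.integers(0, column_alphabet, size=shape)
        return np.take_along_axis(
            np.broadcast_to(col_symbols[:, None, :], (column_alphabet, shape[0], N)),
            picks[None, :, :],
            axis=0,
        )[0]

    founders_a = draw_symbols((n_clusters, N))
    A = founders_a[cluster]
    mut = rng.random(size=(M, N)) < noise
    A = np.where(mut, draw_symbols((M, N)), A)

    bijections = np.array([rng.permutation(n_aa) for _ in range(N)])  # per column
    founders_b = np.take_along_axis(bijections.T, founders_a, axis=0)
    founders_b[:, n_coupled:] = draw_symbols((n_clusters, N))[:, n_coupled:]
    B_bg = founders_b[cluster]
    mut_b = rng.random(size=(M, N)) < noise
    B_bg_mut = np.take_along_axis(bijections.T, draw_symbols((M, N)), axis=0)
    B_bg = np.where(mut_b, B_bg_mut, B_bg)

    B_coupled = np.take_along_axis(bijections.T, A, axis=0)
    use_coupling = rng.random(size=(M, N)) < coupling
    use_coupling[:, n_coupled:] = False
    B = np.where(use_coupling, B_coupled, B_bg)

    pairs = np.array([(j, j) for j in range(n_coupled)], dtype=np.int64)
    return PairedAlignment(
        seqs_A=A.astype(np.uint8),
        seqs_B=B.astype(np.uint8),
        coupled_pairs=pairs if n_coupled else None,
        label=f"synthetic_M{M}_N{N}",
    )


def mutual_information(
    pa: PairedAlignment,
    arr: Arrangement | None = None,
    column_pairs: np.ndarray | None = None,
) -> float:
    """Coevolutionary information of an arrangement, in nats.

    Sums the plug-in Shannon mutual information between column ``i`` of A and
    column ``j`` of B (rows of B re-paired by the arrangement) over the
    designated inter-family column pairs; by default all ``N_A x N_B`` ordered
    pairs.  Intra-family contributions are arrangement-invariant and excluded.
    """
    perm = np.arange(pa.M) if arr is None else arr.perm
    if perm.size != pa.M:
        raise ValueError("arrangement size does not match the alignment")
    M = pa.M
    H_A = pa._column_entropies("A")
    H_B = pa._column_entropies("B")
    if column_pairs is not None:
        column_pairs = np.asarray(column_pairs, dtype=np.int64)
        ii, jj = column_pairs[:, 0], column_pairs[:, 1]
        joint = pa.seqs_A[:, ii].astype(np.int64) * N_SYMBOLS + pa.seqs_B[perm][:, jj]
        n_pairs = column_pairs.shape[0]
        counts = np.zeros((n_pairs, N_SYMBOLS * N_SYMBOLS))
        np.add.at(counts, (np.arange(n_pairs)[None, :], joint), 1.0)
        pj = counts / M
        H_joint = -xlogy(pj, pj).sum(axis=1)
        return float((H_A[ii] + H_B[jj] - H_joint).sum())
    Aoh = pa._onehot("A")
    Boh = pa._onehot("B")[perm]
    counts = (Aoh.T @ Boh).reshape(pa.N_A, N_SYMBOLS, pa.N_B, N_SYMBOLS)
    pj = counts.transpose(0, 2, 1, 3) / M  # (N_A, N_B, 21, 21)
    H_joint = -xlogy(pj, pj).sum(axis=(2, 3))
    mi = H_A[:, None] + H_B[None, :] - H_joint
    return float(mi.sum())


def _derangement(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform derangement by rejection; vacuous for ``size = 0``."""
    if size == 1:
        raise ValueError("no derangement of a single element exists")
    idx = np.arange(size)
    while True:
        perm = rng.permutation(size)
        if size == 0 or not np.any(perm == idx):
            return perm


def sample_arrangement(M: int, n: int, seed=0) -> Arrangement:
    """Uniform random arrangement with exactly ``n`` correct partners.

    Chooses the ``n`` fixed indices uniformly and applies a uniform
    derangement to the remaining ``M - n``.  ``n = M - 1`` is impossible
    (``D_{M,M-1} = 0``) and raises.
    """
    if not 0 <= n <= M:
        raise ValueError(f"n={n} out of range 0..{M}")
    if n == M - 1:
        raise ValueError("no arrangement has exactly M-1 correct partners")
    rng = np.random.default_rng(seed)
    perm = np.arange(M)
    if n < M:
        free = rng.choice(M, size=M - n, replace=False)
        free.sort()
        perm[free] = free[_derangement(rng, M - n)]
    return Arrangement(perm)


@dataclass
class EmpiricalCurve:
    """Empirical ``theta_n`` curve: mean and variance of I per partner count."""

    n_values: np.ndarray
    I_mean: np.ndarray
    I_var: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=np.int64)
        self.I_mean = np.asarray(self.I_mean, dtype=float)
        self.I_var = np.asarray(self.I_var, dtype=float)
        if not (self.n_values.size == self.I_mean.size == self.I_var.size):
            raise ValueError("curve arrays must have matching lengths")
        if np.any(self.I_var < 0):
            raise ValueError("variances must be non-negative")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"n": self.n_values, "I_mean": self.I_mean, "I_var": self.I_var}
        ).to_csv(path, sep="\t", index=False)


def empirical_theta(
    pa: PairedAlignment,
    n_values=None,
    n_samples: int = DEFAULT_CURVE_SAMPLES,
    seed: int = 0,
    column_pairs: np.ndarray | None = None,
) -> EmpiricalCurve:
    """Estimate ``theta_n = {I_n, sigma_n^2}`` by constrained scrambling.

    For each requested ``n``, draws ``n_samples`` arrangements with exactly
    ``n`` correct partners and records the mean and variance of their
    information.  ``n = M`` admits a single arrangement (the native one), so
    its variance is zero.  Defaults to all feasible ``n`` (skipping the
    impossible ``M - 1``).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples per n")
    M = pa.M
    if n_values is None:
        n_values = [n for n in range(M + 1) if n != M - 1]
    n_values = np.asarray(n_values, dtype=np.int64)
    rng = np.random.default_rng(seed)
    means = np.empty(n_values.size)
    vars_ = np.empty(n_values.size)
    for i, n in enumerate(n_values):
        if n == M:
            means[i] = mutual_information(pa, None, column_pairs)
            vars_[i] = 0.0
            continue
        vals = np.empty(n_samples)
        for s in range(n_samples):
            arr = sample_arrangement(M, int(n), rng)
            vals[s] = mutual_information(pa, arr, column_pairs)
        means[i] = vals.mean()
        vars_[i] = vals.var()
    return EmpiricalCurve(n_values, means, vars_, n_samples)


def scrambled_ensemble(
    pa: PairedAlignment,
    n_samples: int = DEFAULT_SCRAMBLE_SAMPLES,
    seed: int = 0,
    column_pairs: np.ndarray | None = None,
) -> tuple[float, float]:
    """Scrambled-ensemble information mean and variance ``{I_0, sigma_0^2}``
    from random arrangements with no correct partner."""
    curve = empirical_theta(pa, [0], n_samples=n_samples, seed=seed, column_pairs=column_pairs)
    return float(curve.I_mean[0]), float(curve.I_var[0])


@dataclass(frozen=True)
class FitResult:
    """Input-function fit: recovered parameters plus regression coefficients."""

    params: ModelParams
    r_information: float
    r_variance: float


def fit_input_functions(curve: EmpiricalCurve, M: int) -> FitResult:
    """Least-squares fit of the input functions to an empirical curve.

    Fits ``I_n = I_0 + alpha x^a`` and ``sigma_n^2 = sigma_0^2 (1 - x^b)`` in
    the regularized coordinate ``x = n / M``, returning the recovered
    ``{alpha, sigma_0^2, a, b}`` and the Pearson regression coefficient of
    each fit.
    """
    if np.unique(curve.n_values).size < 4:
        raise ValueError("need at least 4 distinct n values to fit")
    x = curve.n_values / M

    def f_info(x, I0, alpha, a):
        return I0 + alpha * np.power(x, a, where=x > 0, out=np.zeros_like(x))

    def f_var(x, s0, b):
        return s0 * (1.0 - np.power(x, b, where=x > 0, out=np.zeros_like(x)))

    span = max(curve.I_mean.max() - curve.I_mean.min(), 1e-12)
    p_info, _ = curve_fit(
        f_info,
        x,
        curve.I_mean,
        p0=[curve.I_mean.min(), span, 1.5],
        bounds=([-np.inf, 0.0, 0.05], [np.inf, np.inf, 20.0]),
        maxfev=20_000,
    )
    s0_guess = max(curve.I_var.max(), 1e-12)
    p_var, _ = curve_fit(
        f_var,
        x,
        curve.I_var,
        p0=[s0_guess, 0.7],
        bounds=([0.0, 0.05], [np.inf, 20.0]),
        maxfev=20_000,
    )

    def _pearson(y, yhat):
        if np.std(y) == 0 or np.std(yhat) == 0:
            return 1.0 if np.allclose(y, yhat) else 0.0
        return float(np.corrcoef(y, yhat)[0, 1])

    I0, alpha, a = p_info
    s0, b = p_var
    alpha = max(float(alpha), 1e-12)  # ModelParams requires a positive gap
    params = ModelParams(
        M=M,
        alpha=alpha,
        sigma0_sq=float(s0),
        a=float(a),
        b=float(b),
        I_prime=float(I0) + alpha,
    )
    return FitResult(
        params=params,
        r_information=_pearson(curve.I_mean, f_info(x, *p_info)),
        r_variance=_pearson(curve.I_var, f_var(x, *p_var)),
    )


@dataclass
class SimilarityModel:
    """Pairwise Hamming similarity of family B under a percentile cutoff.

    ``cutoff`` is the given percentile (default 20th) of the off-diagonal
    B-B Hamming distances; ``p_hat`` is the fraction of pairs within the
    cutoff, the empirical similarity probability.
    """

    distances: np.ndarray
    cutoff: float
    p_hat: float

    @classmethod
    def from_alignment(
        cls, pa: PairedAlignment, percentile: float = 20.0
    ) -> "SimilarityModel":
        B = pa.seqs_B
        dist = (B[:, None, :] != B[None, :, :]).sum(axis=2)
        iu = np.triu_indices(pa.M, k=1)
        cutoff = float(np.percentile(dist[iu], percentile))
        p_hat = float(np.mean(dist[iu] <= cutoff))
        return cls(distances=dist, cutoff=cutoff, p_hat=p_hat)


def count_effective(
    arr: Arrangement, sim: SimilarityModel, pa: PairedAlignment | None = None
) -> int:
    """Effective partner count ``n' = n + m``.

    ``m`` counts the mismatched rows whose assigned B sequence lies within the
    Hamming cutoff of the correct one.
    """
    idx = np.arange(arr.M)
    mism = arr.perm != idx
    m = int(np.sum(sim.distances[idx[mism], arr.perm[mism]] <= sim.cutoff))
    return arr.n + m


@dataclass
class OptimizationRun:
    """Accepted-step record of one greedy information-maximization run."""

    steps: list[tuple[int, int, int, float]]  # (step, n, n_eff, I)
    final: Arrangement

    @property
    def final_I(self) -> float:
        return self.steps[-1][3]

    @property
    def final_n(self) -> int:
        return self.steps[-1][1]

    @property
    def final_n_eff(self) -> int:
        return self.steps[-1][2]


@dataclass
class OptimizationResult:
    """Ensemble of independent optimizer runs with averaged TP rates."""

    runs: list[OptimizationRun]
    M: int

    @property
    def tp(self) -> float:
        """Mean final fraction of correct partners over the runs."""
        return float(np.mean([r.final_n for r in self.runs])) / self.M

    @property
    def tp_effective(self) -> float:
        """Mean final fraction of correct-or-similar partners."""
        return float(np.mean([r.final_n_eff for r in self.runs])) / self.M

    def to_dataframe(self):
        import pandas as pd

        rows = [
            (ri, step, n, n_eff, I)
            for ri, run in enumerate(self.runs)
            for step, n, n_eff, I in run.steps
        ]
        return pd.DataFrame(rows, columns=["run", "step", "n", "n_eff", "I"])


def optimize_information(
    pa: PairedAlignment,
    start: Arrangement | None = None,
    max_steps: int | None = None,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
    sim: SimilarityModel | None = None,
    column_pairs: np.ndarray | None = None,
    patience: int | None = None,
) -> OptimizationResult:
    """Greedy swap-based maximization of the coevolutionary information.

    Each run proposes a random transposition of two B assignments per step and
    accepts it iff the information strictly increases, recording
    ``(step, n, n', I)`` at every accepted step (step 0 is the start).  Runs
    start from independent scrambled arrangements (``n = 0``) unless ``start``
    is given; run ``i`` uses ``seed + i``.  A run stops after ``max_steps``
    proposals or once ``patience`` consecutive proposals were rejected.
    """
    if max_steps is None:
        max_steps = 200 * pa.M
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if patience is None:
        patience = pa.M * (pa.M - 1)
    if sim is None:
        sim = SimilarityModel.from_alignment(pa)
    M = pa.M
    runs = []
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        arr = (
            Arrangement(start.perm.copy())
            if start is not None
            else sample_arrangement(M, 0, rng)
        )
        I_cur = mutual_information(pa, arr, column_pairs)
        steps = [(0, arr.n, count_effective(arr, sim, pa), I_cur)]
        rejected = 0
        for t in range(1, max_steps + 1):
            i, j = rng.choice(M, size=2, replace=False)
            arr.perm[[i, j]] = arr.perm[[j, i]]
            I_new = mutual_information(pa, arr, column_pairs)
            if I_new > I_cur:
                I_cur = I_new
                steps.append((t, arr.n, count_effective(arr, sim, pa), I_cur))
                rejected = 0
            else:
                arr.perm[[i, j]] = arr.perm[[j, i]]  # revert
                rejected += 1
                if rejected >= patience:
                    break
        runs.append(OptimizationRun(steps=steps, final=Arrangement(arr.perm.copy(), I=I_cur)))
    return OptimizationResult(runs=runs, M=M)


def estimate_family(
    pa: PairedAlignment,
    n_scrambles: int = DEFAULT_SCRAMBLE_SAMPLES,
    n_runs: int = DEFAULT_N_RUNS,
    max_steps: int | None = None,
    seed: int = 0,
    column_pairs: np.ndarray | None = None,
) -> FamilyEstimate:
    """Place a family on the ``{alpha, sigma_0^2}`` map from simulations.

    ``{I_0, sigma_0^2}`` come from a scrambled ensemble and ``I*`` is the mean
    final information of independent optimizer runs, giving
    ``alpha* = I* - I_0``.
    """
    I0, s0 = scrambled_ensemble(pa, n_samples=n_scrambles, seed=seed, column_pairs=column_pairs)
    opt = optimize_information(
        pa, max_steps=max_steps, n_runs=n_runs, seed=seed + 1, column_pairs=column_pairs
    )
    I_star = float(np.mean([r.final_I for r in opt.runs]))
    return FamilyEstimate.from_information(I_star=I_star, I0=I0, sigma0_sq=s0)
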