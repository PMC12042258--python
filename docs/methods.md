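# Methods

## The statistical model

Two protein families *A* and *B*, each with *M* aligned sequences, can be
paired in *M*! ways.  An arrangement *r* (a permutation of the native
pairing) is characterized by its number of correct partners
*n*(*r*) ∈ {0, …, *M*} and its coevolutionary information *I*(*r*), the sum
of Shannon mutual-information contributions (in nats) between columns of the
two alignments under that pairing.  The joint distribution of {*n*, *I*} is
modeled as a mixture

f(n, I) = wₙ · N(I; Iₙ, σₙ²),

where the mixing weight wₙ = D₍M,n₎/M! is the exact fraction of permutations
with *n* fixed points (rencontres numbers), which converges to the Poisson
law with unit rate as *M* grows.  Each component is Gaussian by a
central-limit argument: *I* is a sum of many column-pair terms.

`coevmatch` uses exact integer rencontres weights for *M* ≤ 50 and the
Poisson(1) limit above (truncated at *n* = *M* and renormalized); the cutover
is configurable.  The exact weights carry the structural zero at
*n* = *M* − 1 (no permutation has exactly *M* − 1 fixed points), which caps
the reachable correct-partner count at *M* − 2 when they are used — a real
feature of permutation dynamics that the Poisson limit smooths away.

### Input functions

Component means and variances interpolate between the scrambled ensemble
(*n* = 0: mean I₀, variance σ₀²) and the native arrangement
(*n* = *M*: mean I′, variance 0):

Iₙ = I₀ + α (n/M)ᵃ,  σₙ² = σ₀² (1 − (n/M)ᵇ),

with α = I′ − I₀ the information gap.  This is the simplest smooth family
satisfying the boundary conditions with one shape exponent per curve; the
defaults a = 1.63 and b = 0.68 are the values that best fit the regularized
empirical curves of the benchmark families, and I′ = 50 nats is the fixed
native reference used in all sweeps.  Both exponents, the gap and the
variance are free parameters of `ModelParams`.

## Markov dynamics and the most likely trajectory

The information domain [I₀, I′] is tiled into *k* = *M* equal bins (so
δI = α/M, the largest width consistent with one bin per component on
average).  State masses P(c) for c = (n, bin) are the CDF differences of the
weighted components across each bin; degenerate components (σₙ² = 0, i.e.
the native one) put all their mass into the bin containing their mean (bins
are half-open, the last bin closed).  Because the Gaussian tails extend
beyond the domain, the binned masses are renormalized to unit total.

An information-maximizing optimizer that swaps two sequences per step can
change *n* by at most one while strictly increasing *I*.  Transitions out of
a state therefore lead to any state with a strictly higher information bin
and a row within ±1; each allowed successor receives probability
proportional to its mass (a right-stochastic, reducible matrix).  A state
with no allowed successor is absorbing.

The trajectory starts at the maximum-mass state (which always lies in the
scrambled region, because the combinatorial weights concentrate at small
*n*) and the most likely path to absorption is solved by dynamic programming
over the increasing-information DAG in log space.  Ties — in the initial
state and at every DP decision — are broken toward the smaller partner
count, then the lower bin, making the solution fully deterministic.  The
predicted true-positive rate is *n*/M at the absorbing endpoint.

**Reachability floor.**  A successor is admitted only if its mass exceeds a
floor, default 0: double-precision arithmetic itself is the resolution
limit, so a state whose binned mass underflows to zero is unreachable.  This
is what confines the absorbing state at large *M* — the weights wₙ decay
super-exponentially, so high-*n* states hold no representable mass — and it
reproduces the characteristic hysteresis: scrambling the native arrangement
is easy, but the most likely optimizing trajectory never returns to it.  An
explicit positive floor can be supplied to model coarser resolution; raising
it to ~10⁻¹² of the maximum mass empties the *M* = 20 sweet spot and the
*M* = 30 reassessed sweet spot, which is why the underflow default is used.

**Variance bridges the bins.**  The bin index of Iₙ is k·(n/M)ᵃ,
independent of α.  With a > 1 the low-*n* components crowd into the lowest
bins, so for vanishing σ₀² no increasing-information path exists and the
trajectory absorbs almost immediately; the climb requires component overlap,
which is why the sweet spot occupies a diagonal band in (α, σ₀²) rather than
the naive "large gap, small variance" corner.

## Reassessment of similar-sequence mismatches

A mismatch onto a partner whose B sequence lies within a Hamming-distance
cutoff (the 20th percentile of the B–B distance distribution, giving
similarity probability p ≈ 0.2) is a *trivial error*.  The effective count
n′ = n + m adds the m similar partners.  At fixed n, m is modeled as
Binomial(M − n, p), and under the approximation θₙₘ ≈ θₙ (the information of
an arrangement is insensitive to how many of its mismatches are similar)
each reassessed component is the grouped finite Gaussian mixture

w′ₙ′ fₙ′(I) = Σ₍n+m=n′₎ wₙ B(m; M−n, p) fₙ(I | θₙ).

The package implements the grouped mixture exactly (each reassessed row is a
weighted sum of the underlying Gaussians) rather than refitting a single
Gaussian per n′.  The dynamics run on the n′-indexed grid with identical
transition rules, and the reported rate is n′/M.  Both approximations are
checked empirically on synthetic families by `validation.theta_nm_study`
(per-cell means and variances against θₙ) and
`validation.m_distribution_check` (total-variation distance to the binomial
law; measured ≈ 0.03–0.06 at the default cluster constructions).

## Synthetic paired alignments

`generate_paired_msa` emulates the features of curated interolog MSAs that
the model cares about, and nothing else:

- **Column conservation.**  Each column draws from a restricted alphabet
  (`column_alphabet`, default 6 of the 20 amino acids), matching the low
  per-column diversity of real alignments.  This matters: with 20 active
  symbols per column and few sequences, plug-in MI is nearly
  permutation-invariant and the optimization landscape degenerates.
- **Planted coupling.**  Each coupled column pair (j, j) carries a fixed
  random bijection of the alphabet; the B symbol follows the bijection of
  the A symbol with probability `coupling`, else falls back to cluster
  background.  `coupling = 1` makes the native arrangement the global
  information maximum; `coupling = 0` removes the gap (α ≈ 0).
- **Clusters.**  Sequences belong to `n_clusters` founder-derived clusters
  (members mutated at rate `noise`), so similar sequences exist and the
  Hamming-percentile similarity probability is controlled by cluster sizes.
  The default `n_clusters = M` (no clustering) suits pure-coupling studies;
  cluster-heavy settings (e.g. M/6 clusters) suit the reassessment studies.

Defaults (`coupling = 0.9`, `noise = 0.3`) give a clear but imperfect
coevolutionary signal with realistic within-family divergence.  What the
generator does *not* emulate: phylogenetic correlation between columns,
alignment gaps as indels, position-specific substitution preferences, and
contact-map geometry.  Tests passing on these alignments therefore show the
machinery is correct under the model's own assumptions, not that real
families satisfy those assumptions.

**Information scoring.**  `mutual_information` sums plug-in Shannon MI over
all ordered inter-family column pairs by default (intra-family pairs are
arrangement-invariant and excluded); gaps count as a 21st symbol.  A
`column_pairs` mask restricts the sum, the analog of computing MI over
contact pairs only.  The empirical studies in the test-suite score with the
planted coupled pairs: all-pairs scoring at very small *M* buries the signal
under small-sample MI bias and creates spurious local optima.

## The swap optimizer

`optimize_information` is a greedy strict-improvement hill climb: each step
proposes a uniformly random transposition of two B assignments and accepts
it iff the information strictly increases.  Runs start from independent
scrambled arrangements (n = 0); ~10 independent runs are averaged; a run
ends after `max_steps` proposals or `patience` consecutive rejections.
Population-level machinery of a full genetic algorithm (selection,
crossover) is deliberately omitted — the swap move and the acceptance rule
are the dynamics the Markov model describes.

One honest caveat: a transposition changes *n* by −2…+2, not ±1.  The ±2
cases are exactly the repair (or creation) of a *mutually* mispaired couple,
and they are not rare in practice — measured at 2–4 % of accepted steps on
clustered synthetic families — and every successful small-*M* run must end
with such a repair, because no permutation has *M* − 1 fixed points.  The
model's ±1 transition hierarchy is therefore an approximation of the
simulated dynamics, good except at the final approach to the native
arrangement.  The optimizer reports every accepted step so the discrepancy
is observable rather than hidden.

## Problem sizes and numerical choices in the shipped checks

The test-suite estimates empirical curves with hundreds to a few thousand
arrangements per *n* (the library defaults remain 10,000 per curve point and
5,000 for the scrambled ensemble), validates the DP against exhaustive path
enumeration on 5-row × 4-bin grids, enumerates all 5! arrangements for the
optimizer oracle, and sweeps the default lattice α ∈ {5, 7.5, …, 50} ×
σ₀² ∈ {0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0} at M ∈ {10, 20, 30, 100}.
Curve fitting uses `scipy.optimize.curve_fit` with positivity bounds on the
gap, the variance and both exponents; the regression coefficient reported is
Pearson's r between data and fit.  All stochastic operations take explicit
seeds; run *i* of a multi-run procedure uses `seed + i`.

## Known limitations

- The model predicts a single most likely trajectory, not the distribution
  of optimizer outcomes; stochastic simulation of the chain is out of scope.
- At *M* = 100 the reassessed sweet spot (TP′ ≥ 0.5) is empty on the default
  lattice (maximum TP′ = 0.45): the binomial credit at p = 0.2 centers n′
  near 0.2·M and double precision cannot populate states much beyond it.
  Conclusions about trivial-error resolvability at *M* ≥ 100 are
  extrapolations from the *M* ≤ 30 maps, where the reassessed sweet spot is
  strictly broader at every *M*.
- Plug-in MI is biased upward at small sample sizes; no finite-size
  correction is applied (the model compares arrangements at fixed *M*, where
  the bias largely cancels).
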