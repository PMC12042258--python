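"""Synthetic paired alignments, information scoring and the swap optimizer."""

import itertools

import numpy as np
import pytest
from scipy import stats

from coevmatch.mixture import ModelParams, mean_information, variance
from coevmatch.simulate import (
    Arrangement,
    EmpiricalCurve,
    PairedAlignment,
    SimilarityModel,
    count_effective,
    empirical_theta,
    fit_input_functions,
    generate_paired_msa,
    mutual_information,
    optimize_information,
    sample_arrangement,
    scrambled_ensemble,
    _encode,
)


class TestGenerator:
    def test_same_seed_identical_fasta(self, tmp_path):
        pa1 = generate_paired_msa(8, 10, seed=3)
        pa2 = generate_paired_msa(8, 10, seed=3)
        for pa, tag in ((pa1, "x"), (pa2, "y")):
            pa.to_fasta(tmp_path / f"{tag}_A.fasta", tmp_path / f"{tag}_B.fasta")
        assert (tmp_path / "x_A.fasta").read_bytes() == (tmp_path / "y_A.fasta").read_bytes()
        assert (tmp_path / "x_B.fasta").read_bytes() == (tmp_path / "y_B.fasta").read_bytes()
        assert not np.array_equal(
            generate_paired_msa(8, 10, seed=4).seqs_B, pa1.seqs_B
        )

    def test_zero_coupling_gives_no_information_gap(self):
        pa = generate_paired_msa(8, 10, coupling=0.0, seed=2)
        I_native = mutual_information(pa)
        I0, _ = scrambled_ensemble(pa, n_samples=200, seed=4)
        # native and scrambled information agree within the scramble spread
        assert abs(I_native - I0) < 3.0

    def test_full_coupling_native_is_global_optimum(self):
        pa = generate_paired_msa(5, 15, coupling=1.0, noise=0.0, seed=1)
        native = mutual_information(pa)
        for perm in itertools.permutations(range(5)):
            assert mutual_information(pa, Arrangement(np.array(perm))) <= native + 1e-12

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_paired_msa(1, 10)
        with pytest.raises(ValueError):
            generate_paired_msa(5, 10, coupling=1.5)
        with pytest.raises(ValueError):
            generate_paired_msa(5, 10, n_clusters=9)
        with pytest.raises(ValueError):
            generate_paired_msa(5, 10, column_alphabet=1)

    def test_fasta_roundtrip_with_mapping(self, tmp_path):
        pa = generate_paired_msa(6, 8, seed=5)
        pa.to_fasta(tmp_path / "A.fasta", tmp_path / "B.fasta")
        pa.mapping_frame().to_csv(tmp_path / "map.tsv", sep="\t", index=False)
        back = PairedAlignment.from_fasta(
            tmp_path / "A.fasta", tmp_path / "B.fasta", mapping=tmp_path / "map.tsv"
        )
        assert np.array_equal(back.seqs_A, pa.seqs_A)
        assert np.array_equal(back.seqs_B, pa.seqs_B)


class TestMutualInformation:
    def test_constant_columns_zero(self):
        pa = PairedAlignment(_encode(["AAA", "AAA", "AAA"]), _encode(["CC", "CC", "CC"]))
        assert mutual_information(pa) == pytest.approx(0.0, abs=1e-12)

    def test_correlated_binary_columns_ln2(self):
        pa = PairedAlignment(_encode(["A", "C", "A", "C"]), _encode(["D", "E", "D", "E"]))
        assert mutual_information(pa) == pytest.approx(np.log(2))

    def test_invariant_under_symbol_relabeling(self):
        pa = generate_paired_msa(6, 8, seed=9)
        arr = sample_arrangement(6, 2, 1)
        base = mutual_information(pa, arr)
        relabeled = (pa.seqs_B + 1) % 20  # bijective recoding of every column
        pa2 = PairedAlignment(pa.seqs_A.copy(), relabeled.astype(np.uint8))
        assert mutual_information(pa2, arr) == pytest.approx(base)

    def test_native_default_equals_identity_arrangement(self):
        pa = generate_paired_msa(6, 8, seed=9)
        assert mutual_information(pa) == pytest.approx(
            mutual_information(pa, Arrangement.native(6))
        )


class TestSampleArrangement:
    def test_identity_at_n_equals_M(self):
        arr = sample_arrangement(7, 7, 0)
        assert np.array_equal(arr.perm, np.arange(7))

    def test_impossible_n(self):
        with pytest.raises(ValueError):
            sample_arrangement(7, 6, 0)
        with pytest.raises(ValueError):
            sample_arrangement(7, 8, 0)

    @pytest.mark.parametrize("n", [0, 2, 4])
    def test_exact_fixed_point_count(self, n, rng):
        for _ in range(50):
            assert sample_arrangement(8, n, rng).n == n

    def test_conditional_uniformity_chi_square(self, rng):
        """At fixed n every qualifying arrangement of M = 6 is equally likely."""
        M, n, draws = 6, 1, 60_000
        counts = {}
        for _ in range(draws):
            key = tuple(sample_arrangement(M, n, rng).perm)
            counts[key] = counts.get(key, 0) + 1
        # D_{6,1} = 264 distinct arrangements with exactly one fixed point
        assert len(counts) == 264
        chi2, pval = stats.chisquare(list(counts.values()))
        assert pval > 1e-3

    def test_mean_fixed_points_of_uniform_permutations(self, rng):
        fp = [(rng.permutation(50) == np.arange(50)).sum() for _ in range(20_000)]
        assert np.mean(fp) == pytest.approx(1.0, abs=0.05)


class TestEmpiricalTheta:
    def test_native_point_has_zero_variance(self, coupled_pa):
        curve = empirical_theta(coupled_pa, [0, 2, coupled_pa.M], n_samples=50, seed=1)
        assert curve.I_var[-1] == 0.0
        assert curve.I_mean[-1] == pytest.approx(mutual_information(coupled_pa))

    def test_information_increases_with_n_when_coupled(self, coupled_pa):
        curve = empirical_theta(
            coupled_pa, [0, 2, 3, 4, coupled_pa.M], n_samples=400, seed=2,
            column_pairs=coupled_pa.coupled_pairs,
        )
        assert np.all(np.diff(curve.I_mean) > 0)

    def test_skips_impossible_n_by_default(self, coupled_pa):
        curve = empirical_theta(coupled_pa, n_samples=5, seed=0)
        assert coupled_pa.M - 1 not in curve.n_values.tolist()


class TestFitInputFunctions:
    def test_recovers_planted_parameters_within_one_percent(self):
        planted = ModelParams(M=30, alpha=25.93, sigma0_sq=0.02, a=1.63, b=0.68)
        nv = np.array([n for n in range(31) if n != 29])
        curve = EmpiricalCurve(
            nv,
            [mean_information(n, planted) for n in nv],
            [variance(n, planted) for n in nv],
            n_samples=2,
        )
        fit = fit_input_functions(curve, 30)
        assert fit.params.alpha == pytest.approx(planted.alpha, rel=0.01)
        assert fit.params.sigma0_sq == pytest.approx(planted.sigma0_sq, rel=0.01)
        assert fit.params.a == pytest.approx(planted.a, rel=0.01)
        assert fit.params.b == pytest.approx(planted.b, rel=0.01)
        assert fit.r_information >= 0.99
        assert fit.r_variance >= 0.99

    def test_flat_curve_gives_zero_gap(self):
        nv = np.arange(0, 10)
        curve = EmpiricalCurve(nv, np.full(10, 7.0), np.full(10, 0.3), 2)
        fit = fit_input_functions(curve, 10)
        assert fit.params.alpha < 0.1

    def test_needs_at_least_four_points(self):
        curve = EmpiricalCurve([0, 1, 2], [1.0, 2.0, 3.0], [0.1, 0.1, 0.1], 2)
        with pytest.raises(ValueError):
            fit_input_functions(curve, 10)


class TestSimilarity:
    def test_percentile_cutoff_gives_expected_p_hat(self, clustered_pa):
        sim = SimilarityModel.from_alignment(clustered_pa)
        assert 0.1 <= sim.p_hat <= 0.35  # near the nominal 0.2
        assert np.all(sim.distances == sim.distances.T)
        assert np.all(np.diag(sim.distances) == 0)

    def test_identity_arrangement_counts_all(self, clustered_pa):
        sim = SimilarityModel.from_alignment(clustered_pa)
        arr = Arrangement.native(clustered_pa.M)
        assert count_effective(arr, sim, clustered_pa) == clustered_pa.M

    def test_all_identical_sequences_forgive_everything(self):
        codes = _encode(["ACDA"] * 6)
        pa = PairedAlignment(codes.copy(), codes.copy())
        sim = SimilarityModel.from_alignment(pa)
        arr = sample_arrangement(6, 0, 3)
        assert count_effective(arr, sim, pa) == 6

    def test_two_cluster_hand_count(self):
        """Worked M = 6 fixture: two tight clusters of B sequences."""
        seqs_b = ["AAAAAA", "AAAAAC", "AAAACC",  # cluster 1
                  "WWWWWW", "WWWWWY", "WWWWYY"]  # cluster 2
        pa = PairedAlignment(_encode(["ACDEFG"] * 6), _encode(seqs_b))
        sim = SimilarityModel.from_alignment(pa)
        # 20th percentile of the 15 pairwise distances -> within-cluster cutoff
        assert sim.cutoff < 6
        arr = Arrangement(np.array([1, 0, 2, 3, 5, 4]))  # swaps inside clusters
        assert arr.n == 2
        assert count_effective(arr, sim, pa) == 6
        arr2 = Arrangement(np.array([3, 4, 5, 0, 1, 2]))  # swaps across clusters
        assert count_effective(arr2, sim, pa) == 0


class TestPipelineClosure:
    def test_generate_theta_fit_classify_is_seed_stable(self, clustered_pa):
        """The generate -> empirical curve -> fit -> classify pipeline gives
        the same inside/outside verdict under independent sampling seeds."""
        from coevmatch.phase import FamilyEstimate, classify_family

        verdicts = []
        for seed in (1, 2):
            curve = empirical_theta(
                clustered_pa, [0, 4, 8, 12, 16, 20, clustered_pa.M],
                n_samples=300, seed=seed, column_pairs=clustered_pa.coupled_pairs,
            )
            fit = fit_input_functions(curve, clustered_pa.M)
            est = FamilyEstimate(
                alpha_star=fit.params.alpha, sigma0_sq=fit.params.sigma0_sq
            )
            verdicts.append(classify_family(est))
        assert verdicts[0] == verdicts[1]


class TestOptimizer:
    def test_native_start_is_stable_under_full_coupling(self, coupled_pa):
        res = optimize_information(
            coupled_pa, start=Arrangement.native(coupled_pa.M), n_runs=2,
            seed=0, max_steps=200, column_pairs=coupled_pa.coupled_pairs,
        )
        assert res.tp == 1.0
        for run in res.runs:
            assert len(run.steps) == 1  # no accepted move improves the optimum

    def test_effective_tp_never_below_tp(self, clustered_pa):
        res = optimize_information(
            clustered_pa, n_runs=3, seed=5, max_steps=800,
            column_pairs=clustered_pa.coupled_pairs,
        )
        assert res.tp_effective >= res.tp
        for run in res.runs:
            assert run.final_n_eff >= run.final_n

    def test_accepted_steps_increase_information(self, clustered_pa):
        res = optimize_information(
            clustered_pa, n_runs=2, seed=3, max_steps=500,
            column_pairs=clustered_pa.coupled_pairs,
        )
        for run in res.runs:
            Is = [s[3] for s in run.steps]
            assert np.all(np.diff(Is) > 0)

    def test_single_swap_changes_n_by_at_most_two(self, clustered_pa):
        """A transposition moves n by -2..+2; the +-2 cases are exactly the
        repair (or breakage) of a mutually mispaired couple."""
        res = optimize_information(
            clustered_pa, n_runs=4, seed=7, max_steps=1000,
            column_pairs=clustered_pa.coupled_pairs,
        )
        for run in res.runs:
            d = np.diff([s[1] for s in run.steps])
            assert np.all(np.abs(d) <= 2)

    def test_reproducible_runs(self, clustered_pa):
        kw = dict(n_runs=2, seed=9, max_steps=300, column_pairs=clustered_pa.coupled_pairs)
        a = optimize_information(clustered_pa, **kw)
        b = optimize_information(clustered_pa, **kw)
        assert [r.steps for r in a.runs] == [r.steps for r in b.runs]
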