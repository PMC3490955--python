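"""Branching-time likelihoods, model selection and rate estimators."""
import math

import numpy as np
import pytest

from sympatree import Chronogram
from sympatree.diversification import (
    BranchingTimes,
    branching_times,
    delta_aicc,
    delta_aicc_null_test,
    delta_aicc_stat,
    expected_crown_size,
    fit_birth_death,
    fit_pure_birth,
    fit_yule_2_rate,
    ltt_curve,
    ms_rate,
    posterior_rate_distribution,
    simulate_yule_tree,
)


class TestBranchingTimes:
    def test_three_tip_example(self):
        bt = branching_times(Chronogram.from_newick("((A:1,B:1):1,C:2);"))
        assert np.allclose(bt.ages, [2.0, 1.0])

    def test_four_tip_two_cherries(self):
        ch = Chronogram.from_newick("((A:1,B:1):2,(C:2,D:2):1);")
        assert np.allclose(branching_times(ch).ages, [3.0, 2.0, 1.0])

    def test_simulated_length(self):
        for seed in range(5):
            tr = simulate_yule_tree(12, 0.7, seed=seed)
            assert len(branching_times(tr)) == 11

    def test_non_ultrametric_rejected(self):
        from sympatree.chronogram import UltrametricityError

        with pytest.raises(UltrametricityError):
            Chronogram.from_newick("((A:1,B:2):1,C:2);")

    def test_invariants(self):
        with pytest.raises(ValueError):
            BranchingTimes([1.0, 2.0])  # increasing
        with pytest.raises(ValueError):
            BranchingTimes([2.0, -1.0])  # non-positive

    def test_ltt_examples(self):
        bt = BranchingTimes([2.0, 1.0])
        assert ltt_curve(bt) == [(2.0, 2), (1.0, 3)]
        bt8 = branching_times(simulate_yule_tree(8, 1.0, seed=1))
        curve = ltt_curve(bt8)
        assert curve[-1][1] == 8
        assert all(c2 > c1 for (_, c1), (_, c2) in zip(curve, curve[1:]))


class TestPureBirth:
    def test_closed_form_small_example(self):
        # intervals: 2 lineages for 1 Myr, 3 lineages for 1 Myr -> G = 5
        fit = fit_pure_birth(BranchingTimes([2.0, 1.0]))
        assert fit.params["lambda"] == pytest.approx(0.2)
        assert fit.logL == pytest.approx(math.log(0.2) - 1.0)

    def test_time_rescaling(self):
        bt = branching_times(simulate_yule_tree(10, 0.5, seed=4))
        lam = fit_pure_birth(bt).params["lambda"]
        scaled = BranchingTimes(bt.ages * 3.0)
        assert fit_pure_birth(scaled).params["lambda"] == pytest.approx(
            lam / 3.0
        )

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            fit_pure_birth(BranchingTimes([1.0]))

    def test_parameter_recovery(self):
        # median relative error <= 10% at 50 tips over 200 replicates
        errs = []
        for s in range(200):
            bt = branching_times(simulate_yule_tree(50, 0.5, seed=1000 + s))
            errs.append(abs(fit_pure_birth(bt).params["lambda"] - 0.5) / 0.5)
        assert np.median(errs) <= 0.10


class TestBirthDeath:
    def test_reduces_to_pure_birth_at_zero_extinction(self):
        bt = branching_times(simulate_yule_tree(20, 0.5, seed=7))
        bd = fit_birth_death(bt)
        pb = fit_pure_birth(bt)
        if bd.params["a"] == 0.0:
            assert bd.logL == pytest.approx(pb.logL, abs=1e-6)
        assert bd.logL >= pb.logL - 1e-9

    def test_pure_birth_truth_recovers_low_extinction(self):
        a_hats, dll, errs = [], [], []
        for s in range(200):
            bt = branching_times(simulate_yule_tree(40, 0.5, seed=s))
            bd = fit_birth_death(bt)
            pb = fit_pure_birth(bt)
            a_hats.append(bd.params["a"])
            dll.append(bd.logL - pb.logL)
            errs.append(abs(bd.params["r"] - 0.5) / 0.5)
        # on most replicates the extinction estimate collapses to zero
        at_zero = np.array(a_hats) <= 1e-6
        assert at_zero.mean() >= 0.4
        assert np.median(a_hats) <= 0.05
        assert all(d < 1e-4 for d, z in zip(dll, at_zero) if z)
        # net rate recovered within 25% median relative error
        assert np.median(errs) <= 0.25

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            fit_birth_death(BranchingTimes([2.0, 1.0]))


class TestYule2Rate:
    def test_homogeneous_data_penalised(self):
        worse = 0
        ratios = []
        for s in range(100):
            bt = branching_times(simulate_yule_tree(30, 0.5, seed=300 + s))
            y2 = fit_yule_2_rate(bt)
            pb = fit_pure_birth(bt)
            assert y2.logL >= pb.logL - 1e-9
            worse += y2.aicc > pb.aicc
            ratios.append(y2.params["lambda2"] / y2.params["lambda1"])
        assert worse >= 60
        assert 1 / 3 <= np.median(ratios) <= 3

    def test_shift_time_recovery(self):
        # 10-fold rate increase: shift time found within the two adjacent
        # branching intervals around the true change point
        ok = 0
        for s in range(100):
            rng = np.random.default_rng(10_000 + s)
            times, k, t = [], 2, 0.0
            for lam, target in ((0.15, 10), (1.5, 30)):
                while k < target:
                    t += rng.exponential(1.0 / (lam * k))
                    times.append(t)
                    k += 1
                if target == 10:
                    shift_abs = t
            t += rng.exponential(1.0 / (1.5 * k))
            ages = np.sort(t - np.array([0.0] + times))[::-1]
            true_s = t - shift_abs
            y2 = fit_yule_2_rate(BranchingTimes(ages))
            older = ages[ages > true_s + 1e-12]
            younger = ages[ages < true_s - 1e-12]
            lo = younger[1] if younger.size > 1 else 0.0
            hi = older[-2] if older.size > 1 else ages[0]
            ok += lo <= y2.params["shift_time"] <= hi
        assert ok >= 80

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            fit_yule_2_rate(BranchingTimes([3.0, 2.0, 1.0]))


class TestModelSelection:
    def test_delta_identical_models_zero(self):
        bt = branching_times(simulate_yule_tree(12, 0.5, seed=9))
        pb = fit_pure_birth(bt)
        assert delta_aicc(pb, pb) == 0.0

    def test_antisymmetry(self):
        bt = branching_times(simulate_yule_tree(12, 0.5, seed=9))
        pb, y2 = fit_pure_birth(bt), fit_yule_2_rate(bt)
        assert delta_aicc(pb, y2) == pytest.approx(-delta_aicc(y2, pb))

    def test_mismatched_data_rejected(self):
        b1 = branching_times(simulate_yule_tree(12, 0.5, seed=9))
        b2 = branching_times(simulate_yule_tree(12, 0.5, seed=10))
        with pytest.raises(ValueError):
            delta_aicc(fit_pure_birth(b1), fit_yule_2_rate(b2))

    def test_aicc_definition(self):
        bt = branching_times(simulate_yule_tree(12, 0.5, seed=9))
        f = fit_pure_birth(bt)
        n, k = len(bt), 1
        assert f.aicc == pytest.approx(
            -2 * f.logL + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        )

    def test_time_rescaling_leaves_statistic_invariant(self):
        bt = branching_times(simulate_yule_tree(20, 0.5, seed=11))
        scaled = BranchingTimes(bt.ages * 2.5)
        assert delta_aicc_stat(bt) == pytest.approx(
            delta_aicc_stat(scaled), abs=1e-6
        )
        assert fit_birth_death(scaled).params["r"] == pytest.approx(
            fit_birth_death(bt).params["r"] / 2.5, rel=1e-3
        )


class TestNullTest:
    def test_deterministic_per_seed(self):
        tr = simulate_yule_tree(12, 0.5, seed=21)
        r1 = delta_aicc_null_test(tr, 14, 12, n_sim=150, seed=3)
        r2 = delta_aicc_null_test(tr, 14, 12, n_sim=150, seed=3)
        assert r1.p == r2.p
        assert np.array_equal(r1.null_stats, r2.null_stats)

    def test_p_definition_from_null_stats(self):
        tr = simulate_yule_tree(12, 0.5, seed=21)
        r = delta_aicc_null_test(tr, 12, 12, n_sim=150, seed=3)
        count = int(np.sum(r.null_stats >= r.observed - 1e-12))
        assert r.p == pytest.approx((count + 1) / 151)
        assert 0 < r.p <= 1

    def test_invalid_counts_rejected(self):
        tr = simulate_yule_tree(12, 0.5, seed=21)
        with pytest.raises(ValueError):
            delta_aicc_null_test(tr, 10, 12, n_sim=150, seed=3)
        with pytest.raises(ValueError):
            delta_aicc_null_test(tr, 12, 11, n_sim=150, seed=3)
        with pytest.raises(ValueError):
            delta_aicc_null_test(tr, 12, 12, n_sim=50, seed=3)


class TestYuleSimulator:
    def test_two_tips_is_cherry(self):
        tr = simulate_yule_tree(2, 1.0, seed=0)
        assert tr.n_tips == 2
        assert len(tr.internal_nodes()) == 1

    def test_seed_reproducibility(self):
        assert (
            simulate_yule_tree(9, 0.8, seed=5).to_newick()
            == simulate_yule_tree(9, 0.8, seed=5).to_newick()
        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_yule_tree(5, 0.0, seed=0)

    def test_mean_crown_age_matches_independent_simulator(self):
        # crown age = sum of exponential inter-event times, 2..n lineages
        ours = np.array(
            [
                simulate_yule_tree(8, 1.0, seed=40_000 + s).crown_age
                for s in range(2000)
            ]
        )
        rng = np.random.default_rng(123)
        ks = np.arange(2, 9)
        ref = rng.exponential(1.0 / ks, size=(2000, ks.size)).sum(axis=1)
        se = math.hypot(
            ours.std() / math.sqrt(ours.size), ref.std() / math.sqrt(ref.size)
        )
        assert abs(ours.mean() - ref.mean()) <= 3 * se


class TestMagallonSanderson:
    def test_minimal_clade_zero_rate(self):
        assert ms_rate(2, 5.0, epsilon=0.0).r == 0.0

    def test_zero_extinction_closed_form(self):
        est = ms_rate(7, 2.8, epsilon=0.0)
        assert est.r == pytest.approx((math.log(7) - math.log(2)) / 2.8)
        assert est.r == pytest.approx(0.4474, abs=2e-4)

    @pytest.mark.parametrize("n", [5, 16, 120])
    @pytest.mark.parametrize("eps", [0.1, 0.5, 0.9])
    def test_inversion_consistency(self, n, eps):
        t = 7.3
        est = ms_rate(n, t, epsilon=eps)
        if est.clamped:
            # zero net diversification already over-predicts the clade size
            assert expected_crown_size(0.0, eps, t) > n
        else:
            assert expected_crown_size(est.r, eps, t) == pytest.approx(
                n, abs=1e-6
            )

    def test_higher_extinction_lowers_rate(self):
        # conditioning on survival inflates expected diversity as epsilon
        # grows, so the same observed n implies slower net diversification
        rates = [ms_rate(16, 8.0, epsilon=e).r for e in (0.0, 0.5, 0.9)]
        assert rates == sorted(rates, reverse=True)

    def test_negative_estimate_clamped_and_flagged(self):
        est = ms_rate(2, 5.0, epsilon=0.5)
        assert est.r == 0.0
        assert est.clamped

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ms_rate(1, 5.0)
        with pytest.raises(ValueError):
            ms_rate(5, 5.0, epsilon=1.0)


class TestPosteriorRates:
    @staticmethod
    def jittered_trees(deltas):
        return [
            Chronogram.from_newick(
                f"(A:{5 + d},(B:1,C:1):{4 + d});"
            )
            for d in deltas
        ]

    def test_identical_trees_identical_estimates(self):
        trees = self.jittered_trees([0.0, 0.0, 0.0])
        ests, skipped = posterior_rate_distribution(trees, ["A", "B", "C"])
        assert skipped == 0
        assert len({e.r for e in ests}) == 1

    def test_jitter_spread_is_monotone(self):
        rng = np.random.default_rng(17)
        spreads = []
        for scale in (0.01, 0.2, 1.0):
            trees = self.jittered_trees(rng.uniform(0, scale, 50))
            ests, _ = posterior_rate_distribution(trees, ["A", "B", "C"])
            spreads.append(np.std([e.r for e in ests]))
        assert spreads == sorted(spreads)

    def test_non_monophyletic_clades_skipped(self):
        trees = [
            Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);"),
            Chronogram.from_newick("((A:1,C:1):1,(B:1,D:1):1);"),
        ]
        ests, skipped = posterior_rate_distribution(trees, ["A", "B"])
        assert len(ests) == 1 and skipped == 1
        ests, skipped = posterior_rate_distribution(trees, ["A", "Z"])
        assert not ests and skipped == 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            posterior_rate_distribution([], ["A", "B"])
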