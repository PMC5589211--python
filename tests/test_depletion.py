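"""Depletion statistic: rates, expectations, ratios, empirical p, permutations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neoscape import depletion as d
from neoscape import synthetic as syn
from neoscape.variants import N_CLASSES


def make_rates(ns_bs: dict[int, tuple[float, float]]) -> d.NullRates:
    ns = np.full(N_CLASSES, np.nan)
    bs = np.full(N_CLASSES, np.nan)
    sup = np.zeros(N_CLASSES, dtype=bool)
    for k, (n, b) in ns_bs.items():
        ns[k], bs[k], sup[k] = n, b, True
    return d.NullRates(ns=ns, bs=bs, supported=sup)


class TestFitNullRates:
    def test_direct_division(self):
        silent = np.zeros(N_CLASSES); missense = np.zeros(N_CLASSES); neo = np.zeros(N_CLASSES)
        silent[7], missense[7], neo[7] = 10, 20, 5
        rates = d.fit_null_rates(silent, missense, neo)
        assert rates.ns[7] == 2.0 and rates.bs[7] == 0.25
        assert rates.supported[7]

    def test_zero_silent_class_flagged_unsupported(self):
        silent = np.zeros(N_CLASSES); missense = np.zeros(N_CLASSES); neo = np.zeros(N_CLASSES)
        silent[0], missense[0] = 5, 5
        missense[1] = 10  # class 1 has no silent mutations
        rates = d.fit_null_rates(silent, missense, neo)
        assert not rates.supported[1]
        assert np.isnan(rates.ns[1])
        assert np.isfinite(rates.ns[0])

    def test_zero_neoepitopes_is_valid_bs_zero(self):
        silent = np.zeros(N_CLASSES); missense = np.zeros(N_CLASSES); neo = np.zeros(N_CLASSES)
        silent[3], missense[3] = 4, 8
        rates = d.fit_null_rates(silent, missense, neo)
        assert rates.bs[3] == 0.0

    def test_all_unsupported_is_error(self):
        z = np.zeros(N_CLASSES)
        with pytest.raises(d.DepletionError):
            d.fit_null_rates(z, z, z)


class TestPredictExpected:
    def test_hand_summation(self):
        rates = make_rates({0: (2.0, 0.25), 1: (1.0, 0.2)})
        ss = np.zeros(N_CLASSES); ss[0], ss[1] = 2, 1
        npred, bpred, expected = d.predict_expected(ss, rates)
        assert npred == pytest.approx(5.0)
        assert bpred == pytest.approx(1.2)
        assert expected == pytest.approx(0.24)

    def test_single_class_sum(self):
        rates = make_rates({5: (3.0, 0.1)})
        ss = np.zeros(N_CLASSES); ss[5] = 4
        npred, bpred, _ = d.predict_expected(ss, rates)
        assert npred == 12.0 and bpred == pytest.approx(1.2)

    def test_zero_bs_gives_zero_bpred(self):
        rates = make_rates({0: (2.0, 0.0)})
        ss = np.zeros(N_CLASSES); ss[0] = 3
        npred, bpred, expected = d.predict_expected(ss, rates)
        assert bpred == 0.0 and expected == 0.0

    def test_npred_zero_is_error(self):
        rates = make_rates({0: (2.0, 0.25)})
        ss = np.zeros(N_CLASSES); ss[1] = 5  # silent only in unsupported class
        with pytest.raises(d.DepletionError, match="Npred"):
            d.predict_expected(ss, rates)


class TestDepletionRatio:
    def test_worked_example(self):
        rates = make_rates({0: (2.0, 0.25), 1: (1.0, 0.2)})
        ss = np.zeros(N_CLASSES); ss[0], ss[1] = 2, 1
        res = d.depletion_ratio("s", ss, nobs=5, bobs=1, rates=rates)
        assert res.observed == pytest.approx(0.2)
        assert res.r == pytest.approx(0.8333, abs=1e-4)
        assert res.log2r == pytest.approx(-0.263, abs=1e-3)

    def test_self_consistency_r_equals_one(self):
        rates = make_rates({0: (2.0, 0.25), 1: (1.0, 0.2)})
        ss = np.zeros(N_CLASSES); ss[0], ss[1] = 2, 1
        # Bobs/Nobs chosen equal to Bpred/Npred = 0.24
        res = d.depletion_ratio("s", ss, nobs=100, bobs=24, rates=rates)
        assert res.r == pytest.approx(1.0) and res.log2r == pytest.approx(0.0)

    def test_zero_bobs_sentinel(self):
        rates = make_rates({0: (2.0, 0.25)})
        ss = np.zeros(N_CLASSES); ss[0] = 2
        with pytest.warns(UserWarning, match="sentinel"):
            res = d.depletion_ratio("s", ss, nobs=5, bobs=0, rates=rates)
        assert res.r == 0.0 and res.log2r == -np.inf


class TestEmpiricalP:
    def test_counting_examples(self):
        null99 = list(np.arange(99) + 1.0)
        assert d.empirical_p(0.0, null99) == pytest.approx(0.02)
        null9 = list(np.arange(9) + 1.0)
        assert d.empirical_p(0.0, null9) == pytest.approx(0.2)

    def test_central_value_capped_at_one(self):
        null = [-2.0, -1.0, 0.0, 1.0, 2.0]
        assert d.empirical_p(0.0, null) == 1.0

    @given(
        null=st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=1, max_size=20,
        ),
        obs=st.floats(min_value=-12, max_value=12, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_rank_counting(self, null, obs):
        """Oracle: count ranks with explicit loops, apply the two-sided
        add-one formula directly."""
        r_le = sum(1 for x in null if x <= obs)
        r_ge = sum(1 for x in null if x >= obs)
        expected = min(1.0, 2.0 * (min(r_le, r_ge) + 1) / (len(null) + 1))
        assert d.empirical_p(obs, null) == pytest.approx(expected)

    def test_empty_null_is_error(self):
        with pytest.raises(d.DepletionError):
            d.empirical_p(0.0, [])


class TestCohortMachinery:
    def test_npred_conservation_on_pooled_self_fit(self):
        """Fitting Ns on the pooled cohort and predicting from the pooled
        silent spectrum must return exactly the pooled missense count."""
        co = syn.simulate_cohort(
            syn.SimulationConfig.reference_cohort(seed=5, n_samples=20,
                                                  mutations_per_sample=150)
        )
        silent, missense, neo = d.pooled_class_counts(co.occurrences)
        rates = d.fit_null_rates(silent, missense, neo)
        npred, _, _ = d.predict_expected(silent.astype(float), rates)
        assert npred == pytest.approx(missense[silent > 0].sum())

    def test_cohort_empirical_p_within_cohort(self):
        co = syn.simulate_cohort(
            syn.SimulationConfig.reference_cohort(seed=6, n_samples=30,
                                                  mutations_per_sample=200)
        )
        results = d.cohort_empirical_p(d.cohort_depletion(co.occurrences))
        assert all(0 < r.p_empirical <= 1 for r in results)


class TestPermutationNull:
    def _cohort(self, seed=7, n=5, muts=120.0):
        return syn.simulate_cohort(
            syn.SimulationConfig(seed=seed, n_samples=n, mutations_per_sample=muts)
        )

    def test_emits_exactly_n_perm_distinct_permutations(self):
        co = self._cohort()
        _, null = d.permutation_null(co.occurrences, n_perm=150, seed=1)
        assert null.shape[1] == 150
        cols = {tuple(np.round(null[c].to_numpy(), 12)) for c in null.columns}
        # distinct assignments can still collide in log2R only by chance;
        # near-complete distinctness is the expectation
        assert len(cols) >= 149

    def test_same_seed_identical_p_values(self):
        co = self._cohort()
        r1, n1 = d.permutation_null(co.occurrences, n_perm=60, seed=9)
        r2, n2 = d.permutation_null(co.occurrences, n_perm=60, seed=9)
        assert [r.p_empirical for r in r1] == [r.p_empirical for r in r2]
        assert n1.equals(n2)

    def test_small_permutation_space_warns_and_uses_all(self):
        occ = pd.DataFrame(
            {
                "sample": ["a", "a", "b", "b"],
                "mutation_id": ["m1", "m2", "m3", "m4"],
                "class_idx": [0, 0, 0, 0],
                "mclass": ["silent", "missense", "silent", "missense"],
                "is_neoepitope": [False, True, False, False],
            }
        )
        with pytest.warns(UserWarning, match="distinct permutations"):
            _, null = d.permutation_null(occ, n_perm=150, seed=2)
        assert null.shape[1] == 6  # C(4,2) distinct partitions

    def test_p_values_calibrated_under_null(self):
        """Samples drawn with no depletion should rarely be extreme against
        their own permutation distribution."""
        co = self._cohort(seed=11, n=6, muts=250.0)
        results, _ = d.permutation_null(co.occurrences, n_perm=150, seed=3)
        assert min(r.p_empirical for r in results) > 0.01


class TestCalibrationAndRecovery:
    def test_null_cohort_median_log2r_near_zero(self):
        co = syn.simulate_cohort(
            syn.SimulationConfig.reference_cohort(seed=21, n_samples=60,
                                                  mutations_per_sample=300)
        )
        results = d.cohort_depletion(co.occurrences)
        med = np.median([r.log2r for r in results])
        assert abs(med) < 0.1  # scaled-down cohort; full scale in acceptance

    def test_injected_depletion_recovered(self):
        ref = syn.simulate_cohort(
            syn.SimulationConfig.reference_cohort(seed=22, n_samples=60,
                                                  mutations_per_sample=300)
        )
        dep = syn.simulate_cohort(
            syn.SimulationConfig.reference_cohort(seed=23, n_samples=60,
                                                  mutations_per_sample=300,
                                                  depletion_delta=0.5)
        )
        rates = d.fit_null_rates(*d.pooled_class_counts(ref.occurrences))
        med = np.median([r.r for r in d.cohort_depletion(dep.occurrences, rates=rates)])
        assert 0.4 <= med <= 0.65


def test_normality_report_runs_all_three_tests(rng):
    rep = d.normality_report(rng.normal(size=50))
    assert set(rep["test"]) == {"shapiro_wilk", "dagostino_pearson", "kolmogorov_smirnov"}
    assert ((rep["p"] >= 0) & (rep["p"] <= 1)).all()


def test_results_frame_is_rectangular():
    rates = make_rates({0: (2.0, 0.25), 1: (1.0, 0.2)})
    ss = np.zeros(N_CLASSES); ss[0], ss[1] = 2, 1
    res = [d.depletion_ratio("s", ss, 5, 1, rates)]
    frame = d.results_to_frame(res)
    assert list(frame.columns)[:3] == ["sample", "nobs", "bobs"]
    assert len(frame) == 1
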