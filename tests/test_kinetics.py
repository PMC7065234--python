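"""Dwell extraction, censored-MLE k_off estimation and site comparison."""

import numpy as np
import pytest

from lipidex import (
    BindingSite,
    ContactTrace,
    DwellTimeSet,
    binarize_contacts,
    compare_sites,
    contact_frequency,
    estimate_koff,
    extract_dwells,
    koff_from_survival,
    simulate_contact_trace,
    simulate_dwell_times,
    site_occupancy,
    survival_curve,
)


def _state_trace(states, dt=1.0, site_id="s"):
    return ContactTrace(site_id, dt, np.asarray(states, dtype=np.int8), kind="state")


class TestBinarize:
    def test_all_close_is_all_bound(self):
        t = ContactTrace("s", 1.0, np.full(200, 0.3), kind="distance")
        assert binarize_contacts(t).values.all()

    def test_hysteresis_keeps_bound_between_cutoffs(self):
        # enter below d_on once, then oscillate in the hysteresis band
        d = np.concatenate([[0.4], np.tile([0.6, 0.9], 50)])
        out = binarize_contacts(ContactTrace("s", 1.0, d, kind="distance"),
                                d_on=0.55, d_off=1.0)
        assert out.values.all()

    def test_exit_requires_crossing_d_off(self):
        d = np.array([0.4, 0.7, 1.2, 0.7, 0.4, 0.7])
        out = binarize_contacts(ContactTrace("s", 1.0, d, kind="distance"),
                                d_on=0.55, d_off=1.0)
        assert list(out.values) == [1, 1, 0, 0, 1, 1]

    def test_invalid_cutoffs_rejected(self):
        t = ContactTrace("s", 1.0, np.full(10, 0.3), kind="distance")
        with pytest.raises(ValueError):
            binarize_contacts(t, d_on=1.0, d_off=0.5)

    def test_binary_trace_passes_through(self):
        t = _state_trace([0, 1, 1, 0])
        assert binarize_contacts(t) is t

    def test_dual_cutoff_absorbs_rattling(self):
        site = BindingSite("s", k_on=20.0, k_off_true=20.0)
        trace = simulate_contact_trace(
            site, 100_000.0, 0.5, rattle_rate=40.0, rattle_mean=2.0,
            seed=13, emit="distance",
        )
        dual = extract_dwells(binarize_contacts(trace, 0.55, 1.0), gap_tolerance=0.0)
        single = extract_dwells(binarize_contacts(trace, 0.55, 0.55), gap_tolerance=0.0)
        assert dual.durations.mean() > single.durations.mean()


class TestExtractDwells:
    def test_interior_run_uncensored(self):
        v = np.zeros(300, dtype=int)
        v[100:200] = 1
        dwells = extract_dwells(_state_trace(v))
        assert dwells.durations.tolist() == [100.0]
        assert not dwells.censored[0]

    def test_run_touching_trace_end_is_censored(self):
        v = np.zeros(100, dtype=int)
        v[80:] = 1
        dwells = extract_dwells(_state_trace(v))
        assert dwells.censored[0]

    def test_short_gap_merged(self):
        v = np.zeros(100, dtype=int)
        v[10:30] = 1
        v[33:50] = 1  # 3-frame gap at dt=1 -> 3 ns <= 5 ns tolerance
        dwells = extract_dwells(_state_trace(v), gap_tolerance=5.0)
        assert dwells.durations.tolist() == [40.0]

    def test_long_gap_not_merged(self):
        v = np.zeros(100, dtype=int)
        v[10:30] = 1
        v[40:50] = 1
        dwells = extract_dwells(_state_trace(v), gap_tolerance=5.0)
        assert dwells.durations.tolist() == [20.0, 10.0]

    def test_empty_trace_gives_empty_set(self):
        dwells = extract_dwells(_state_trace(np.zeros(50, dtype=int)))
        assert dwells.n_events == 0


class TestSurvival:
    def test_counting_definition(self):
        dwells = DwellTimeSet([10.0, 20.0, 30.0], [False] * 3)
        S = survival_curve(dwells)
        assert S.at(0.0) == 1.0
        assert S.at(15.0) == pytest.approx(2 / 3)

    def test_matches_exponential_within_dkw_band(self):
        dwells = simulate_dwell_times(10.0, 5000, seed=21)
        S = survival_curve(dwells)
        expected = np.exp(-0.01 * S.times)
        assert np.max(np.abs(S.S - expected)) < 0.03

    def test_all_censored_is_an_error(self):
        dwells = DwellTimeSet([10.0, 20.0], [True, True])
        with pytest.raises(ValueError, match="longer traces"):
            survival_curve(dwells)

    def test_log_slope_agrees_with_mle(self):
        dwells = simulate_dwell_times(32.5, 5000, seed=3)
        k_mle = estimate_koff(dwells, n_boot=50, seed=0).k_off
        k_slope = koff_from_survival(survival_curve(dwells))
        assert abs(k_slope - k_mle) / k_mle < 0.15


class TestEstimateKoff:
    def test_uncensored_rate_is_inverse_mean(self):
        dwells = DwellTimeSet([100.0] * 20, [False] * 20)
        est = estimate_koff(dwells, n_boot=50, seed=0)
        assert est.k_off == pytest.approx(10.0)

    def test_censored_dwells_extend_denominator_only(self):
        durations = [100.0] * 10 + [100.0] * 10
        censored = [False] * 10 + [True] * 10
        est = estimate_koff(DwellTimeSet(durations, censored), n_boot=50, seed=0)
        assert est.k_off == pytest.approx(5.0)

    def test_recovers_intermediate_site_rate(self):
        dwells = simulate_dwell_times(32.5, 5000, seed=7)
        est = estimate_koff(dwells, n_boot=200, seed=7)
        assert 31.0 <= est.k_off <= 34.0
        assert est.ci_low <= est.k_off <= est.ci_high

    def test_too_few_uncensored_dwells_rejected(self):
        dwells = DwellTimeSet([50.0] * 9, [False] * 9)
        with pytest.raises(ValueError, match="uncensored"):
            estimate_koff(dwells, n_boot=10, seed=0)

    @pytest.mark.parametrize("k_true", [5.0, 10.0, 32.5, 75.0])
    def test_mle_consistency_across_rates(self, k_true):
        # |k_hat - k| / k < 4/sqrt(n) in >= 99 % of seeded replicates
        n, reps, bound = 2000, 200, 4 / np.sqrt(2000)
        rng = np.random.default_rng(int(k_true * 10))
        hits = 0
        for _ in range(reps):
            d = rng.exponential(1000.0 / k_true, n)
            k_hat = 1000.0 * n / d.sum()
            hits += abs(k_hat - k_true) / k_true < bound
        assert hits / reps >= 0.99

    def test_bootstrap_ci_coverage(self):
        # nominal 95 % percentile CI covers the true rate in >= 90 % of
        # replicates at n = 500
        k_true, n, reps = 20.0, 500, 200
        rng = np.random.default_rng(99)
        covered = 0
        for i in range(reps):
            dwells = simulate_dwell_times(k_true, n, seed=int(rng.integers(2**31)))
            est = estimate_koff(dwells, n_boot=300, seed=int(rng.integers(2**31)))
            covered += est.ci_low <= k_true <= est.ci_high
        assert covered / reps >= 0.90

    def test_censoring_accounted_without_upward_bias(self):
        # truncating a long-dwell experiment and *dropping* censored dwells
        # overestimates k; the censored MLE must not
        k_true, horizon = 10.0, 150.0
        d = simulate_dwell_times(k_true, 2000, seed=5).durations
        censored = d > horizon
        observed = np.minimum(d, horizon)
        est = estimate_koff(DwellTimeSet(observed, censored), n_boot=100, seed=0)
        n_unc = int((~censored).sum())
        se = k_true / np.sqrt(n_unc)
        assert abs(est.k_off - k_true) < 2 * se
        naive = 1000.0 / observed[~censored].mean()
        assert naive - k_true > 4 * se  # the naive estimator is visibly biased

    def test_rattle_robustness_of_estimated_rate(self):
        site = BindingSite("s", k_on=10.0, k_off_true=20.0)
        kw = dict(duration=400_000.0, dt=0.5, seed=29)
        plain = simulate_contact_trace(site, **kw)
        rattled = simulate_contact_trace(site, rattle_rate=10.0, rattle_mean=2.0, **kw)
        k_plain = estimate_koff(
            extract_dwells(plain, gap_tolerance=5.0), n_boot=50, seed=0
        ).k_off
        k_rattled = estimate_koff(
            extract_dwells(rattled, gap_tolerance=5.0), n_boot=50, seed=0
        ).k_off
        assert abs(k_rattled - k_plain) / k_plain < 0.10


class TestCompareSites:
    def _est(self, site_id, k, ci=0.05):
        dwells = simulate_dwell_times(k, 2000, seed=hash(site_id) % 1000)
        return estimate_koff(dwells, n_boot=100, seed=1)

    def test_fold_ratio(self):
        a = estimate_koff(DwellTimeSet([100.0] * 50, [False] * 50), 50, seed=0)
        a.site_id = "slow"
        b = estimate_koff(DwellTimeSet([100.0 / 3] * 50, [False] * 50), 50, seed=0)
        b.site_id = "fast"
        cmp_res = compare_sites([b, a])
        assert cmp_res.order == ["slow", "fast"]
        assert cmp_res.pairs.iloc[0]["fold"] == pytest.approx(3.0)

    def test_equal_sites_flagged_overlapping(self):
        a = estimate_koff(simulate_dwell_times(10.0, 500, seed=2), 200, seed=2)
        b = estimate_koff(simulate_dwell_times(10.0, 500, seed=2), 200, seed=2)
        a.site_id, b.site_id = "a", "b"
        cmp_res = compare_sites([a, b])
        assert cmp_res.pairs.iloc[0]["fold"] == pytest.approx(1.0)
        assert bool(cmp_res.pairs.iloc[0]["ci_overlap"])

    def test_leut_sites_ordered_with_threefold_separation(self, leut_fixture):
        rng = np.random.default_rng(leut_fixture.seed)
        estimates = []
        for site in leut_fixture.sites:
            dwells = simulate_dwell_times(
                site.k_off_true,
                leut_fixture.n_events[site.site_id],
                seed=int(rng.integers(2**31)),
                site_id=site.site_id,
            )
            estimates.append(estimate_koff(dwells, n_boot=200,
                                           seed=int(rng.integers(2**31))))
        cmp_res = compare_sites(estimates)
        assert cmp_res.order[0] == "R88/K376"  # interfacial site slowest
        folds = cmp_res.pairs.set_index(["slow", "fast"])["fold"]
        assert folds[("R88/K376", "R453/R446")] > 3.0
        assert folds[("R88/K376", "R11/I441")] > 3.0


class TestOccupancyAndAccessibility:
    def test_all_bound(self):
        assert site_occupancy(_state_trace([1, 1, 1])) == 1.0

    def test_alternating(self):
        assert site_occupancy(_state_trace([0, 1] * 50)) == 0.5

    def test_interfacial_site_nearly_always_occupied(self, leut_fixture):
        site = next(s for s in leut_fixture.sites if s.site_id == "R88/K376")
        trace = simulate_contact_trace(site, 100_000.0, 0.5, seed=41)
        assert site_occupancy(trace) > 0.9

    def test_full_contact_frequency(self):
        t = ContactTrace("s", 1.0, np.full(500, 0.2), kind="distance")
        profile = contact_frequency({("outward", "R24"): t})
        assert profile.frequency("outward", "R24") == 1.0

    def test_missing_cell_is_absent_not_zero(self):
        t = _state_trace([1, 0, 1, 0])
        profile = contact_frequency({("outward", "R24"): t, ("inward", "F256"): t})
        assert np.isnan(profile.matrix.loc["outward", "F256"])
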