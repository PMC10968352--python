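"""SWB filtering, SMOTE balancing, repeated regression, group t-test, BY FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from eegasym import (
    AsymSample,
    ConfigurationError,
    DegenerateDataError,
    by_fdr,
    filter_participant_swb,
    filter_swb_arrays,
    fit_participant_slope,
    group_slope_test,
    smote_balance,
)


def samples_from_counts(counts, rng=None):
    """Build (values, swb) arrays with the given rating->count table."""
    rng = rng or np.random.default_rng(0)
    swb = np.concatenate([[r] * c for r, c in counts.items()])
    return rng.normal(size=swb.size), swb.astype(int)


class TestFilterSwb:
    @pytest.mark.parametrize(
        "counts,kept_ratings,excluded",
        [
            ({6: 7, 7: 5, 8: 2, 3: 1}, {6, 7}, True),
            ({5: 3, 6: 3, 7: 3}, {5, 6, 7}, False),
            ({6: 10, 7: 3, 8: 3, 2: 1}, {6, 7, 8}, False),
        ],
    )
    def test_rule_examples(self, counts, kept_ratings, excluded):
        values, swb = samples_from_counts(counts)
        v, s, excl = filter_swb_arrays(values, swb)
        assert set(s.tolist()) == kept_ratings
        assert excl is excluded
        assert v.size == sum(counts[r] for r in kept_ratings)

    def test_object_form_agrees_with_array_form(self):
        counts = {6: 7, 7: 5, 8: 2, 3: 1}
        values, swb = samples_from_counts(counts)
        objs = [
            AsymSample("alpha", "AF4", "F7", v, int(s))
            for v, s in zip(values, swb)
        ]
        kept, excluded = filter_participant_swb(objs)
        assert excluded is True
        assert sorted({o.swb for o in kept}) == [6, 7]


class TestSmote:
    def test_already_balanced_input_is_returned_unchanged(self, rng):
        values, swb = samples_from_counts({6: 4, 7: 4}, rng)
        v, s = smote_balance(values, swb, seed=1)
        assert np.array_equal(v, values)
        assert np.array_equal(s, swb)

    def test_minority_oversampled_to_majority_count(self, rng):
        values, swb = samples_from_counts({6: 5, 7: 3}, rng)
        v, s = smote_balance(values, swb, seed=1)
        assert np.sum(s == 6) == 5
        assert np.sum(s == 7) == 5
        # originals retained in order
        assert np.array_equal(v[: values.size], values)

    def test_synthetics_confined_to_class_range(self, rng):
        values, swb = samples_from_counts({5: 9, 6: 4, 7: 3}, rng)
        v, s = smote_balance(values, swb, seed=7)
        for c in (6, 7):
            orig = values[swb == c]
            assert v[s == c].min() >= orig.min() - 1e-12
            assert v[s == c].max() <= orig.max() + 1e-12

    def test_seed_reproducibility_and_count_stability(self, rng):
        values, swb = samples_from_counts({6: 8, 7: 4, 8: 3}, rng)
        v1, s1 = smote_balance(values, swb, seed=5)
        v2, s2 = smote_balance(values, swb, seed=5)
        v3, s3 = smote_balance(values, swb, seed=6)
        assert np.array_equal(v1, v2) and np.array_equal(s1, s2)
        assert not np.array_equal(v1, v3)
        assert np.array_equal(np.bincount(s1), np.bincount(s3))

    def test_singleton_class_rejected(self, rng):
        values, swb = samples_from_counts({6: 4, 7: 1}, rng)
        with pytest.raises(DegenerateDataError, match="interpolation impossible"):
            smote_balance(values, swb, seed=0)

    def test_k_auto_reduced_to_class_size_minus_one(self, rng):
        # class of 3 with default k=5 must still work
        values, swb = samples_from_counts({6: 9, 7: 3}, rng)
        v, s = smote_balance(values, swb, k_neighbors=5, seed=2)
        assert np.sum(s == 7) == 9


class TestFitParticipantSlope:
    def test_exact_line_recovered_for_any_seed(self):
        # within each rating class all Asym equal and SWB = 2*Asym + 1
        swb = np.array([3] * 4 + [5] * 3 + [7] * 3)
        values = (swb - 1) / 2.0
        for seed in (0, 1, 99):
            fit = fit_participant_slope(values, swb, seed=seed)
            assert fit.slope == pytest.approx(2.0, abs=1e-12)
            assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_fields_are_means_over_repeats(self, rng):
        values, swb = samples_from_counts({5: 6, 6: 4, 7: 3}, rng)
        values = values + 0.3 * swb
        fit = fit_participant_slope(values, swb, n_repeats=10, seed=3)
        # recompute the repeat fits by hand with the same seed derivation
        from eegasym.stats import _ols, smote_balance as sb

        slopes = []
        for child in np.random.SeedSequence(3).spawn(10):
            bv, bs = sb(values, swb, seed=np.random.default_rng(child))
            slopes.append(_ols(bv, bs.astype(float))[0])
        assert fit.slope == pytest.approx(np.mean(slopes), abs=1e-14)
        assert fit.n_repeats == 10

    def test_many_repeats_converge_to_same_mean(self, rng):
        values, swb = samples_from_counts({5: 8, 6: 6, 7: 5}, rng)
        values = values + 0.5 * swb
        a = fit_participant_slope(values, swb, n_repeats=10, seed=0)
        b = fit_participant_slope(values, swb, n_repeats=400, seed=1)
        spread = np.ptp(
            [fit_participant_slope(values, swb, n_repeats=10, seed=s).slope
             for s in range(2, 10)]
        )
        assert abs(a.slope - b.slope) < max(3 * spread, 1e-6)

    def test_constant_asym_cannot_be_fit(self):
        swb = np.array([5] * 3 + [6] * 3 + [7] * 3)
        values = np.ones(swb.size)
        with pytest.raises(DegenerateDataError, match="repeats skipped"):
            fit_participant_slope(values, swb, seed=0)

    def test_asym_on_swb_orientation(self):
        swb = np.array([3] * 3 + [5] * 3 + [7] * 3)
        values = 0.25 * swb + 1.0
        fit = fit_participant_slope(values, swb, orientation="asym_on_swb", seed=0)
        assert fit.slope == pytest.approx(0.25, abs=1e-12)


def make_fits(slopes):
    from eegasym import ParticipantFit

    return [
        ParticipantFit(f"P{i}", s, 0.0, 10, 30) for i, s in enumerate(slopes)
    ]


class TestGroupSlopeTest:
    def test_closed_form_oracle_values(self):
        from scipy import stats as sst

        res = group_slope_test(make_fits([0.5, 1.0, 1.5]))
        assert res.t_stat == pytest.approx(3.4641, abs=1e-4)
        assert res.p_value == pytest.approx(0.0742, abs=1e-4)
        # closed-form t-distribution oracle: mean +/- t(0.975, 2) * SE
        half = sst.t.ppf(0.975, 2) * np.std([0.5, 1.0, 1.5], ddof=1) / np.sqrt(3)
        assert res.ci_low == pytest.approx(1.0 - half, abs=1e-12)
        assert res.ci_high == pytest.approx(1.0 + half, abs=1e-12)
        assert res.ci_low == pytest.approx(-0.2421, abs=1e-3)
        assert res.ci_high == pytest.approx(2.2421, abs=1e-3)

    def test_symmetric_slopes_give_t_zero_p_one(self):
        res = group_slope_test(make_fits([-1.0, 0.0, 1.0]))
        assert res.t_stat == 0.0
        assert res.p_value == 1.0

    def test_location_equivariance_of_ci(self):
        base = group_slope_test(make_fits([0.5, 1.0, 1.5]))
        shifted = group_slope_test(make_fits([2.5, 3.0, 3.5]))
        assert shifted.ci_low == pytest.approx(base.ci_low + 2.0, abs=1e-12)
        assert shifted.ci_high == pytest.approx(base.ci_high + 2.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateDataError):
            group_slope_test(make_fits([1.0]))
        with pytest.raises(DegenerateDataError):
            group_slope_test(make_fits([1.0, 1.0, 1.0]))


def by_adjust_bruteforce(p):
    """Independent step-up oracle: p~_(i) = min_{j>=i}( m*c(m)*p_(j)/j )."""
    p = np.asarray(p, float)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    for rank_i in range(m):
        candidates = [
            m * c_m * p[order[j]] / (j + 1) for j in range(rank_i, m)
        ]
        adjusted_sorted[rank_i] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


class TestByFdr:
    def test_worked_vector_equalizes_to_0114167(self):
        adjusted, reject = by_fdr([0.01, 0.02, 0.03, 0.04, 0.05], alpha=0.1)
        assert np.allclose(adjusted, 0.1141666666666667, atol=1e-6)
        assert not reject.any()

    def test_single_p_unchanged(self):
        adjusted, _ = by_fdr([0.03])
        assert adjusted[0] == pytest.approx(0.03, abs=1e-15)

    def test_all_ones_none_rejected(self):
        adjusted, reject = by_fdr([1.0, 1.0, 1.0])
        assert np.all(adjusted == 1.0)
        assert not reject.any()

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.integers(1, 21)
            p = rng.uniform(1e-6, 1.0, size=m)
            adjusted, _ = by_fdr(p)
            assert np.allclose(adjusted, by_adjust_bruteforce(p), atol=1e-12)

    def test_empty_and_invalid_inputs(self):
        adjusted, reject = by_fdr([])
        assert adjusted.size == 0 and reject.size == 0
        with pytest.raises(ConfigurationError):
            by_fdr([0.0, 0.5])
        with pytest.raises(ConfigurationError):
            by_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=60)
    @given(
        p=st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1, max_size=20,
        )
    )
    def test_by_dominates_bh_dominates_raw(self, p):
        p = np.array(p)
        by_adj, _ = by_fdr(p)
        _, bh_adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.all(by_adj >= bh_adj - 1e-12)
        assert np.all(bh_adj >= p - 1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(
        p=st.lists(
            st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=15
        )
    )
    def test_adjusted_monotone_on_sorted_input(self, p):
        p = np.sort(np.array(p))
        adjusted, _ = by_fdr(p)
        assert np.all(np.diff(adjusted) >= -1e-12)
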