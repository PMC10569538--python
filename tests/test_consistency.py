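"""Split-half machinery, noise-corrected consistency, aggregation."""

import numpy as np
import pytest

import interanimal as ia


class TestSplitTrials:
    def test_two_trials_partition_into_single_trials(self, rng):
        resp = rng.normal(size=(10, 2, 3))
        rec = ia.PopulationRecording(resp, "a")
        s1, s2 = ia.split_trials(rec, seed=0)
        trials = {0: resp[:, 0], 1: resp[:, 1]}
        assert any(np.array_equal(s1, trials[i]) and
                   np.array_equal(s2, trials[1 - i]) for i in (0, 1))

    def test_zero_noise_halves_identical(self, noiseless_cohort):
        recs, _ = noiseless_cohort
        s1, s2 = ia.split_trials(recs[0], seed=3)
        assert np.allclose(s1, s2)

    def test_deterministic_given_seed(self, small_cohort):
        recs, _ = small_cohort
        a = ia.split_trials(recs[0], seed=7)
        b = ia.split_trials(recs[0], seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_rejects_single_trial(self, rng):
        rec = ia.PopulationRecording(rng.normal(size=(5, 2, 2)), "a")
        rec.responses = rec.responses[:, :1]
        with pytest.raises(ValueError):
            ia.split_trials(rec, seed=0)

    def test_odd_trial_count_drops_one(self, rng):
        rec = ia.PopulationRecording(rng.normal(size=(6, 5, 2)), "a")
        s1, s2 = ia.split_trials(rec, seed=0)
        assert s1.shape == s2.shape == (6, 2)


class TestSpearmanBrown:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (0.0, 0.0),
                                            (1.0 / 3.0, 0.5)])
    def test_exact_values(self, r, expected):
        assert ia.spearman_brown(r) == pytest.approx(expected, abs=1e-12)

    def test_domain_error_below_minus_one(self):
        with pytest.raises(ValueError):
            ia.spearman_brown(-1.0)

    def test_vectorised(self):
        out = ia.spearman_brown(np.array([0.0, 1.0 / 3.0, 1.0]))
        assert np.allclose(out, [0.0, 0.5, 1.0], atol=1e-12)


class TestInternalConsistency:
    def test_zero_noise_equals_one(self, noiseless_cohort):
        recs, _ = noiseless_cohort
        ic = ia.internal_consistency(recs[0], ia.SplitHalfPlan(5))
        assert np.allclose(ic, 1.0)

    def test_matches_closed_form_with_correction(self):
        # signal var 1, noise var 1, 2 trials: raw 0.5, corrected 2/3
        recs, _ = ia.generate_cohort(n_animals=1, n_units=40, n_stimuli=1000,
                                     n_trials=2, noise_sd=1.0, seed=31)
        plan = ia.SplitHalfPlan(50, seed=1)
        raw = ia.internal_consistency(recs[0], plan, corrected=False)
        cor = ia.internal_consistency(recs[0], plan, corrected=True)
        assert abs(raw.mean() - 0.5) < 0.05
        assert abs(cor.mean() - 2.0 / 3.0) < 0.05

    def test_gaussian_split_half_identity(self):
        # Corr(s1, s2) ~ Corr(t, s2)^2 under Gaussian trial noise
        recs, gt = ia.generate_cohort(n_animals=1, n_units=10,
                                      n_stimuli=10_000, n_trials=10,
                                      noise_sd=1.5, seed=13)
        s1, s2 = ia.split_trials(recs[0], seed=4)
        t = gt.true_responses[0]
        lhs = np.array([np.corrcoef(s1[:, u], s2[:, u])[0, 1]
                        for u in range(10)])
        rhs = np.array([np.corrcoef(t[:, u], s2[:, u])[0, 1] ** 2
                        for u in range(10)])
        assert np.max(np.abs(lhs - rhs)) < 0.02


class TestPairwiseConsistency:
    def test_noiseless_identity_population_scores_one(self, noiseless_cohort):
        recs, gt = noiseless_cohort
        # target = same true responses as source, zero trial noise
        twin = ia.PopulationRecording(recs[0].responses.copy(), "twin")
        res = ia.noise_corrected_pairwise_consistency(
            recs[0], twin, ia.MappingSpec(kind="ridge", ridge_penalty=1e-8),
            ia.SplitHalfPlan(4, seed=0), ia.StimulusSplitPlan(n_splits=2, seed=0))
        assert res.median == pytest.approx(1.0, abs=1e-6)

    def test_linear_transform_target_recovered(self, fast_plans):
        half, split = fast_plans
        recs, gt = ia.generate_cohort(n_animals=2, n_units=60, n_stimuli=118,
                                      n_trials=50, seed=55)
        res = ia.noise_corrected_pairwise_consistency(
            recs[0], recs[1], ia.MappingSpec(kind="ridge"), half, split)
        assert 0.9 < res.median < 1.1

    def test_independent_target_scores_zero(self, fast_plans):
        half, split = fast_plans
        recs, _ = ia.generate_cohort(n_animals=2, n_units=40, n_stimuli=118,
                                     n_trials=50, seed=56, shared_signal=False)
        res = ia.noise_corrected_pairwise_consistency(
            recs[0], recs[1], ia.MappingSpec(kind="ridge"), half, split)
        assert abs(res.median) < 0.12

    def test_mismatched_stimuli_rejected(self, small_cohort, rng):
        recs, _ = small_cohort
        other = ia.PopulationRecording(
            rng.normal(size=(recs[0].n_stimuli, 4, 3)), "x",
            stimulus_ids=[f"other_{i}" for i in range(recs[0].n_stimuli)])
        with pytest.raises(ValueError):
            ia.noise_corrected_pairwise_consistency(recs[0], other)

    def test_corrected_value_exceeds_numerator_when_denominator_below_one(
            self, small_cohort, fast_plans):
        recs, _ = small_cohort
        half, split = fast_plans
        res = ia.noise_corrected_pairwise_consistency(
            recs[0], recs[1], ia.MappingSpec(kind="ridge"), half, split)
        num_med = np.nanmedian(res.numerator_trace)
        den_med = np.nanmedian(res.denominator_trace)
        assert 0 < den_med < 1
        assert res.median > num_med

    def test_uncorrected_numerator_decreases_with_noise(self, fast_plans):
        half, split = fast_plans
        meds = []
        for noise in (0.5, 2.0):
            recs, _ = ia.generate_cohort(n_animals=2, n_units=30,
                                         n_stimuli=100, n_trials=20,
                                         noise_sd=noise, seed=60)
            res = ia.noise_corrected_pairwise_consistency(
                recs[0], recs[1], ia.MappingSpec(kind="ridge"), half, split)
            meds.append(np.nanmedian(res.numerator_trace))
        assert meds[1] < meds[0]

    def test_nonlinear_relation_lowers_corrected_consistency(self, fast_plans):
        half, split = fast_plans
        meds = []
        for tag in ("none", "squash"):
            recs, _ = ia.generate_cohort(n_animals=2, n_units=30,
                                         n_stimuli=100, n_trials=20,
                                         noise_sd=0.5, nonlinearity_tag=tag,
                                         seed=61)
            if tag == "squash":
                # linear source vs squashed target: mapping mismatch
                recs_lin, _ = ia.generate_cohort(
                    n_animals=2, n_units=30, n_stimuli=100, n_trials=20,
                    noise_sd=0.5, nonlinearity_tag="none", seed=61)
                src = recs_lin[0]
            else:
                src = recs[0]
            res = ia.noise_corrected_pairwise_consistency(
                src, recs[1], ia.MappingSpec(kind="one_to_one"), half, split)
            meds.append(res.median)
        assert meds[1] <= meds[0] + 0.05


class TestPooledSource:
    def test_two_animal_pooled_reduces_to_pairwise(self, small_cohort,
                                                   fast_plans):
        recs, _ = small_cohort
        half, split = fast_plans
        pooled = ia.pooled_source_consistency(
            recs, ia.MappingSpec(kind="ridge"), half, split)
        pair01 = ia.noise_corrected_pairwise_consistency(
            recs[0], recs[1], ia.MappingSpec(kind="ridge"), half, split)
        assert np.allclose(pooled[1].per_unit_values,
                           pair01.per_unit_values, equal_nan=True)

    def test_pooling_beats_single_source_on_shared_signal(self, fast_plans):
        half, split = fast_plans
        recs, _ = ia.generate_cohort(n_animals=3, n_units=25, n_stimuli=100,
                                     n_trials=16, noise_sd=1.5, seed=71)
        pooled = ia.pooled_source_consistency(
            recs, ia.MappingSpec(kind="ridge"), half, split)
        pair = ia.noise_corrected_pairwise_consistency(
            recs[1], recs[0], ia.MappingSpec(kind="ridge"), half, split)
        assert pooled[0].median >= pair.median - 0.02

    def test_single_animal_rejected(self, small_cohort):
        recs, _ = small_cohort
        with pytest.raises(ValueError):
            ia.pooled_source_consistency(recs[:1])


class TestAggregateUnits:
    def _result(self, values):
        values = np.asarray(values, dtype=float)
        return ia.ConsistencyResult(
            per_unit_values=values,
            n_excluded=np.zeros(len(values), dtype=int),
            n_evaluations=10, kept_mask=np.ones(len(values), dtype=bool))

    def test_single_result_median(self):
        med, sem, vals = ia.aggregate_units([self._result([0.2, 0.4, 0.9])])
        assert med == pytest.approx(0.4)
        assert len(vals) == 3

    def test_disjoint_sets_concatenate_before_median(self):
        med, _, _ = ia.aggregate_units(
            [self._result([0.2, 0.4]), self._result([0.6, 0.8])])
        assert med == pytest.approx(0.5)

    def test_order_invariance(self):
        a, b = self._result([0.1, 0.5]), self._result([0.3, 0.9])
        assert ia.aggregate_units([a, b])[:2] == ia.aggregate_units([b, a])[:2]

    def test_all_excluded_signalled(self):
        r = self._result([0.5])
        r.kept_mask = np.zeros(1, dtype=bool)
        with pytest.raises(ValueError):
            ia.aggregate_units([r])


class TestLogLinearExtrapolation:
    def test_two_point_fit_exact(self):
        a, b = 0.1, 0.2
        fit = ia.fit_loglinear_extrapolation(
            [10, 100], [b + a, b + 2 * a])
        assert fit.a == pytest.approx(0.1, abs=1e-12)
        assert fit.b == pytest.approx(0.2, abs=1e-12)

    def test_noiseless_five_points_residuals_tiny(self):
        n = np.array([5, 10, 50, 100, 500], dtype=float)
        y = 0.07 * np.log10(n) + 0.55
        fit = ia.fit_loglinear_extrapolation(n, y)
        assert np.max(np.abs(fit.predict(n) - y)) < 1e-10

    def test_positive_slope_prediction_monotone(self):
        fit = ia.fit_loglinear_extrapolation([10, 100, 1000],
                                             [0.4, 0.5, 0.6])
        grid = np.array([10.0, 50.0, 200.0, 900.0])
        pred = fit.predict(grid)
        assert np.all(np.diff(pred) > 0)

    def test_prediction_clipped_at_one(self):
        fit = ia.fit_loglinear_extrapolation([10, 100], [0.8, 1.0])
        assert fit.predict(1e6) == 1.0

    @pytest.mark.parametrize("n,y", [([10], [0.5]), ([10, 10], [0.4, 0.5]),
                                     ([-5, 10], [0.1, 0.2])])
    def test_invalid_inputs_rejected(self, n, y):
        with pytest.raises(ValueError):
            ia.fit_loglinear_extrapolation(n, y)
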