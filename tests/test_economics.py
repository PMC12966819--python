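"""Eligibility, fixed-effects benchmark and Monte Carlo benefit simulation."""

import numpy as np
import pandas as pd
import pytest

from tierstack import (
    EconomicScenario,
    SimulationSummary,
    eligible_patients,
    fixed_effects_benefit,
    monte_carlo_benefit,
    select_dominant,
    sgd_to_usd,
    summarize_draws,
)
from tierstack.economics import intervention_burden
from tierstack.errors import EmptyInputError, InvalidSpecError, ShapeError


def _records(next_los, cost):
    return pd.DataFrame({"next_los_days": next_los, "next_inpatient_cost": cost})


class TestEligibility:
    def test_everyone_predicted_tier0_is_empty(self):
        rec = _records([0, 8, 20, 40], [0, 1000, 2000, 3000])
        out = eligible_patients(rec, [0, 0, 0, 0])
        assert len(out) == 0

    def test_perfect_predictions_modes_coincide(self):
        rec = _records([0, 8, 20, 40], [0, 1000, 2000, 3000])
        perfect = [0, 1, 2, 3]
        a = eligible_patients(rec, perfect, mode="identified_users")
        b = eligible_patients(rec, perfect, mode="correct_only")
        pd.testing.assert_frame_equal(a, b)

    def test_six_record_toy_matches_hand_enumeration(self):
        # (actual los, predicted): user/non-user x hit/miss combinations
        rec = _records([0, 0, 8, 8, 20, 40], [0, 0, 500, 600, 700, 800])
        pred = [0, 2, 0, 1, 3, 3]
        ident = eligible_patients(rec, pred, mode="identified_users")
        # identified users: records 3 (pred 1), 4 (pred 3), 5 (pred 3)
        assert ident.cost.tolist() == [600, 700, 800]
        assert ident.predicted_tier.tolist() == [1, 3, 3]
        correct = eligible_patients(rec, pred, mode="correct_only")
        # correct only: records 3 (actual tier1 == pred) and 5 (actual tier3 == pred)
        assert correct.cost.tolist() == [600, 800]
        assert intervention_burden(rec, pred) == 1  # record 1: non-user flagged tier 2

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ShapeError):
            eligible_patients(_records([0, 8], [0, 100]), [0])


class TestFixedEffects:
    def test_empty_and_single(self):
        assert fixed_effects_benefit(pd.DataFrame({"predicted_tier": [], "cost": []})) == 0.0
        one = pd.DataFrame({"predicted_tier": [2], "cost": [10_000.0]})
        assert fixed_effects_benefit(one, 0.5) == 5_000.0

    def test_toy_sum(self):
        toy = pd.DataFrame({"predicted_tier": [1, 2, 3], "cost": [8_000.0, 12_000.0, 30_000.0]})
        assert fixed_effects_benefit(toy, 0.5) == 25_000.0

    def test_fraction_domain(self, toy_eligible):
        with pytest.raises(InvalidSpecError):
            fixed_effects_benefit(toy_eligible, 1.5)


class TestMonteCarlo:
    def test_zero_benefit_all_draws_zero(self, toy_eligible):
        sc = EconomicScenario(benefit_mean=0.0, benefit_sd=0.0, n_iterations=50, seed=1)
        draws, _ = monte_carlo_benefit(toy_eligible, sc)
        assert np.all(draws == 0.0)

    def test_degenerate_limit_equals_fixed_effects(self, toy_eligible):
        sc = EconomicScenario(
            benefit_mean=0.5,
            benefit_sd=0.0,
            reach_means={1: 1.0, 2: 1.0, 3: 1.0},
            reach_sd=0.0,
            n_iterations=200,
            seed=2,
        )
        draws, _ = monte_carlo_benefit(toy_eligible, sc)
        fx = fixed_effects_benefit(toy_eligible, 0.5)
        np.testing.assert_allclose(draws, fx, atol=1e-6)

    def test_mean_matches_analytic_expectation(self, toy_eligible):
        """E[total] = sum_i reach_mean[tier_i] * benefit_mean * cost_i."""
        sc = EconomicScenario(n_iterations=10_000, seed=3)
        draws, summary = monte_carlo_benefit(toy_eligible, sc)
        reach = np.array([sc.reach_means[t] for t in toy_eligible.predicted_tier])
        expected = float(np.sum(reach * sc.benefit_mean * toy_eligible.cost))
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(summary.mean - expected) < 3 * se

    def test_reproducible_and_seed_sensitive(self, toy_eligible):
        sc = EconomicScenario(n_iterations=500, seed=4)
        d1, _ = monte_carlo_benefit(toy_eligible, sc)
        d2, _ = monte_carlo_benefit(toy_eligible, sc)
        np.testing.assert_array_equal(d1, d2)
        d3, _ = monte_carlo_benefit(toy_eligible, sc.replace(seed=5))
        assert not np.array_equal(d1, d3)

    def test_disjoint_seed_streams_same_distribution(self, toy_eligible):
        from scipy.stats import ks_2samp

        sc = EconomicScenario(n_iterations=2000, seed=10)
        base, _ = monte_carlo_benefit(toy_eligible, sc)
        for seed in (11, 12, 13):
            other, _ = monte_carlo_benefit(toy_eligible, sc.replace(seed=seed))
            assert ks_2samp(base, other).pvalue > 0.01

    def test_monotone_in_reach_and_benefit(self, toy_eligible):
        """With matched seeds, raising any reach mean or the benefit mean never
        lowers a single draw (coupling argument)."""
        base = EconomicScenario(n_iterations=300, seed=6)
        d0, _ = monte_carlo_benefit(toy_eligible, base)
        for kw in (
            {"reach_means": {1: 0.60, 2: 0.70, 3: 0.90}},
            {"reach_means": {1: 0.50, 2: 0.80, 3: 0.90}},
            {"reach_means": {1: 0.50, 2: 0.70, 3: 0.99}},
            {"benefit_mean": 0.30},
        ):
            d1, _ = monte_carlo_benefit(toy_eligible, base.replace(**kw))
            assert np.all(d1 >= d0 - 1e-9)

    def test_truncation_bound_never_exceeded(self, toy_eligible):
        sc = EconomicScenario(benefit_mean=0.9, benefit_sd=0.5, n_iterations=1000, seed=7)
        draws, _ = monte_carlo_benefit(toy_eligible, sc)
        assert np.all(draws <= toy_eligible.cost.sum() + 1e-9)

    def test_per_iteration_benefit_draw_mode(self, toy_eligible):
        sc = EconomicScenario(n_iterations=2000, seed=8, benefit_draw="per_iteration")
        draws, summary = monte_carlo_benefit(toy_eligible, sc)
        # same expectation as per-patient draws, larger between-iteration spread
        sc_pp = sc.replace(benefit_draw="per_patient")
        _, summary_pp = monte_carlo_benefit(toy_eligible, sc_pp)
        assert summary.mean == pytest.approx(summary_pp.mean, rel=0.05)
        assert summary.sd > summary_pp.sd

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(InvalidSpecError):
            EconomicScenario(n_iterations=0).validate()
        with pytest.raises(InvalidSpecError):
            EconomicScenario(reach_means={1: 0.9, 2: 0.7, 3: 0.5}).validate()


class TestSummaries:
    def test_small_draws(self):
        s = summarize_draws([1, 2, 3, 4])
        assert s.median == 2.5 and s.min == 1 and s.max == 4
        assert s.iqr == pytest.approx(s.q75 - s.q25)

    def test_constant_draws(self):
        s = summarize_draws(np.full(10, 7.0))
        assert s.sd == 0.0 and s.iqr == 0.0

    def test_normal_quantiles(self, rng):
        draws = rng.normal(0, 1, 100_000)
        s = summarize_draws(draws)
        assert s.q25 == pytest.approx(-0.6745, abs=0.02)
        assert s.q75 == pytest.approx(0.6745, abs=0.02)

    def test_ordering_invariant(self, rng):
        s = summarize_draws(rng.lognormal(1, 2, 5000))
        assert s.min <= s.q25 <= s.median <= s.q75 <= s.max

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize_draws([])


class TestDominantSelection:
    @staticmethod
    def _summary(median, mean):
        return SimulationSummary(mean=mean, sd=1, median=median, iqr=1, min=0, max=2 * median, q25=0, q75=1)

    def test_single_model(self):
        assert select_dominant({"A": self._summary(10, 10)}) == "A"

    def test_highest_median_wins(self):
        sums = {"A": self._summary(152, 150), "B": self._summary(150, 151), "C": self._summary(149, 160)}
        assert select_dominant(sums) == "A"

    def test_median_tie_broken_by_mean_then_id(self):
        sums = {"B": self._summary(100, 90), "A": self._summary(100, 95)}
        assert select_dominant(sums) == "A"
        sums = {"B": self._summary(100, 95), "A": self._summary(100, 95)}
        assert select_dominant(sums) == "A"

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            select_dominant({})


def test_currency_conversion_divides():
    assert sgd_to_usd(1.370) == pytest.approx(1.0)
    assert sgd_to_usd(137.0) == pytest.approx(100.0)
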