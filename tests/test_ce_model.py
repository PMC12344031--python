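"""Unit and property tests for the colonisation-extinction likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoce import (
    OccupancySeries,
    TransitionCounts,
    closed_form_rates,
    count_transitions,
    fit_covariate_model,
    fit_site_rates,
    negative_log_likelihood,
    transition_matrix,
)
from thermoce.ce_model import BoundaryRateWarning
from thermoce.simulate import SimulationConfig, simulate_dataset
from thermoce.io import build_occupancy_series

from conftest import markov_series, random_series


def brute_force_nll(series: OccupancySeries, c: float, e: float) -> float:
    """Independent oracle: product of per-pair transition probabilities."""
    total = 0.0
    for row in series.states:
        for k in range(len(series.survey_times) - 1):
            dt = series.survey_times[k + 1] - series.survey_times[k]
            P = transition_matrix(c, e, dt)
            total -= np.log(P[row[k], row[k + 1]])
    return total


class TestTransitionMatrix:
    def test_no_time_elapsed_is_identity(self):
        assert np.allclose(transition_matrix(0.3, 0.3, 0.0), np.eye(2))

    def test_long_run_reaches_stationary_occupancy(self):
        P = transition_matrix(0.3, 0.3, 1e6)
        assert np.allclose(P, 0.5)
        P = transition_matrix(0.2, 0.6, 1e6)
        assert np.allclose(P[:, 1], 0.25)

    def test_one_year_step_matches_matrix_exponential(self):
        # frozen from expm([[-c, c], [e, -e]]) at c = e = 0.3, dt = 1
        P = transition_matrix(0.3, 0.3, 1.0)
        assert P[0, 1] == pytest.approx(0.225594, abs=1e-6)
        assert P[1, 1] == pytest.approx(0.774406, abs=1e-6)

    @pytest.mark.parametrize("c,e,dt", [(0.0, 0.3, 1.0), (0.3, -0.1, 1.0), (0.3, 0.3, -1.0)])
    def test_domain_errors(self, c, e, dt):
        with pytest.raises(ValueError):
            transition_matrix(c, e, dt)

    @given(
        c=st.floats(1e-3, 50.0),
        e=st.floats(1e-3, 50.0),
        dt=st.floats(0.0, 50.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rows_stochastic(self, c, e, dt):
        P = transition_matrix(c, e, dt)
        assert np.all(P >= 0) and np.all(P <= 1)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_colonisation_probability_monotone_in_dt_and_c(self):
        dts = np.linspace(0.1, 10.0, 40)
        p = [transition_matrix(0.3, 0.4, dt)[0, 1] for dt in dts]
        assert np.all(np.diff(p) > 0)
        cs = np.linspace(0.05, 2.0, 40)
        p = [transition_matrix(c, 0.4, 1.0)[0, 1] for c in cs]
        assert np.all(np.diff(p) > 0)


class TestCountTransitions:
    def test_single_species_enumeration(self):
        s = OccupancySeries("a", [0.0, 1.0, 2.0], [[0, 1, 1]])
        counts = count_transitions(s)
        assert np.array_equal(counts.counts(1.0), [0, 1, 0, 1])

    def test_two_year_gap_bucket(self):
        s = OccupancySeries("a", [1993.0, 1995.0], [[0, 0], [1, 0]])
        counts = count_transitions(s)
        assert list(counts.dts) == [2.0]
        assert np.array_equal(counts.counts(2.0), [1, 0, 1, 0])

    def test_total_count_is_species_times_pairs(self, rng):
        s = random_series(rng, n_species=100, n_surveys=30)
        assert count_transitions(s).n_transitions == 100 * 29

    def test_too_few_surveys_rejected(self):
        with pytest.raises(ValueError):
            OccupancySeries("a", [2000.0], [[1]])


class TestNegativeLogLikelihood:
    def test_frozen_single_transition_values(self):
        # -ln P(0->1) and -ln P(0->1) - ln P(1->1) at c = e = 0.3, dt = 1,
        # frozen from the closed-form transition probabilities
        counts = TransitionCounts({1.0: [0, 1, 0, 0]})
        assert negative_log_likelihood(counts, 0.3, 0.3) == pytest.approx(
            1.489018, abs=1e-6
        )
        counts = TransitionCounts({1.0: [0, 1, 0, 1]})
        assert negative_log_likelihood(counts, 0.3, 0.3) == pytest.approx(
            1.744677, abs=1e-6
        )

    @pytest.mark.parametrize("irregular", [False, True])
    def test_matches_bruteforce_product(self, rng, irregular):
        for _ in range(25):
            s = random_series(rng, n_species=4, n_surveys=5, irregular=irregular)
            counts = count_transitions(s)
            for c, e in [(0.3, 0.3), (0.9, 0.12)]:
                assert negative_log_likelihood(counts, c, e) == pytest.approx(
                    brute_force_nll(s, c, e), abs=1e-10
                )

    def test_permutation_and_split_invariance(self, rng):
        s = random_series(rng, n_species=8, n_surveys=10)
        perm = rng.permutation(8)
        s_perm = OccupancySeries("a", s.survey_times, s.states[perm])
        left = OccupancySeries("a", s.survey_times[:6], s.states[:, :6])
        right = OccupancySeries("a", s.survey_times[5:], s.states[:, 5:])
        for c, e in [(0.25, 0.4), (1.2, 0.8)]:
            base = negative_log_likelihood(count_transitions(s), c, e)
            assert negative_log_likelihood(count_transitions(s_perm), c, e) == pytest.approx(base, abs=1e-10)
            split = negative_log_likelihood(
                count_transitions(left), c, e
            ) + negative_log_likelihood(count_transitions(right), c, e)
            assert split == pytest.approx(base, abs=1e-10)


class TestClosedForm:
    def test_symmetric_counts_frozen_value(self):
        counts = TransitionCounts({1.0: [40, 10, 10, 40]})
        fit = closed_form_rates(counts)
        assert fit.c == pytest.approx(-np.log(0.6) / 2, abs=1e-10)
        assert fit.e == pytest.approx(fit.c, abs=1e-10)

    def test_doubling_dt_halves_rates(self):
        r1 = closed_form_rates(TransitionCounts({1.0: [40, 10, 10, 40]}))
        r2 = closed_form_rates(TransitionCounts({2.0: [40, 10, 10, 40]}))
        assert r2.c == pytest.approx(r1.c / 2, rel=1e-12)
        assert r2.e == pytest.approx(r1.e / 2, rel=1e-12)

    def test_reproduces_empirical_frequencies(self):
        counts = TransitionCounts({1.0: [55, 20, 11, 30]})
        fit = closed_form_rates(counts)
        P = transition_matrix(fit.c, fit.e, 1.0)
        assert P[0, 1] == pytest.approx(20 / 75, abs=1e-12)
        assert P[1, 0] == pytest.approx(11 / 41, abs=1e-12)

    def test_boundary_and_embedding_failures(self):
        with pytest.raises(ValueError, match="no colonisations"):
            closed_form_rates(TransitionCounts({1.0: [50, 0, 10, 40]}))
        with pytest.raises(ValueError, match="no valid continuous-time"):
            closed_form_rates(TransitionCounts({1.0: [10, 40, 45, 5]}))


class TestFitSiteRates:
    def test_matches_closed_form_on_regular_sampling(self, rng):
        for _ in range(5):
            s = markov_series(rng, c=0.3, e=0.4, n_species=30, n_surveys=20)
            cf = closed_form_rates(count_transitions(s))
            fit = fit_site_rates(s)
            assert fit.c == pytest.approx(cf.c, rel=1e-4)
            assert fit.e == pytest.approx(cf.e, rel=1e-4)

    def test_recovers_generating_rates(self):
        cfg = SimulationConfig(
            n_sites=3, n_species=200, survey_years=(1991, 2020),
            missing_survey_prob=0.0, range_model="none",
            beta0_c=np.log(0.3), beta1_c=0.0, beta0_e=np.log(0.4), beta1_e=0.0,
            seed=11,
        )
        ds = simulate_dataset(cfg)
        s = build_occupancy_series(ds.observations, "site002")
        fit = fit_site_rates(s)
        assert fit.c == pytest.approx(0.3, abs=0.05)
        assert fit.e == pytest.approx(0.4, abs=0.05)

    def test_interval_coverage_over_replicates(self):
        """Log-rate Wald intervals cover the generating rates ~nominally."""
        hits_c = hits_e = 0
        bias_c = bias_e = 0.0
        n_rep = 20
        for rep in range(n_rep):
            cfg = SimulationConfig(
                n_sites=1, n_species=100, survey_years=(1991, 2020),
                missing_survey_prob=0.0, range_model="none",
                beta0_c=np.log(0.3), beta1_c=0.0,
                beta0_e=np.log(0.4), beta1_e=0.0, seed=100 + rep,
            )
            ds = simulate_dataset(cfg)
            s = build_occupancy_series(ds.observations, "site001")
            fit = fit_site_rates(s)
            bias_c += fit.c - 0.3
            bias_e += fit.e - 0.4
            lo, hi = np.exp(np.log(fit.c) + 1.96 * np.array([-1, 1]) * fit.se_log_c)
            hits_c += lo <= 0.3 <= hi
            lo, hi = np.exp(np.log(fit.e) + 1.96 * np.array([-1, 1]) * fit.se_log_e)
            hits_e += lo <= 0.4 <= hi
        assert abs(bias_c / n_rep) < 0.05 * 0.3
        assert abs(bias_e / n_rep) < 0.05 * 0.4
        assert hits_c >= 0.9 * n_rep and hits_e >= 0.9 * n_rep

    def test_result_independent_of_species_order(self, rng):
        s = markov_series(rng, n_species=20, n_surveys=15)
        fit1 = fit_site_rates(s)
        s2 = OccupancySeries("a", s.survey_times, s.states[::-1])
        fit2 = fit_site_rates(s2)
        assert fit1.c == pytest.approx(fit2.c, rel=1e-8)

    def test_no_colonisations_pins_rate_with_warning(self):
        s = OccupancySeries("a", np.arange(5.0), [[1, 1, 1, 0, 0], [1, 0, 0, 0, 0]])
        with pytest.warns(BoundaryRateWarning):
            fit = fit_site_rates(s)
        assert fit.boundary_flag == "no_colonisations"
        assert fit.c == pytest.approx(1e-6)
        assert fit.e > 0.01

    def test_all_absent_matrix_rejected(self):
        s = OccupancySeries("a", np.arange(4.0), np.zeros((3, 4), dtype=int))
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_site_rates(s)


class TestCovariateModel:
    @staticmethod
    def _series_list(cfg):
        ds = simulate_dataset(cfg)
        universe = list(ds.sti["species"])
        return (
            [
                build_occupancy_series(ds.observations, sid, species_universe=universe)
                for sid in ds.sites["site_id"]
            ],
            ds.truth,
        )

    def test_null_effect_not_detected(self):
        cfg = SimulationConfig(
            n_sites=12, n_species=120, missing_survey_prob=0.0, range_model="none",
            beta1_c=0.0, beta1_e=0.0, seed=3,
        )
        series, truth = self._series_list(cfg)
        m = fit_covariate_model(series, truth["covariate"], "z")
        assert abs(m.beta1_c) < 2 * m.se[1]
        assert abs(m.beta1_e) < 2 * m.se[3]

    def test_recovers_link_parameters_within_3_se(self):
        cfg = SimulationConfig(
            n_sites=60, n_species=150, missing_survey_prob=0.05,
            range_model="none", seed=17,
        )
        series, truth = self._series_list(cfg)
        m = fit_covariate_model(series, truth["covariate"], "z")
        true = np.array([-1.0, -0.4, -0.8, 0.6])
        assert np.all(np.abs(m.params - true) < 3 * m.se)

    def test_constant_covariate_rejected(self, rng):
        series = [random_series(rng, 10, 8) for _ in range(4)]
        with pytest.raises(ValueError, match="constant"):
            fit_covariate_model(series, np.ones(4), "flat")

    def test_too_few_sites_rejected(self, rng):
        series = [random_series(rng, 10, 8) for _ in range(2)]
        with pytest.raises(ValueError, match="3 sites"):
            fit_covariate_model(series, np.array([0.0, 1.0]), "x")
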