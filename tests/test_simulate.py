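import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from jointmeta.simulate import (
    SimulationScenario,
    gompertz_from_moments,
    simulate_censoring,
    simulate_dataset,
    simulate_event_time,
)


class TestGompertzCalibration:
    def test_printed_shape_parameter(self):
        g = gompertz_from_moments(3.0, 0.5)
        assert g.theta1 == pytest.approx(2.5651, abs=5e-5)

    def test_printed_scale_parameter(self):
        g = gompertz_from_moments(3.0, 0.5)
        assert g.theta0 == pytest.approx(-7.330517, abs=5e-7)

    def test_unit_shape_reduction(self):
        # sigma0 = pi/sqrt(6) makes the shape exactly 1
        g = gompertz_from_moments(2.0, math.pi / math.sqrt(6.0))
        assert g.theta1 == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("sigma0", [0.0, -1.0])
    def test_nonpositive_sd_rejected(self, sigma0):
        with pytest.raises(ValueError):
            gompertz_from_moments(3.0, sigma0)


class TestEventTimeInversion:
    def test_closed_form_inverse_of_cumulative_hazard(self):
        # pick U so that -log U equals the Gompertz cumulative hazard at t*
        g = gompertz_from_moments(3.0, 0.5)
        t_star = 2.7
        Lam = math.exp(g.theta0) * (math.exp(g.theta1 * t_star) - 1.0) / g.theta1
        U = math.exp(-Lam)
        T = simulate_event_time(
            np.array([U]), np.array([0.0]), np.zeros((1, 2)), 0.0, g
        )
        assert T[0] == pytest.approx(t_star, rel=1e-10)

    def test_u_near_one_gives_time_near_zero(self):
        g = gompertz_from_moments(3.0, 0.5)
        T = simulate_event_time(
            np.array([1 - 1e-12]), np.array([0.0]), np.zeros((1, 2)), 0.0, g
        )
        assert T[0] == pytest.approx(0.0, abs=1e-6)

    def test_matches_numerical_root_of_integrated_hazard(self):
        # independent oracle: solve Lambda(t) = -log U numerically
        g = gompertz_from_moments(3.0, 0.5)
        alpha2, beta21 = 0.5, 0.7
        b = np.array([[0.3, -1.2]])
        treat = np.array([1.0])
        b3c = 0.25
        U = np.array([0.37])

        def cumhaz(t):
            # integral of exp(theta0 + theta1 s + beta21 + a2 (b0 + b1 s) + b3c)
            c = g.theta1 + alpha2 * b[0, 1]
            eta = g.theta0 + beta21 * treat[0] + alpha2 * b[0, 0] + b3c
            return math.exp(eta) * (math.exp(c * t) - 1.0) / c

        T = simulate_event_time(
            U, treat, b, b3c, g, beta21=beta21, alpha2=alpha2
        )
        root = brentq(lambda t: cumhaz(t) + math.log(U[0]), 1e-10, 100.0)
        assert T[0] == pytest.approx(root, rel=1e-9)

    def test_cure_condition_assigns_infinite_times(self):
        g = gompertz_from_moments(3.0, 0.5)
        # strongly negative random slope makes the effective shape negative
        b = np.array([[0.0, -10.0]])
        U = np.array([0.5])  # cure probability close to 1 here
        T = simulate_event_time(U, np.array([0.0]), b, 0.0, g, alpha2=1.0)
        assert np.isinf(T[0])

    def test_invalid_uniform_rejected(self):
        g = gompertz_from_moments(3.0, 0.5)
        with pytest.raises(ValueError):
            simulate_event_time(
                np.array([0.0]), np.array([0.0]), np.zeros((1, 2)), 0.0, g
            )


class TestCensoring:
    def test_exact_values(self):
        assert simulate_censoring(np.exp(-1.0), 1.0) == pytest.approx(1.0)
        assert simulate_censoring(1 - 1e-15, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_large_sample_mean(self):
        lam = math.exp(-0.426)
        rng = np.random.default_rng(1)
        T = simulate_censoring(rng.uniform(size=200_000), lam)
        assert T.mean() == pytest.approx(1.0 / lam, rel=0.01)

    @given(st.floats(0.01, 0.99), st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_u(self, u, lam):
        assert simulate_censoring(u, lam) >= simulate_censoring(min(u + 0.005, 0.995), lam)


class TestSimulateDataset:
    def test_reproducible_from_seed(self, toy_scenario):
        a = simulate_dataset(toy_scenario, seed=9)
        b = simulate_dataset(toy_scenario, seed=9)
        assert a.long.equals(b.long)
        assert a.surv.equals(b.surv)

    def test_exact_one_to_one_randomization(self, toy_dataset):
        counts = toy_dataset.surv.groupby("study")["treat"].sum()
        n = toy_dataset.surv.groupby("study").size()
        assert (counts == n // 2).all()

    def test_survival_invariants(self):
        ds, truth = simulate_dataset(
            SimulationScenario(K=2, n_per_study=200), seed=4, return_truth=True
        )
        m = ds.surv.merge(truth, on=["study", "subject"])
        events = m["status"] == 1
        # events come from finite latent event times, at the event time
        assert np.isfinite(m.loc[events, "T_event"]).all()
        np.testing.assert_allclose(
            m.loc[events, "survtime"], m.loc[events, "T_event"]
        )
        # infinite latent event times always resolve to censoring
        cured = np.isinf(m["T_event"])
        assert (m.loc[cured, "status"] == 0).all()
        np.testing.assert_allclose(m.loc[cured, "survtime"], m.loc[cured, "T_cens"])

    def test_longitudinal_truncation_monotone_in_survival_time(
        self, toy_scenario, toy_dataset
    ):
        m = toy_dataset.m_ki.rename("m").reset_index()
        merged = m.merge(toy_dataset.surv, on=["study", "subject"])
        # m_ki is exactly the number of scheduled times <= T_S, hence
        # non-decreasing in T_S
        grid = np.asarray(toy_scenario.meas_times)
        expect = [int((grid <= t).sum()) for t in merged["survtime"]]
        assert merged["m"].tolist() == expect
        order = merged.sort_values("survtime")["m"].to_numpy()
        assert (np.diff(order) >= 0).all()

    def test_noise_free_trajectories_are_the_fixed_line(self):
        sc = SimulationScenario(
            K=2,
            n_per_study=30,
            alpha2=0.0,
            alpha3=0.0,
            sigma_e2=1e-30,
            D=((0.0, 0.0), (0.0, 0.0)),
            A=((0.0, 0.0), (0.0, 0.0)),
        )
        ds = simulate_dataset(sc, seed=0)
        expect = 1.0 + 3.0 * ds.long["time"] + 2.0 * ds.long["treat"]
        np.testing.assert_allclose(ds.long["y"], expect, atol=1e-9)

    def test_null_event_times_match_target_moments(self):
        g = gompertz_from_moments(3.0, 0.5)
        rng = np.random.default_rng(12)
        n = 60_000
        T = simulate_event_time(
            rng.uniform(size=n), np.zeros(n), np.zeros((n, 2)), 0.0, g
        )
        assert T.mean() == pytest.approx(3.0, abs=0.02)
        assert T.std() == pytest.approx(0.5, abs=0.02)

    def test_between_study_variance_vanishes_without_study_effects(self):
        sc = SimulationScenario(
            K=6,
            n_per_study=300,
            alpha2=0.0,
            alpha3=0.0,
            A=((0.0, 0.0), (0.0, 0.0)),
        )
        ds = simulate_dataset(sc, seed=2)
        base = ds.long[ds.long["time"] == 0.0]
        means = base.groupby("study")["y"].mean()
        # study means vary only through D/n + sigma_e2/n sampling noise
        var_pred = (1.0 + sc.sigma_e2) / 300.0
        assert means.var() < 9.0 * var_pred

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError):
            SimulationScenario(D=((1.0, 2.0), (2.0, 1.0)))
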