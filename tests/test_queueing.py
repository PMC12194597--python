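"""Closed-form queue identities and the routing-threshold optimizer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vppflow.queueing import (
    CostSpec,
    InstabilityError,
    QueueParams,
    ScoreOC,
    brute_force_threshold,
    mm1_metrics,
    mm1_vacation_metrics,
    optimal_threshold,
    routing_cost,
)


class TestMM1:
    def test_closed_form_half_load(self):
        m = mm1_metrics(0.5, 1.0)
        assert m["mean_wait_in_queue"] == pytest.approx(1.0)
        assert m["utilization"] == pytest.approx(0.5)
        assert m["mean_number_in_system"] == pytest.approx(1.0)

    def test_zero_arrivals(self):
        m = mm1_metrics(0.0, 1.0)
        assert m["mean_wait_in_queue"] == 0.0
        assert m["mean_number_in_system"] == 0.0

    def test_critical_load_rejected(self):
        with pytest.raises(InstabilityError):
            mm1_metrics(1.0, 1.0)

    @given(st.floats(0.05, 0.95), st.floats(0.5, 20.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_littles_law_identity(self, rho, mu):
        lam = rho * mu
        m = mm1_metrics(lam, mu)
        w_total = m["mean_wait_in_queue"] + 1.0 / mu
        assert m["mean_number_in_system"] == pytest.approx(lam * w_total)


class TestVacationQueue:
    def test_decomposition_example(self):
        m = mm1_vacation_metrics(0.5, 1.0, 2.0)
        assert m["mean_wait_in_queue"] == pytest.approx(1.5)

    def test_vanishing_vacations_recover_mm1(self):
        vac = mm1_vacation_metrics(0.5, 1.0, 1e9)
        base = mm1_metrics(0.5, 1.0)
        assert vac["mean_wait_in_queue"] == pytest.approx(
            base["mean_wait_in_queue"], abs=1e-6)

    def test_wait_strictly_decreasing_in_theta(self):
        thetas = np.linspace(0.5, 10.0, 25)
        waits = [mm1_vacation_metrics(0.6, 1.0, t)["mean_wait_in_queue"] for t in thetas]
        assert all(a > b for a, b in zip(waits, waits[1:]))

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            mm1_vacation_metrics(0.5, 1.0, 0.0)


def _instance(seed):
    rng = np.random.default_rng(seed)
    params = QueueParams(
        lambda_total=float(rng.uniform(2.0, 8.0)),
        mu_vpp=float(rng.uniform(5.0, 12.0)),
        mu_main=float(rng.uniform(8.0, 14.0)),
        theta=float(rng.uniform(1.0, 6.0)),
        prevalence=float(rng.uniform(0.4, 0.9)),
    )
    cost = CostSpec(c_type1=float(rng.uniform(5, 60)), c_type2=float(rng.uniform(5, 60)))
    oc = ScoreOC.beta(
        a_bed=float(rng.uniform(3, 7)), b_bed=float(rng.uniform(1.2, 3)),
        a_no_bed=float(rng.uniform(1.2, 3)), b_no_bed=float(rng.uniform(3, 7)),
    )
    return params, cost, oc


class TestRoutingCost:
    def test_degenerate_no_vpp_split(self):
        params = QueueParams(4.0, 8.0, 10.0, 2.0, prevalence=0.7)
        cost = CostSpec(c_type1=30.0, c_type2=45.0)
        oc = ScoreOC.beta()
        got = routing_cost(0.0, params, cost, oc)
        expected = (mm1_metrics(4.0, 10.0)["mean_wait_in_queue"] * 60.0
                    + 45.0 * (1 - 0.7))
        assert got == pytest.approx(expected)

    def test_tau_out_of_range(self):
        params, cost, oc = _instance(0)
        with pytest.raises(ValueError):
            routing_cost(1.5, params, cost, oc)

    def test_unstable_split_returns_inf(self):
        params = QueueParams(9.0, 2.0, 9.5, 2.0, prevalence=0.5)
        assert routing_cost(1.0, params, CostSpec(), ScoreOC.beta()) == math.inf

    def test_cost_monotone_in_penalties_at_fixed_tau(self):
        params, _, oc = _instance(3)
        for tau in (0.2, 0.5, 0.8):
            base = routing_cost(tau, params, CostSpec(c_type1=10, c_type2=10), oc)
            up1 = routing_cost(tau, params, CostSpec(c_type1=25, c_type2=10), oc)
            up2 = routing_cost(tau, params, CostSpec(c_type1=10, c_type2=25), oc)
            assert up1 >= base and up2 >= base


class TestOptimalThreshold:
    def test_matches_brute_force_grid(self):
        for seed in range(6):
            params, cost, oc = _instance(seed)
            sol = optimal_threshold(params, cost, oc)
            tau_bf, cost_bf = brute_force_threshold(params, cost, oc, grid_step=1e-4)
            assert abs(sol.tau - tau_bf) <= 1e-3 + 1e-9 or \
                sol.expected_cost <= cost_bf + 1e-9

    def test_pure_bed_population_routes_nobody(self):
        # with no work credit, a VPP visit is pure loss when everyone needs a bed
        params = QueueParams(3.0, 8.0, 10.0, 2.0, prevalence=1.0,
                             requeue_load_frac=1.0)
        sol = optimal_threshold(params, CostSpec(), ScoreOC.beta())
        assert sol.tau == 0.0

    def test_threshold_depends_on_arrival_rate(self):
        _, cost, oc = _instance(1)
        lo = optimal_threshold(QueueParams(2.0, 8.0, 10.0, 2.0, 0.7), cost, oc)
        hi = optimal_threshold(QueueParams(8.5, 8.0, 10.0, 2.0, 0.7), cost, oc)
        assert lo.tau != hi.tau

    def test_threshold_monotone_in_misrouting_penalties(self):
        params, _, oc = _instance(2)
        taus_c1 = [optimal_threshold(params, CostSpec(c_type1=c, c_type2=30.0), oc).tau
                   for c in (5.0, 30.0, 90.0)]
        assert all(a >= b - 1e-3 for a, b in zip(taus_c1, taus_c1[1:]))
        taus_c2 = [optimal_threshold(params, CostSpec(c_type1=30.0, c_type2=c), oc).tau
                   for c in (5.0, 30.0, 90.0)]
        assert all(b >= a - 1e-3 for a, b in zip(taus_c2, taus_c2[1:]))

    def test_infeasible_instance_raises(self):
        params = QueueParams(50.0, 2.0, 2.5, 2.0, prevalence=0.8)
        with pytest.raises(InstabilityError):
            optimal_threshold(params, CostSpec(), ScoreOC.beta())

    def test_empirical_oc_from_scores(self):
        rng = np.random.default_rng(0)
        oc = ScoreOC.from_scores(rng.beta(5, 2, 400), rng.beta(2, 5, 400))
        assert oc.type1_frac(1.0) == pytest.approx(1.0)
        assert oc.no_bed_vpp_frac(0.0) == pytest.approx(0.0)
        assert oc.type1_frac(0.5) <= oc.no_bed_vpp_frac(0.5)
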