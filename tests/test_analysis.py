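"""Analysis operations: threshold detection, circle timescales and the
exponent fits, each validated on constructed inputs with known answers,
plus small end-to-end simulation checks."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from spatialsir.analysis import (
    CircleTimescales,
    PropagationCurve,
    SweepResult,
    beta_sweep,
    circle_timescales,
    fit_dmin,
    fit_dmin_first_passage,
    intervention_outcome,
    log_derivative_thresholds,
    propagation_curve,
    run_intervention_experiment,
)
from spatialsir.exceptions import ParameterError
from spatialsir.network import ModelParams, build_network
from spatialsir.sir import InterventionSpec


def make_curve(t, r, zeta=10, L=100, runs=None):
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    return PropagationCurve(
        t=t,
        rmax_mean=r,
        rmax_mean_active=r,
        n_active=np.full(t.size, 10),
        zeta=zeta,
        L=L,
        beta=0.5,
        replicates=10,
        degenerate=False,
        rmax_runs=runs,
        durations=None,
    )


class TestLogDerivativeThresholds:
    def test_recovers_two_sigmoid_inflections(self):
        # synthetic R(beta): log R is a sum of two smoothed steps with
        # centres 0.25 and 0.45 -> derivative peaks there
        params = ModelParams(L=100, zeta=10, k_intra=4, k_inter=1e-3)
        betas = np.linspace(0.1, 0.6, 26)
        # amplitudes keep R above the 1/N floor everywhere
        log_r = -5.0 + 1.8 * np.tanh((betas - 0.25) / 0.02) + 1.4 * np.tanh((betas - 0.45) / 0.02)
        sweep = SweepResult(
            params=params,
            betas=betas,
            final_r=np.exp(log_r)[None, :].repeat(2, axis=0),
            seed=0,
        )
        det = log_derivative_thresholds(sweep)
        step = betas[1] - betas[0]
        assert not det.collided
        assert abs(det.beta_1 - 0.25) <= step + 1e-9
        assert abs(det.beta_2 - 0.45) <= step + 1e-9

    def test_single_transition_flags_collision(self):
        params = ModelParams(L=100, zeta=10, k_intra=4, k_inter=1e-3)
        betas = np.linspace(0.1, 0.6, 21)
        log_r = -10 + 6 * np.tanh((betas - 0.3) / 0.03)
        sweep = SweepResult(
            params=params, betas=betas, final_r=np.exp(log_r)[None, :], seed=0
        )
        det = log_derivative_thresholds(sweep)
        assert det.collided
        assert abs(det.beta_1 - 0.3) <= 0.05

    def test_requires_enough_grid_points(self):
        params = ModelParams(L=20, zeta=10, k_intra=4, k_inter=0)
        sweep = SweepResult(
            params=params,
            betas=np.linspace(0.1, 0.5, 5),
            final_r=np.full((1, 5), 0.5),
            seed=0,
        )
        with pytest.raises(ParameterError):
            log_derivative_thresholds(sweep)


class TestCircleTimescales:
    def test_staircase_plateaus(self):
        z = 10
        r = np.concatenate(
            [np.zeros(10), np.full(6, z), np.full(4, 2 * z), np.full(3, 3 * z)]
        )
        curve = make_curve(np.arange(r.size), r, zeta=z)
        taus = circle_timescales(curve)
        assert taus.tau0 == 10
        assert taus.tau1 == 6
        assert taus.tau2 == 4
        assert taus.tau_x is not None

    def test_ballistic_curve_returns_absent_markers(self):
        z = 10
        t = np.arange(30)
        curve = make_curve(t, 15.0 * t, zeta=z, L=1000)
        taus = circle_timescales(curve)
        assert taus.tau0 is None and taus.tau1 is None and taus.tau2 is None

    def test_degenerate_curve(self):
        curve = make_curve(np.arange(5), np.zeros(5))
        curve.degenerate = True
        assert circle_timescales(curve) == CircleTimescales(None, None, None, None)


class TestFitDmin:
    def test_exact_power_law(self):
        t = np.arange(1, 400)
        r = t ** (1 / 1.13)
        curve = make_curve(t, r, zeta=1, L=10_000)
        assert fit_dmin(curve, window=(50, 350)) == pytest.approx(1.13, abs=1e-6)

    def test_linear_curve_gives_one(self):
        t = np.arange(1, 200)
        curve = make_curve(t, 2.0 * t, zeta=1, L=10_000)
        assert fit_dmin(curve, window=(10, 150)) == pytest.approx(1.0, abs=1e-9)

    def test_window_too_short_raises(self):
        t = np.arange(1, 100)
        curve = make_curve(t, t.astype(float), zeta=1, L=10_000)
        with pytest.raises(ParameterError):
            fit_dmin(curve, window=(10, 12))

    def test_first_passage_exact_power_law(self):
        # per-run series all follow r = t**(1/1.13) exactly
        t = np.arange(1, 400, dtype=float)
        r = t ** (1 / 1.13)
        runs = np.tile(np.concatenate([[0.0], r]), (12, 1))
        curve = make_curve(
            np.arange(r.size + 1), np.concatenate([[0.0], r]), zeta=10, L=400, runs=runs
        )
        est = fit_dmin_first_passage(curve, r_window=(30, 150))
        assert est == pytest.approx(1.13, abs=0.02)  # discretization of argmax

    def test_first_passage_needs_run_series(self):
        curve = make_curve(np.arange(10), np.arange(10, dtype=float))
        with pytest.raises(ParameterError):
            fit_dmin_first_passage(curve)


class TestBetaSweepSimulation:
    def test_subcritical_grid_stays_near_floor(self):
        params = ModelParams(L=40, zeta=10, k_intra=3, k_inter=0.05)
        sweep = beta_sweep(params, [0.05, 0.15, 0.25], replicates=10, seed=3)
        assert np.all(sweep.mean_r < 0.02)

    def test_beta_one_equals_origin_component_fraction(self):
        # deterministic flood: final_R must equal exactly the relative
        # size of the origin's connected component (csgraph oracle)
        params = ModelParams(L=30, zeta=10, k_intra=2.5, k_inter=0.02)
        net = build_network(params, seed=8)
        from spatialsir.sir import EpidemicParams, run_sir

        n = net.n_nodes
        adj = coo_matrix(
            (np.ones(net.n_edges), (net.edge_u, net.edge_v)), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels)
        for seed in range(5):
            run = run_sir(net, EpidemicParams(beta=1.0), seed=seed)
            assert run.final_r == pytest.approx(sizes[labels[run.origin]] / n)


class TestPropagationAndIntervention:
    def test_curve_shapes_and_monotonicity(self):
        params = ModelParams(L=40, zeta=10, k_intra=4, k_inter=0.1)
        curve = propagation_curve(params, beta=0.6, replicates=8, seed=2, max_steps=60)
        assert np.all(np.diff(curve.rmax_mean) >= 0)
        assert np.all(np.diff(curve.n_active) <= 0) or curve.n_active[0] == curve.replicates
        assert curve.rmax_mean[0] <= params.zeta

    def test_requires_supercritical_beta(self):
        params = ModelParams(L=40, zeta=10, k_intra=4, k_inter=0.1)
        with pytest.raises(ParameterError):
            propagation_curve(params, beta=0.2, replicates=2, seed=0, max_steps=10)

    def test_immediate_total_shutdown_freezes_origin(self):
        params = ModelParams(L=40, zeta=10, k_intra=4, k_inter=0.1)
        iv = InterventionSpec("social", t_x=0, new_value=0.0)
        runs = run_intervention_experiment(
            params, beta=0.6, interventions=[iv], replicates=6, seed=4, max_steps=50
        )
        outcome = intervention_outcome(runs, zeta=params.zeta)
        assert outcome.extent_at_intervention == 0.0
        assert outcome.final_extent == 0.0
        assert outcome.stopped

    def test_outcome_requires_interventions(self):
        params = ModelParams(L=40, zeta=10, k_intra=4, k_inter=0.1)
        from spatialsir.analysis import run_intervention_experiment

        runs = run_intervention_experiment(
            params, beta=0.6, interventions=[], replicates=3, seed=4, max_steps=30
        )
        with pytest.raises(ParameterError):
            intervention_outcome(runs, zeta=params.zeta)
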