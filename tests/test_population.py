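import numpy as np
import pytest
from dataclasses import replace

import bulbgenesis as bg
from bulbgenesis.population import (
    PopulationParams, steady_activities_symmetric4, resilience_symmetric4,
    population_rhs, integrate_populations, nullclines_symmetric4,
    fixed_point_symmetric4, discrete_fixed_point_prediction,
    extinction_threshold, optimal_threshold, pair_correlation_exact,
    correlation_expansion, threshold_scan, mixture_comparison,
    mixture_nullcline_size, integrate_mixture, PairPopulationModel,
)


def steep_params(**kw):
    base = dict(influx=1.0, inh_weight=0.05, resilience_threshold=0.02,
                survival_threshold=1.0, steepness=1e7, amplitude=1.0,
                spontaneous=0.1, similarity=0.2)
    base.update(kw)
    return PopulationParams(**base)


class TestActivities:
    def test_uninhibited_limit(self):
        p = steep_params()
        m_s, m_w = steady_activities_symmetric4(0.0, 0.0, p)
        assert m_s == pytest.approx((p.amplitude + p.spontaneous))
        assert m_w == pytest.approx(p.spontaneous)

    def test_activities_decrease_with_inhibition(self):
        p = steep_params()
        m0 = steady_activities_symmetric4(0.0, 0.0, p)
        m1 = steady_activities_symmetric4(10.0, 5.0, p)
        assert m1[0] < m0[0] and m1[1] < m0[1]

    def test_matches_explicit_network_solve(self):
        # independent oracle: build the 4-cell network with one lumped
        # granule cell per pair population and solve it exactly
        p = steep_params()
        a, b = 12.0, 3.0
        pairs = {(0, 1): a, (2, 3): a,
                 (0, 2): b, (0, 3): b, (1, 2): b, (1, 3): b}
        exc = np.zeros((6, 4), dtype=bool)
        wts = np.zeros((6, 4))
        for row, ((i, j), n) in enumerate(pairs.items()):
            exc[row, [i, j]] = True
            wts[row, [i, j]] = p.inh_weight * n
        net = bg.NetworkState(4, exc, exc.copy(), wts, p.spontaneous)
        train = bg.generate_symmetric4(0.0, amplitude=p.amplitude)
        ss = bg.solve_steady_state(net, train)
        m_s, m_w = steady_activities_symmetric4(a, b, p)
        np.testing.assert_allclose(sorted(ss.mitral[:, 0])[2:], m_s, atol=1e-12)
        np.testing.assert_allclose(sorted(ss.mitral[:, 0])[:2], m_w, atol=1e-12)


class TestPopulationRhs:
    def test_zero_influx_zero_state(self):
        p = steep_params(influx=0.0)
        assert population_rhs(0.0, [0.0, 0.0], p) == [0.0, 0.0]

    def test_guaranteed_survival_gives_pure_growth(self):
        p = steep_params(survival_threshold=0.0, resilience_threshold=0.0)
        da, db = population_rhs(0.0, [1.0, 1.0], p)
        assert da == pytest.approx(p.influx, abs=1e-9)
        assert db == pytest.approx(p.influx, abs=1e-9)

    def test_matches_stochastic_one_step_mean(self):
        # master-equation oracle: mean one-step change of the birth-death
        # process equals influx - (1 - P) n at the current state
        from bulbgenesis.neurogenesis import survival_probability
        p = steep_params(steepness=5.0)
        a, b = 20.0, 10.0
        r_a, r_b = resilience_symmetric4(a, b, p)
        params = bg.SurvivalParams(
            resilience_threshold=p.resilience_threshold,
            survival_threshold=p.survival_threshold, steepness=p.steepness,
            influx=0, connections_per_cell=2, inh_weight=p.inh_weight)
        P_a = survival_probability(r_a, params)
        rng = np.random.default_rng(0)
        draws = rng.random((4000, int(a))) < P_a
        mean_change = draws.sum(axis=1).mean() - a
        expected = population_rhs(0.0, [a, b], p)[0] - p.influx
        se = draws.sum(axis=1).std() / np.sqrt(4000)
        assert mean_change == pytest.approx(expected, abs=4 * se)


class TestFixedPoints:
    def test_closed_form_matches_ode_interior(self):
        p = steep_params(resilience_threshold=0.02)
        fp = fixed_point_symmetric4(p)
        a, b = integrate_populations(p, rtol=1e-11, atol=1e-12)
        assert fp.regime == "interior"
        assert a == pytest.approx(fp.coactive, rel=1e-5)
        assert b == pytest.approx(fp.interfering, rel=1e-5)

    def test_closed_form_matches_ode_floor(self):
        p = steep_params(resilience_threshold=0.3)
        fp = fixed_point_symmetric4(p)
        a, b = integrate_populations(p, rtol=1e-11, atol=1e-12)
        assert fp.regime == "floor"
        assert fp.interfering == pytest.approx(p.influx * p.dt)
        assert a == pytest.approx(fp.coactive, rel=1e-5)
        assert b == pytest.approx(fp.interfering, rel=1e-5)

    def test_continuity_across_extinction_threshold(self):
        p = steep_params()
        th_ext = extinction_threshold(p)
        lo = fixed_point_symmetric4(replace(p, resilience_threshold=th_ext - 1e-9))
        hi = fixed_point_symmetric4(replace(p, resilience_threshold=th_ext + 1e-9))
        assert lo.coactive == pytest.approx(hi.coactive, rel=1e-6)
        assert lo.interfering == pytest.approx(hi.interfering, rel=1e-4)

    def test_interior_coactive_independent_of_threshold(self):
        p = steep_params()
        fps = [fixed_point_symmetric4(replace(p, resilience_threshold=t))
               for t in (0.0, 0.01, 0.02)]
        assert len({round(f.coactive, 9) for f in fps}) == 1
        assert fps[0].interfering > fps[1].interfering > fps[2].interfering

    def test_nonnegative_populations(self):
        for th in np.linspace(0, 0.5, 11):
            fp = fixed_point_symmetric4(steep_params(resilience_threshold=th))
            assert fp.coactive >= 0 and fp.interfering >= 0

    def test_invalid_regime_raises(self):
        with pytest.raises(ValueError):
            fixed_point_symmetric4(steep_params(survival_threshold=10.0))

    def test_steepness_corrected_form_matches_finite_beta_ode(self):
        p = steep_params(inh_weight=0.01, steepness=50.0)
        fp = fixed_point_symmetric4(p, steepness_correction=True)
        a, b = integrate_populations(p, rtol=1e-10, atol=1e-12)
        assert a == pytest.approx(fp.coactive, rel=1e-4)
        assert b == pytest.approx(fp.interfering, rel=1e-4)

    def test_discrete_prediction_shifted_by_influx(self):
        p = steep_params(inh_weight=0.01, steepness=50.0)
        fp = fixed_point_symmetric4(p, steepness_correction=True)
        pred = discrete_fixed_point_prediction(p)
        assert pred.coactive == pytest.approx(fp.coactive - p.influx)
        assert pred.interfering == pytest.approx(fp.interfering - p.influx)


class TestNullclines:
    def test_interfering_nullcline_symmetry_and_monotonicity(self):
        p = steep_params()
        a_grid = np.linspace(0, 25, 15)
        b_null = nullclines_symmetric4(p, a_grid, "interfering")
        valid = ~np.isnan(b_null)
        # more co-active inhibition requires fewer interfering cells on the
        # nullcline (inhibition lowers activity)
        assert np.all(np.diff(b_null[valid]) < 0)

    def test_nullcline_points_satisfy_resilience_equation(self):
        p = steep_params()
        a_grid = np.array([0.0, 5.0, 10.0])
        b_null = nullclines_symmetric4(p, a_grid, "interfering")
        for a, b in zip(a_grid, b_null):
            _, r_b = resilience_symmetric4(a, b, p)
            assert r_b == pytest.approx(p.survival_threshold, abs=1e-8)

    def test_ode_nullcline_converges_to_steep_approximation(self):
        # as steepness grows the finite-beta fixed point approaches the
        # steep-limit nullcline intersection (sup-norm over the scan)
        p0 = steep_params(inh_weight=0.01)
        target = fixed_point_symmetric4(p0)
        errs = []
        for beta in (50.0, 500.0, 5000.0):
            a, b = integrate_populations(replace(p0, steepness=beta),
                                         rtol=1e-10, atol=1e-12)
            errs.append(max(abs(a - target.coactive),
                            abs(b - target.interfering)))
        assert errs[0] > errs[1] > errs[2]

    def test_trajectory_growth_then_capture(self):
        # from zero both populations first grow linearly at the influx rate
        p = steep_params()
        sol = integrate_populations(p, dense=True, rtol=1e-8, atol=1e-10)
        t_early = sol.t[sol.t < 1.0]
        a_early = np.interp(t_early, sol.t, sol.y[0])
        np.testing.assert_allclose(a_early, p.influx * t_early, rtol=1e-3,
                                   atol=1e-6)
        # and end on the fixed point
        fp = fixed_point_symmetric4(p)
        assert sol.y[0, -1] == pytest.approx(fp.coactive, rel=1e-4)


class TestOptimalThreshold:
    def test_closed_form_value(self):
        p = steep_params()
        assert optimal_threshold(p) == pytest.approx(
            p.spontaneous * p.survival_threshold / (2 * p.amplitude))

    def test_extinction_threshold_converges_to_optimum_at_small_influx(self):
        gaps = []
        for alpha in (1.0, 0.1, 0.01):
            p = steep_params(influx=alpha)
            gaps.append(abs(extinction_threshold(p) - optimal_threshold(p)))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3

    def test_bisection_oracle_finds_same_extinction_point(self):
        # smallest threshold at which the interfering population reaches its
        # turnover floor, located by bisection on the closed-form fixed point
        p = steep_params(influx=0.1)
        lo, hi = 0.0, 0.2
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            fp = fixed_point_symmetric4(replace(p, resilience_threshold=mid))
            if fp.interfering <= p.influx * p.dt + 1e-12:
                hi = mid
            else:
                lo = mid
        assert hi == pytest.approx(extinction_threshold(p), abs=1e-9)

    def test_scan_minimum_at_optimum(self):
        p = steep_params(influx=0.01)
        thetas = np.round(np.arange(0.0, 0.101, 0.005), 4)
        scan = threshold_scan(p, thetas, method="closed_form")
        assert scan["argmin_threshold"] == pytest.approx(
            optimal_threshold(p), abs=0.005)
        # interfering population at the floor above the optimum
        above = scan["thresholds"] > optimal_threshold(p) + 0.005
        assert np.all(scan["interfering"][above] <= p.influx * p.dt + 1e-9)


class TestCorrelation:
    def test_no_network_limit_equals_input_correlation(self):
        p = steep_params()
        from bulbgenesis.metrics import pearson
        ens = bg.generate_symmetric4(p.similarity, amplitude=p.amplitude)
        r_in = pearson(ens[0].values, ens[1].values)
        assert pair_correlation_exact(0.0, 0.0, p) == pytest.approx(r_in)
        assert correlation_expansion(0.0, 0.0, p) == pytest.approx(
            1 - p.similarity ** 2)

    def test_partial_derivative_signs(self):
        p = steep_params()
        a, b, h = 10.0, 3.0, 1e-5
        for f in (pair_correlation_exact, correlation_expansion):
            da = (f(a + h, b, p) - f(a - h, b, p)) / (2 * h)
            db = (f(a, b + h, p) - f(a, b - h, p)) / (2 * h)
            assert da < 0 < db

    def test_exact_formula_matches_network_solve(self):
        # independent oracle: solve the 4-cell network for the test stimuli
        # and compute the Pearson correlation of the mitral outputs
        from bulbgenesis.metrics import pearson
        p = steep_params(similarity=0.35)
        a, b = 14.0, 2.5
        pairs = {(0, 1): a, (2, 3): a,
                 (0, 2): b, (0, 3): b, (1, 2): b, (1, 3): b}
        exc = np.zeros((6, 4), dtype=bool)
        wts = np.zeros((6, 4))
        for row, ((i, j), n) in enumerate(pairs.items()):
            exc[row, [i, j]] = True
            wts[row, [i, j]] = p.inh_weight * n
        net = bg.NetworkState(4, exc, exc.copy(), wts, p.spontaneous)
        probe = bg.generate_symmetric4(p.similarity, amplitude=p.amplitude)
        ss = bg.solve_steady_state(net, probe)
        r_net = pearson(ss.mitral[:, 0], ss.mitral[:, 1])
        assert pair_correlation_exact(a, b, p) == pytest.approx(r_net,
                                                                abs=1e-12)

    def test_expansion_error_is_higher_order_in_similarity(self):
        p0 = steep_params()
        a, b = 10.0, 2.0
        errs = []
        for delta in (0.2, 0.1, 0.05):
            p = replace(p0, similarity=delta)
            errs.append(abs(correlation_expansion(a, b, p)
                            - pair_correlation_exact(a, b, p)) / delta ** 2)
        # error relative to delta^2 still shrinks -> higher than second order
        assert errs[0] > errs[1] > errs[2]


class TestMixtureComparison:
    def test_ordering_holds_generic(self):
        comp = mixture_comparison(steep_params(resilience_threshold=0.02))
        assert comp.ordering_holds
        assert comp.p_mixed_alt < comp.p_mixture < comp.p_pure_alt

    def test_closed_form_matches_ode(self):
        p = steep_params(resilience_threshold=0.02)
        assert integrate_mixture(p) == pytest.approx(
            mixture_nullcline_size(p), rel=1e-5)

    def test_degenerate_symmetry_point_equalizes_populations(self):
        # when (E+2 s0)/(theta+T/4) = 12E/T - 2 the alternating protocol's
        # two populations and the mixture population coincide
        E, T, th = 1.0, 1.0, 0.05
        Q = 12 * E / T - 2
        s0 = ((th + T / 4) * Q - E) / 2
        p = steep_params(amplitude=E, survival_threshold=T,
                         resilience_threshold=th, spontaneous=s0)
        fp = fixed_point_symmetric4(p)
        p_mix = mixture_nullcline_size(p)
        assert fp.coactive == pytest.approx(fp.interfering, rel=1e-9)
        assert p_mix == pytest.approx(fp.coactive, rel=1e-9)


class TestPairPopulationModel:
    def test_general_model_reproduces_reduced_fixed_point(self):
        p = steep_params(inh_weight=0.01, steepness=200.0)
        train = bg.generate_symmetric4(0.0, amplitude=p.amplitude)
        model = PairPopulationModel(train.matrix, p)
        n = model.steady_state(rtol=1e-9)
        sizes = dict(zip(model.pairs, n))
        a_general = np.mean([sizes[(0, 1)], sizes[(2, 3)]])
        b_general = np.mean([sizes[(0, 2)], sizes[(0, 3)],
                             sizes[(1, 2)], sizes[(1, 3)]])
        a_red, b_red = integrate_populations(p, rtol=1e-9, atol=1e-11)
        assert a_general == pytest.approx(a_red, rel=1e-4)
        assert b_general == pytest.approx(b_red, rel=1e-3)

    def test_connectivity_assembly(self):
        p = steep_params()
        model = PairPopulationModel(np.eye(3), p)
        n = np.zeros(model.n_pairs)
        n[model.pairs.index((0, 1))] = 2.0
        W = model.connectivity(n)
        w = p.inh_weight
        expected = np.array([[2 * w, 2 * w, 0],
                             [2 * w, 2 * w, 0],
                             [0, 0, 0]])
        np.testing.assert_allclose(W, expected)
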