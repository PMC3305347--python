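import numpy as np
import pytest

import bulbgenesis as bg
from bulbgenesis.network import save_network, load_network


def damped_iteration_oracle(net, ensemble, rect=False, iters=200_000,
                            eta=0.3, tol=1e-12):
    """Independent fixed-point iteration of the steady-state equations."""
    E = ensemble.matrix
    drive = E.T + net.spontaneous
    C = net.exc_sources.astype(float)
    Bw = net.inh_weights
    relu = (lambda x: np.maximum(x, 0.0)) if rect else (lambda x: x)
    m = drive.copy()
    g = net.exc_weight * (C @ relu(m))
    for _ in range(iters):
        new_m = drive - Bw.T @ relu(g)
        new_g = net.exc_weight * (C @ relu(new_m))
        if max(np.abs(new_m - m).max(),
               np.abs(new_g - g).max() if g.size else 0.0) < tol:
            break
        m = (1 - eta) * m + eta * new_m
        g = (1 - eta) * g + eta * new_g
    return m, g


class TestSolveSteadyState:
    def test_no_granule_cells_passthrough(self, symmetric4_probe):
        net = bg.NetworkState.empty(4, spontaneous=0.25)
        ss = bg.solve_steady_state(net, symmetric4_probe)
        np.testing.assert_allclose(ss.mitral,
                                   symmetric4_probe.matrix.T + 0.25)
        assert ss.residual == 0.0

    def test_zero_stimulus_gives_spontaneous_activity(self):
        net = bg.NetworkState.empty(3, spontaneous=0.4)
        zero = bg.StimulusEnsemble([bg.GlomerularPattern("0", [0.0, 0, 0])])
        ss = bg.solve_steady_state(net, zero)
        np.testing.assert_allclose(ss.mitral, 0.4)

    def test_linear_solve_matches_damped_iteration_toy3(self, rng):
        # three mitral cells, a large co-active population on cells 1-2
        ens = bg.generate_toy3(1.0, 0.2)
        net = bg.NetworkState.empty(3, spontaneous=0.1)
        exc = np.zeros((60, 3), dtype=bool)
        exc[:40, [0, 1]] = True          # co-active population
        exc[40:50, [0, 2]] = True
        exc[50:, [1, 2]] = True
        w = np.where(exc, 0.01, 0.0)
        net = bg.NetworkState(3, exc, exc.copy(), w, 0.1)
        ss = bg.solve_steady_state(net, ens)
        m_oracle, g_oracle = damped_iteration_oracle(net, ens)
        np.testing.assert_allclose(ss.mitral, m_oracle, atol=1e-8)
        np.testing.assert_allclose(ss.granule, g_oracle, atol=1e-8)

    def test_linear_solve_matches_iteration_at_scale(self, rng):
        # mid-scale network: 50 mitral, 500 granule cells
        net = bg.NetworkState.empty(50, spontaneous=0.2)
        net = net.add_granule_cells(500, 8, 0.002, rng)
        ens = bg.StimulusEnsemble(
            [bg.GlomerularPattern(f"s{i}", rng.random(50)) for i in range(3)])
        ss = bg.solve_steady_state(net, ens)
        m_oracle, _ = damped_iteration_oracle(net, ens)
        assert np.abs(ss.mitral - m_oracle).max() < 1e-8
        assert ss.residual < 1e-9

    def test_rectified_agrees_with_linear_when_positive(self, rng):
        net = bg.NetworkState.empty(6, spontaneous=0.5)
        net = net.add_granule_cells(20, 2, 0.005, rng)
        ens = bg.StimulusEnsemble(
            [bg.GlomerularPattern("s", 0.5 + rng.random(6))])
        lin = bg.solve_steady_state(net, ens, coupling="linear")
        rect = bg.solve_steady_state(net, ens, coupling="rectified", tol=1e-12)
        assert np.all(lin.mitral > 0)
        np.testing.assert_allclose(rect.mitral, lin.mitral, atol=1e-8)

    def test_rectified_matches_rectified_oracle(self, rng):
        # strong inhibition drives some activities negative -> rectifier binds
        net = bg.NetworkState.empty(5, spontaneous=0.05)
        net = net.add_granule_cells(80, 2, 0.05, rng)
        ens = bg.StimulusEnsemble(
            [bg.GlomerularPattern("s", np.array([2.0, 0.1, 0, 1.5, 0.0]))])
        rect = bg.solve_steady_state(net, ens, coupling="rectified", tol=1e-12)
        m_oracle, _ = damped_iteration_oracle(net, ens, rect=True)
        np.testing.assert_allclose(rect.mitral, m_oracle, atol=1e-7)

    def test_singular_system_raises(self):
        # cross-wired 2-cell network with unit loop gain: I + W is singular
        exc = np.array([[False, True], [True, False]])
        inh = np.array([[True, False], [False, True]])
        w = np.where(inh, 1.0, 0.0)
        net = bg.NetworkState(2, exc, inh, w, 0.0)
        ens = bg.StimulusEnsemble([bg.GlomerularPattern("s", [1.0, 1.0])])
        with pytest.raises(np.linalg.LinAlgError):
            bg.solve_steady_state(net, ens)


class TestEffectiveConnectivity:
    def test_empty_network_zero_matrix(self):
        net = bg.NetworkState.empty(5)
        np.testing.assert_array_equal(bg.effective_connectivity(net),
                                      np.zeros((5, 5)))

    def test_single_cell_direct_count(self):
        exc = np.zeros((1, 4), dtype=bool)
        exc[0, [1, 2]] = True
        net = bg.NetworkState(4, exc, exc.copy(),
                              np.where(exc, 0.3, 0.0), 0.0)
        W = bg.effective_connectivity(net)
        expected = np.zeros((4, 4))
        expected[np.ix_([1, 2], [1, 2])] = 0.3
        np.testing.assert_allclose(W, expected)

    def test_reciprocal_uniform_network_symmetric_psd(self, small_network):
        W = bg.effective_connectivity(small_network)
        np.testing.assert_allclose(W, W.T)
        eigs = np.linalg.eigvalsh(W)
        assert eigs.min() > -1e-12   # Gram-matrix structure

    def test_shared_cell_count_identity(self, small_network):
        # under uniform weights W = w * (# granule cells shared by i and j)
        C = small_network.exc_sources.astype(float)
        shared = C.T @ C
        np.testing.assert_allclose(bg.effective_connectivity(small_network),
                                   0.02 * shared)


class TestRewire:
    def test_fraction_zero_is_identity(self, small_network, rng):
        out = bg.rewire(small_network, 0.0, rng)
        np.testing.assert_array_equal(out.inh_targets,
                                      small_network.inh_targets)
        np.testing.assert_allclose(
            bg.effective_connectivity(out),
            bg.effective_connectivity(small_network))

    def test_half_fraction_moves_half_the_targets(self, rng):
        net = bg.NetworkState.empty(40, 0.0)
        net = net.add_granule_cells(30, 8, 0.01, rng)
        out = bg.rewire(net, 0.5, rng)
        kepts = []
        for j in range(30):
            kept = (net.inh_targets[j] & out.inh_targets[j]).sum()
            # 4 targets kept; a redirected synapse may land by chance on a
            # previously removed target (collision policy), never below 4
            assert 4 <= kept <= 8
            assert out.inh_targets[j].sum() == 8
            kepts.append(kept)
        assert np.mean(kepts) == pytest.approx(4 + 4 * 4 / 32, abs=0.8)
        np.testing.assert_array_equal(out.exc_sources, net.exc_sources)

    def test_full_rewiring_decouples_targets_from_sources(self, rng):
        M, K, N = 30, 6, 400
        net = bg.NetworkState.empty(M, 0.0)
        net = net.add_granule_cells(N, K, 0.01, rng)
        out = bg.rewire(net, 1.0, rng)
        overlap = (out.inh_targets & out.exc_sources).sum() / N
        # expected overlap of two independent K-subsets of M cells
        assert overlap == pytest.approx(K * K / M, abs=0.35)

    def test_weight_mass_preserved(self, small_network, rng):
        out = bg.rewire(small_network, 0.7, rng)
        assert out.inh_weights.sum() == pytest.approx(
            small_network.inh_weights.sum())


class TestHeterogenizeWeights:
    def test_zero_delta_identity(self, small_network, rng):
        out = bg.heterogenize_weights(small_network, "two_point", 0.0, rng)
        np.testing.assert_array_equal(out.inh_weights,
                                      small_network.inh_weights)

    def test_two_point_full_delta_silences_half(self, rng):
        net = bg.NetworkState.empty(20, 0.0)
        net = net.add_granule_cells(300, 4, 0.01, rng)
        out = bg.heterogenize_weights(net, "two_point", 0.01, rng)
        vals = out.inh_weights[out.inh_targets]
        frac_zero = np.mean(vals == 0.0)
        assert frac_zero == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("mode", ["two_point", "uniform"])
    def test_mean_weight_preserved(self, mode, rng):
        net = bg.NetworkState.empty(20, 0.0)
        net = net.add_granule_cells(500, 4, 0.01, rng)
        out = bg.heterogenize_weights(net, mode, 0.008, rng)
        vals = out.inh_weights[out.inh_targets]
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean() - 0.01) < 4 * se

    def test_delta_exceeding_weight_raises(self, small_network, rng):
        with pytest.raises(ValueError):
            bg.heterogenize_weights(small_network, "uniform", 0.05, rng)


class TestRescaleSelfInhibition:
    def test_gamma_one_identity(self, rng):
        W = rng.random((6, 6))
        np.testing.assert_allclose(bg.rescale_self_inhibition(W, 1.0), W)

    def test_row_sums_preserved_exactly(self, rng):
        W = rng.random((8, 8)) + np.diag(rng.random(8))
        for gamma in (0.0, 0.3, 1.7):
            out = bg.rescale_self_inhibition(W, gamma)
            np.testing.assert_allclose(out.sum(axis=1), W.sum(axis=1),
                                       rtol=0, atol=1e-12)
            np.testing.assert_allclose(np.diag(out), gamma * np.diag(W))

    def test_two_by_two_closed_form(self):
        out = bg.rescale_self_inhibition(np.array([[2.0, 1.0], [1.0, 2.0]]), 0.0)
        np.testing.assert_allclose(out, [[0.0, 3.0], [3.0, 0.0]])

    def test_infeasible_gamma_raises(self):
        W = np.array([[3.0, 0.1], [0.1, 3.0]])
        with pytest.raises(ValueError):
            bg.rescale_self_inhibition(W, 2.0)


class TestAsymmetryRatio:
    def test_symmetric_matrix_zero(self, rng):
        W = rng.random((5, 5))
        assert bg.asymmetry_ratio(W + W.T) == pytest.approx(0.0)

    def test_constructed_twenty_percent(self, rng):
        S = rng.random((6, 6))
        S = S + S.T
        A = rng.random((6, 6))
        A = A - A.T
        A *= 0.2 * np.linalg.norm(S) / np.linalg.norm(A)
        assert bg.asymmetry_ratio(S + A) == pytest.approx(0.2)

    def test_scale_invariant(self, small_network, rng):
        W = bg.effective_connectivity(
            bg.heterogenize_weights(small_network, "two_point", 0.02, rng))
        assert bg.asymmetry_ratio(3.7 * W) == pytest.approx(
            bg.asymmetry_ratio(W))

    def test_zero_symmetric_part_raises(self):
        with pytest.raises(ZeroDivisionError):
            bg.asymmetry_ratio(np.array([[0.0, 1.0], [-1.0, 0.0]]))


class TestStabilitySpectrum:
    def test_uncoupled_network_relaxation_rate(self):
        net = bg.NetworkState.empty(4, 0.1)
        eigs = bg.stability_spectrum(net)
        np.testing.assert_allclose(eigs.real, -1.0)

    def test_eigenvalues_continuous_in_weak_coupling(self, rng):
        net0 = bg.NetworkState.empty(6, 0.1)
        net0 = net0.add_granule_cells(12, 2, 0.0, rng)
        base = np.sort(bg.stability_spectrum(net0).real)
        net_w = net0.copy()
        net_w.inh_weights = np.where(net_w.inh_targets, 1e-6, 0.0)
        pert = np.sort(bg.stability_spectrum(net_w).real)
        np.testing.assert_allclose(pert, base, atol=1e-2)

    def test_reciprocal_network_stable(self, small_network):
        assert bg.stability_spectrum(small_network).real.max() < 0

    def test_rewired_heterogeneous_network_stable(self, small_network, rng):
        net = bg.rewire(small_network, 0.5, rng)
        net = bg.heterogenize_weights(net, "two_point", 0.02, rng)
        assert bg.stability_spectrum(net).real.max() < 0


def test_network_snapshot_roundtrip(tmp_path, small_network):
    path = tmp_path / "net.h5"
    save_network(small_network, path)
    loaded = load_network(path)
    np.testing.assert_array_equal(loaded.exc_sources,
                                  small_network.exc_sources)
    np.testing.assert_array_equal(loaded.inh_targets,
                                  small_network.inh_targets)
    np.testing.assert_allclose(loaded.inh_weights, small_network.inh_weights)
    assert loaded.spontaneous == small_network.spontaneous


def test_validate_degree_constraint(small_network):
    small_network.validate(connections_per_cell=3)
    with pytest.raises(ValueError):
        small_network.validate(connections_per_cell=4)
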