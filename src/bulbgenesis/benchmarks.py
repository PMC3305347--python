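"""End-to-end property benchmarks of the simulator and its mean-field theory.

Each function recomputes one headline property from scratch — generating the
stimuli, running the discrete simulator and/or the population equations, and
measuring the result — and returns a plain dict of numbers.  They are the
computational core of ``scripts/acceptance.py`` and of the acceptance test
suite; problem sizes are chosen so the full battery completes in a few
minutes on one CPU (see docs/methods.md for the scaling rationale).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import binomtest, mannwhitneyu, spearmanr

import bulbgenesis as bg
from bulbgenesis.experiments import (ExperimentConfig, run_enrichment_protocols,
                                     run_novelty, response_fraction_curve,
                                     default_survival_params, natural_ensemble)
from bulbgenesis.metrics import correlation_matrix
from bulbgenesis.neurogenesis import detect_plateau
from bulbgenesis.population import (PopulationParams, fixed_point_symmetric4,
                                    discrete_fixed_point_prediction,
                                    integrate_populations, optimal_threshold,
                                    threshold_scan, mixture_comparison,
                                    integrate_mixture, mixture_nullcline_size)

__all__ = [
    "meanfield_benchmark", "threshold_benchmark", "protocol_benchmark",
    "reciprocity_benchmark", "novelty_benchmark", "selfregulation_benchmark",
]

#: weak-coupling study conditions of the two-connection comparison
MEANFIELD_STEEP = dict(influx=1.0, inh_weight=0.05, resilience_threshold=0.02,
                       survival_threshold=1.0, steepness=1e8, amplitude=1.0,
                       spontaneous=0.1)
MEANFIELD_DISCRETE = dict(MEANFIELD_STEEP, inh_weight=0.002, steepness=50.0)


def _pair_population_sizes(net: bg.NetworkState) -> tuple[float, float]:
    """Mean sizes of the co-active and interfering K=2 populations."""
    counts: dict[tuple, int] = {}
    for j in range(net.n_granule):
        src = tuple(np.flatnonzero(net.exc_sources[j]))
        counts[src] = counts.get(src, 0) + 1
    coactive = np.mean([counts.get(p, 0) for p in [(0, 1), (2, 3)]])
    interfering = np.mean([counts.get(p, 0)
                           for p in [(0, 2), (0, 3), (1, 2), (1, 3)]])
    return float(coactive), float(interfering)


def meanfield_benchmark(seed: int = 0, n_seeds: int = 16,
                        n_steps: int = 2500) -> dict:
    """Closed-form fixed points vs ODE integration vs discrete simulation.

    Steep-sigmoid regime: the closed forms must agree with forward Radau
    integration of the population equations in both the interior and the
    interference-extinct regime.  Weak-coupling regime (small weight, large
    populations, finite steepness): ``n_seeds`` independent K=2 simulations
    on the collapsed-pair training ensemble are compared against the
    mean-field prediction for the discrete-time process.
    """
    out: dict = {}
    # --- steep limit: closed form vs forward ODE integration
    rel_errors = []
    for th in (0.02, 0.3):            # interior and floor regimes
        pp = PopulationParams(**{**MEANFIELD_STEEP,
                                 "resilience_threshold": th})
        fp = fixed_point_symmetric4(pp)
        a, b = integrate_populations(pp, rtol=1e-12, atol=1e-13)
        rel_errors.append(abs(a - fp.coactive) / fp.coactive)
        rel_errors.append(abs(b - fp.interfering) / max(fp.interfering,
                                                        pp.influx))
        out[f"closed_form_coactive_theta{th}"] = fp.coactive
        out[f"closed_form_interfering_theta{th}"] = fp.interfering
    out["ode_max_rel_error"] = float(max(rel_errors))

    # --- weak coupling: discrete K=2 simulation vs mean-field prediction
    pp = PopulationParams(**MEANFIELD_DISCRETE)
    pred = discrete_fixed_point_prediction(pp)
    params = bg.SurvivalParams(
        resilience_threshold=pp.resilience_threshold,
        survival_threshold=pp.survival_threshold, steepness=pp.steepness,
        influx=6, connections_per_cell=2, inh_weight=pp.inh_weight,
        spontaneous=pp.spontaneous)
    train = bg.generate_symmetric4(0.0)
    a_vals, b_vals = [], []
    for s in range(seed, seed + n_seeds):
        rng = np.random.default_rng(s)
        net = bg.NetworkState.empty(4, pp.spontaneous)
        for step in range(n_steps):
            net, _, _ = bg.evolution_step(net, train, params, rng, step=step)
        a, b = _pair_population_sizes(net)
        a_vals.append(a)
        b_vals.append(b)
    a_vals, b_vals = np.asarray(a_vals), np.asarray(b_vals)
    out.update({
        "discrete_coactive_mean": float(a_vals.mean()),
        "discrete_coactive_se": float(a_vals.std(ddof=1) / np.sqrt(n_seeds)),
        "discrete_interfering_mean": float(b_vals.mean()),
        "discrete_interfering_se": float(b_vals.std(ddof=1) / np.sqrt(n_seeds)),
        "predicted_coactive": pred.coactive,
        "predicted_interfering": pred.interfering,
        "n_seeds": n_seeds,
    })
    out["coactive_z"] = abs(out["discrete_coactive_mean"]
                            - pred.coactive) / out["discrete_coactive_se"]
    out["interfering_z"] = abs(out["discrete_interfering_mean"]
                               - pred.interfering) / out["discrete_interfering_se"]
    return out


def threshold_benchmark(grid_step: float = 0.005) -> dict:
    """Resilience-threshold scan of the population model (forward ODE).

    The within-pair output correlation of the similar test stimuli must be
    minimized at the closed-form optimal threshold (to grid resolution), and
    the interfering population must sit at its turnover floor above it.
    Small influx keeps the finite-influx extinction point close to the
    idealized optimum.
    """
    pp = PopulationParams(influx=0.01, inh_weight=0.05,
                          resilience_threshold=0.0, survival_threshold=1.0,
                          steepness=1e7, amplitude=1.0, spontaneous=0.1,
                          similarity=0.2)
    thetas = np.round(np.arange(0.0, 0.1 + grid_step / 2, grid_step), 6)
    scan = threshold_scan(pp, thetas, method="ode")
    opt = optimal_threshold(pp)
    above = thetas > opt + grid_step / 2
    floor = pp.influx * pp.dt
    return {
        "optimal_threshold_closed_form": opt,
        "argmin_threshold_scan": scan["argmin_threshold"],
        "grid_step": grid_step,
        "correlation_at_optimum": float(
            scan["correlation"][np.argmin(np.abs(thetas - opt))]),
        "max_interfering_above_optimum": float(
            scan["interfering"][above].max()),
        "turnover_floor": floor,
        "n_grid": int(len(thetas)),
    }


def protocol_benchmark(seed: int = 0, n_seeds: int = 16,
                       n_steps: int = 600) -> dict:
    """Alternating vs mixture enrichment, analytically and in simulation.

    Analytic model: the mixture-protocol population falls strictly between
    the alternating protocol's interfering (mixed) and co-active (pure)
    populations, and the closed forms match forward ODE integration.  Full
    simulation: lower test-mixture correlations under the mixture protocol
    at eight connections per cell, no significant difference at one.
    """
    pp = PopulationParams(influx=1.0, inh_weight=0.05,
                          resilience_threshold=0.02, survival_threshold=1.0,
                          steepness=1e7, amplitude=1.0, spontaneous=0.1)
    comp = mixture_comparison(pp)
    p_mix_ode = integrate_mixture(pp)
    cfg = ExperimentConfig(experiment="enrichment_protocols", n_steps=n_steps,
                           record_every=50,
                           seeds=list(range(seed, seed + n_seeds)))
    rep = run_enrichment_protocols(cfg)
    return {
        "analytic_p_mixed_alt": comp.p_mixed_alt,
        "analytic_p_mixture": comp.p_mixture,
        "analytic_p_pure_alt": comp.p_pure_alt,
        "analytic_ordering_holds": bool(comp.ordering_holds),
        "analytic_p_mixture_ode_rel_error": abs(
            p_mix_ode - mixture_nullcline_size(pp)) / p_mix_ode,
        "K8_mean_alternating": rep["K8"]["mean_alternating"],
        "K8_mean_mixture": rep["K8"]["mean_mixture"],
        "K8_rank_pvalue_mixture_lower": rep["K8"]["rank_test_pvalue"],
        "K8_all_seeds_lower": bool(np.all(
            rep["K8"]["mixture"] < rep["K8"]["alternating"])),
        "K1_mean_alternating": rep["K1"]["mean_alternating"],
        "K1_mean_mixture": rep["K1"]["mean_mixture"],
        "K1_rank_pvalue_two_sided": rep["K1"]["rank_test_pvalue_two_sided"],
        "K8_cross_within_alternating": rep["K8"][
            "cross_within_ratio_alternating"],
        "K8_cross_within_mixture": rep["K8"]["cross_within_ratio_mixture"],
        "n_seeds": n_seeds,
    }


def reciprocity_benchmark(seed: int = 0, n_seeds: int = 3,
                          n_steps: int = 1500) -> dict:
    """Decorrelation vs rewiring fraction on the symmetric four-channel set.

    Training uses the collapsed-pair ensemble; the similar test pair probes
    decorrelation.  Full rewiring must leave every pairwise correlation at
    its input value (the surviving inhibition is unstructured), and the
    within-pair correlation must be non-decreasing in the rewired fraction.
    Row-sum preservation under self-inhibition rescaling is checked exactly.
    """
    train = bg.generate_symmetric4(0.0)
    probe = bg.generate_symmetric4(0.2)
    inp = correlation_matrix(probe).matrix
    iu = np.triu_indices(4, k=1)
    params = bg.SurvivalParams(resilience_threshold=0.02,
                               survival_threshold=1.0, steepness=50.0,
                               influx=6, connections_per_cell=2,
                               inh_weight=0.002, spontaneous=0.1)
    fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
    pair_corrs, max_devs = [], []
    x_frac, y_corr = [], []            # per-seed replicates for the rank test
    for frac in fractions:
        mats = []
        for s in range(seed, seed + n_seeds):
            rng = np.random.default_rng(s)
            net = bg.NetworkState.empty(4, params.spontaneous)
            net, traj = bg.evolve(net, train, n_steps, params, rng,
                                  record_every=n_steps // 5,
                                  rewire_fraction=frac,
                                  probe_ensemble=probe)
            mat_s = np.mean(traj.correlations[-2:], axis=0)
            mats.append(mat_s)
            x_frac.append(frac)
            y_corr.append(0.5 * (mat_s[0, 1] + mat_s[2, 3]))
        mat = np.mean(mats, axis=0)
        pair_corrs.append(float(0.5 * (mat[0, 1] + mat[2, 3])))
        max_devs.append(float(np.abs(mat - inp)[iu].max()))
    rho, pval = spearmanr(x_frac, y_corr)

    # exact row-sum preservation of the self/lateral rescaling
    rng = np.random.default_rng(seed)
    net = bg.NetworkState.empty(12, 0.1).add_granule_cells(80, 3, 0.01, rng)
    W = bg.effective_connectivity(net)
    errs = [np.abs(bg.rescale_self_inhibition(W, g).sum(axis=1)
                   - W.sum(axis=1)).max() for g in (0.0, 0.5, 2.0)]
    return {
        "fractions": fractions,
        "pair_correlations": pair_corrs,
        "input_pair_correlation": float(inp[0, 1]),
        "max_abs_corr_deviation_full_rewire": max_devs[-1],
        "spearman_rho": float(rho),
        "spearman_pvalue_increasing": float(pval / 2 if rho > 0 else 1.0),
        "gamma_rowsum_max_error": float(max(errs)),
        "n_seeds": n_seeds,
    }


def novelty_benchmark(seed: int = 0, n_seeds: int = 32) -> dict:
    """Young-cohort response to a novel versus familiar odors.

    With the IEG threshold equal to the resilience threshold and a moderate
    survival slope, the response ratio of the novel odor must fall below
    that of the familiar odors (sign test across seeds); the response
    fraction must approach 1 at zero IEG threshold and 0 far above it.
    """
    cfg = ExperimentConfig(experiment="novelty",
                           seeds=list(range(seed, seed + n_seeds)),
                           survival={"steepness": 2.5})
    rep = run_novelty(cfg)
    theta = rep["theta_ieg"]
    curve_cfg = ExperimentConfig(experiment="novelty", seeds=[seed],
                                 survival={"steepness": 2.5})
    curve = response_fraction_curve(curve_cfg, [0.0, 10 * theta + 5.0])
    return {
        "rho_novel_mean": float(np.nanmean(rep["rho_novel"])),
        "rho_familiar_mean": float(np.nanmean(rep["rho_familiar"])),
        "n_seeds_novel_below_familiar": rep["n_seeds_novel_below_familiar"],
        "sign_test_pvalue": rep["sign_test_pvalue"],
        "theta_ieg": theta,
        "response_fraction_at_zero_threshold": curve["mean_fraction"][0],
        "response_fraction_far_above_threshold": curve["mean_fraction"][1],
        "n_seeds": n_seeds,
    }


def selfregulation_benchmark(seed: int = 0, n_seeds: int = 2,
                             n_steps: int = 500) -> dict:
    """Homeostasis of the granule-cell population on the natural-like set.

    The count must plateau (trailing-window slope test), halving the
    stimulus amplitudes must lower the plateau, and removals must balance
    the influx at the plateau.
    """
    ens = natural_ensemble(0)
    params = default_survival_params()
    results = {}
    for label, scale in (("full", 1.0), ("half", 0.5)):
        counts, rates = [], []
        for s in range(seed, seed + n_seeds):
            rng = np.random.default_rng(s)
            net = bg.NetworkState.empty(ens.n_channels, params.spontaneous)
            net, traj = bg.evolve(net, ens.scaled(scale), n_steps, params,
                                  rng, record_every=10)
            counts.append(traj.granule_count)
            rates.append(traj.removal_rate)
        mean_counts = np.mean(counts, axis=0)
        ok, slope = detect_plateau(mean_counts, window=20)
        results[label] = {
            "plateau": bool(ok),
            "slope": float(slope),
            "count": float(mean_counts[-10:].mean()),
            "removal_over_influx": float(np.mean(np.asarray(rates)[:, -20:])),
        }
    return {
        "plateau_reached_full": results["full"]["plateau"],
        "plateau_slope_full": results["full"]["slope"],
        "plateau_count_full": results["full"]["count"],
        "plateau_count_half": results["half"]["count"],
        "plateau_reached_half": results["half"]["plateau"],
        "removal_over_influx": results["full"]["removal_over_influx"],
        "n_seeds": n_seeds,
    }
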