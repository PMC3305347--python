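"""Scripted in-silico experiments on the adaptive bulbar network.

Each ``run_*`` function reproduces one protocol family: decorrelation of an
odor ensemble from an empty network, robustness to imperfect synapse
reciprocity, novelty response of young granule-cell cohorts, perceptual
learning through odor enrichment, the alternating-versus-mixture enrichment
protocols, and the mean-field population analysis.  All functions are pure
given an explicit seed and return a plain-dict report embedding the resolved
configuration; when an output directory is given they also write CSV tables,
JSON manifests and PNG figures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, binomtest

from bulbgenesis import population as popmod
from bulbgenesis.metrics import (correlation_matrix, quadrant_sums,
                                 sort_for_display)
from bulbgenesis.network import (NetworkState, solve_steady_state,
                                 effective_connectivity)
from bulbgenesis.neurogenesis import (SurvivalParams, Trajectory, evolve,
                                      response_fraction, response_ratio)
from bulbgenesis.stimuli import (StimulusEnsemble, Schedule,
                                 make_enrichment_schedule, mix,
                                 synthetic_odor_set)

__all__ = [
    "ExperimentConfig", "default_survival_params", "natural_ensemble",
    "run_decorrelation", "run_reciprocity_study", "run_novelty",
    "response_fraction_curve", "run_perceptual_learning",
    "run_enrichment_protocols", "run_population_analysis",
    "run_experiment", "EXPERIMENTS",
]

#: Study conditions for the synthetic natural-like odor ensemble (98 channels).
#: Chosen once to place the network in the decorrelating regime with a
#: plateau of roughly ten granule cells per mitral cell; see docs/methods.md.
DEFAULT_SURVIVAL = dict(
    resilience_threshold=0.3,
    survival_threshold=0.5,
    steepness=10.0,
    influx=25,
    connections_per_cell=8,
    inh_weight=0.008,
    spontaneous=0.2,
)


def default_survival_params(**overrides) -> SurvivalParams:
    """Survival/evolution parameters of the synthetic study conditions."""
    cfg = dict(DEFAULT_SURVIVAL)
    cfg.update(overrides)
    return SurvivalParams(**cfg)


def natural_ensemble(seed: int = 0, odors: Sequence[str] | None = None
                     ) -> StimulusEnsemble:
    """Synthetic eight-odor ensemble emulating natural glomerular maps."""
    oset = synthetic_odor_set(seed=seed)
    if odors is None:
        odors = ["limonene_plus", "limonene_minus", "carvone_plus",
                 "carvone_minus", "butanol", "hexanol", "heptanol",
                 "acetic_acid"]
    return StimulusEnsemble([oset[o] for o in odors])


@dataclass
class ExperimentConfig:
    """Configuration of a scripted experiment.

    ``stimulus_seed`` controls the synthetic odor set; ``seeds`` the
    evolution runs (multi-run averages use consecutive seeds).  Perturbation
    fields apply where the experiment supports them.
    """

    experiment: str = "decorrelation"
    n_steps: int = 600
    record_every: int = 25
    seeds: list[int] = field(default_factory=lambda: [0])
    stimulus_seed: int = 0
    survival: dict = field(default_factory=dict)
    rewire_fraction: float = 0.0
    weight_mode: str | None = None
    weight_delta: float = 0.0
    gamma: float = 1.0
    enrichment_start: int | None = None
    stop_influx_at_enrichment: bool = False
    theta_ieg: float | None = None
    outdir: str | None = None
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def params(self, **overrides) -> SurvivalParams:
        merged = dict(self.survival)
        merged.update(overrides)
        return default_survival_params(**merged)

    def resolved(self) -> dict:
        return asdict(self)


def _write_report(report: dict, outdir: str | None) -> None:
    if outdir is None:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def default(o: Any):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return asdict(o)
        return str(o)

    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=default))


def _final_corr(traj: Trajectory, tail: int = 5) -> np.ndarray:
    """Mean correlation matrix over the trailing recorded snapshots."""
    tail = min(tail, len(traj.correlations))
    return np.mean(traj.correlations[-tail:], axis=0)


def run_decorrelation(config: ExperimentConfig) -> dict:
    """Evolve a network from no granule cells on a fixed odor ensemble.

    Reports input and output correlation matrices, the trajectory of the
    mean correlation and of the granule-cell count, and the display ordering
    of the final effective connectivity.
    """
    ensemble = natural_ensemble(config.stimulus_seed)
    params = config.params()
    report: dict[str, Any] = {"config": config.resolved()}
    report["input_correlations"] = correlation_matrix(ensemble).matrix
    report["input_mean_correlation"] = correlation_matrix(ensemble).mean
    report["labels"] = ensemble.labels
    finals, counts, trajs = [], [], []
    for seed in config.seeds:
        rng = np.random.default_rng(seed)
        net = NetworkState.empty(ensemble.n_channels, params.spontaneous)
        net, traj = evolve(net, ensemble, config.n_steps, params, rng,
                           record_every=config.record_every,
                           rewire_fraction=config.rewire_fraction,
                           weight_mode=config.weight_mode,
                           weight_delta=config.weight_delta,
                           gamma=config.gamma)
        finals.append(_final_corr(traj))
        counts.append(traj.granule_count[-1])
        trajs.append(traj)
    report["output_correlations"] = np.mean(finals, axis=0)
    iu = np.triu_indices(len(ensemble), k=1)
    report["output_mean_correlation"] = float(
        np.nanmean(report["output_correlations"][iu]))
    report["final_granule_count"] = float(np.mean(counts))
    report["trajectory"] = trajs[0].to_dataframe().to_dict(orient="list")
    order = sort_for_display(ensemble[0].values, ensemble[2].values)
    report["display_order"] = order
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        trajs[0].save(out / "trajectory.csv", out / "manifest.json")
        pd.DataFrame(report["output_correlations"],
                     index=ensemble.labels, columns=ensemble.labels
                     ).to_csv(out / "output_correlations.csv")
    _write_report(report, config.outdir)
    return report


def run_reciprocity_study(config: ExperimentConfig) -> dict:
    """Sweep rewiring fraction, weight heterogeneity, and self-inhibition.

    ``config.extras`` may set ``fractions``, ``deltas`` (two-point weight
    spread as a multiple of w) and ``gammas``.
    """
    ensemble = natural_ensemble(config.stimulus_seed)
    params = config.params()
    input_corr = correlation_matrix(ensemble).matrix
    fractions = config.extras.get("fractions", [0.0, 0.25, 0.5, 0.75, 1.0])
    deltas = config.extras.get("deltas", [0.0, 0.5, 1.0])
    gammas = config.extras.get("gammas", [0.25, 1.0, 2.0])
    report: dict[str, Any] = {"config": config.resolved(),
                              "labels": ensemble.labels,
                              "input_correlations": input_corr}

    def sweep(kind: str, values, **kw_of):
        rows = []
        for v in values:
            mats = []
            for seed in config.seeds:
                rng = np.random.default_rng(seed)
                net = NetworkState.empty(ensemble.n_channels,
                                         params.spontaneous)
                net, traj = evolve(net, ensemble, config.n_steps, params, rng,
                                   record_every=config.record_every,
                                   **kw_of(v))
                mats.append(_final_corr(traj))
            mat = np.mean(mats, axis=0)
            iu = np.triu_indices(len(ensemble), k=1)
            rows.append({kind: v, "mean_correlation": float(np.nanmean(mat[iu])),
                         "matrix": mat})
        return rows

    report["rewire"] = sweep("fraction", fractions,
                             kw_of=lambda v: {"rewire_fraction": v})
    report["heterogeneity"] = sweep(
        "delta_over_w", deltas,
        kw_of=lambda v: {"weight_mode": "two_point" if v else None,
                         "weight_delta": v * params.inh_weight})
    report["self_inhibition"] = sweep("gamma", gammas,
                                      kw_of=lambda v: {"gamma": v})
    _write_report(report, config.outdir)
    return report


def run_novelty(config: ExperimentConfig) -> dict:
    """Response of young granule-cell cohorts to novel versus familiar odors.

    The network evolves on a background ensemble (the novel odor excluded
    from survival assessment); cells integrated during a marking window are
    tagged, and the fraction responding above ``theta_ieg`` is followed over
    time for every stimulus.  Reports the response ratio rho (final over
    post-marking fraction) per stimulus and seed, plus a response-fraction
    curve over a grid of IEG thresholds.
    """
    probe = natural_ensemble(config.stimulus_seed)
    # default novel odor: carvone_plus, with its enantiomer partner also
    # withheld from the background so the novel glomerular region is
    # genuinely undriven during survival assessment
    novel_idx = config.extras.get("novel_index", 2)
    excluded = set(config.extras.get("exclude_indices", [2, 3]))
    excluded.add(novel_idx)
    background = probe.subset([i for i in range(len(probe))
                               if i not in excluded])
    params = config.params()
    theta = (config.theta_ieg if config.theta_ieg is not None
             else params.resilience_threshold)
    n_build = config.extras.get("build_steps", 400)
    mark_len = config.extras.get("marking_steps", 30)
    n_follow = config.extras.get("follow_steps", 300)
    rho_novel, rho_familiar, rows = [], [], []
    for seed in config.seeds:
        rng = np.random.default_rng(seed)
        net = NetworkState.empty(probe.n_channels, params.spontaneous)
        total = n_build + mark_len + n_follow
        net, traj = evolve(net, background, total, params, rng,
                           record_every=config.record_every,
                           cohort_window=(n_build, n_build + mark_len),
                           probe_ensemble=probe, theta_ieg=theta)
        recs = traj.manifest["response_records"]
        if len(recs) < 2:
            raise RuntimeError("not enough cohort records; increase follow_steps")
        f0 = np.asarray(recs[0]["fractions"])
        f1 = np.asarray(recs[-1]["fractions"])
        rho = response_ratio(f0, f1)
        fam = [i for i in range(len(probe)) if i not in excluded]
        rho_novel.append(rho[novel_idx])
        rho_familiar.append(np.nanmean(rho[fam]))
        rows.append({"seed": seed, "rho": rho, "n_marked_final":
                     recs[-1]["n_marked"]})
    rho_novel = np.asarray(rho_novel)
    rho_familiar = np.asarray(rho_familiar)
    diffs = rho_novel - rho_familiar
    n_neg = int(np.sum(diffs < 0))
    test = binomtest(n_neg, diffs.size, 0.5, alternative="greater")
    report = {
        "config": config.resolved(), "labels": probe.labels,
        "novel_index": novel_idx, "theta_ieg": theta,
        "rho_novel": rho_novel, "rho_familiar": rho_familiar,
        "sign_test_pvalue": float(test.pvalue),
        "n_seeds_novel_below_familiar": n_neg,
        "per_seed": rows,
    }
    _write_report(report, config.outdir)
    return report


def response_fraction_curve(config: ExperimentConfig,
                            thetas: Sequence[float]) -> dict:
    """Mean marked-cell response fraction across an IEG-threshold grid."""
    probe = natural_ensemble(config.stimulus_seed)
    novel_idx = config.extras.get("novel_index", 2)
    excluded = set(config.extras.get("exclude_indices", [2, 3]))
    excluded.add(novel_idx)
    background = probe.subset([i for i in range(len(probe))
                               if i not in excluded])
    params = config.params()
    n_build = config.extras.get("build_steps", 400)
    mark_len = config.extras.get("marking_steps", 30)
    rng = np.random.default_rng(config.seeds[0])
    net = NetworkState.empty(probe.n_channels, params.spontaneous)
    net, _ = evolve(net, background, n_build + mark_len, params, rng,
                    record_every=max(n_build // 2, 1),
                    cohort_window=(n_build, n_build + mark_len))
    state = solve_steady_state(net, probe)
    mask = net.cohort == 1
    curve = []
    for th in thetas:
        fr = [response_fraction(state, mask, th, s) for s in range(len(probe))]
        curve.append(float(np.mean(fr)))
    return {"thetas": list(map(float, thetas)), "mean_fraction": curve,
            "n_marked": int(mask.sum())}


def run_perceptual_learning(config: ExperimentConfig) -> dict:
    """Odor enrichment and the correlation of a held-out test pair.

    A default network is built on a four-odor background; at the enrichment
    onset the schedule adds either odors related to the test pair (the two
    limonene enantiomers) or unrelated ones (the carvones), optionally with
    the granule-cell influx stopped.  The test stimuli never drive survival.
    """
    oset = synthetic_odor_set(config.stimulus_seed)
    background = StimulusEnsemble(
        [oset[o] for o in ("butanol", "hexanol", "heptanol", "acetic_acid")])
    test = StimulusEnsemble([oset["limonene_plus"], oset["limonene_minus"]])
    related = [oset["limonene_plus"], oset["limonene_minus"]]
    unrelated = [oset["carvone_plus"], oset["carvone_minus"]]
    params = config.params()
    start = config.enrichment_start or config.n_steps // 3
    total = config.n_steps

    def run(enrich, influx_scale):
        if enrich is None:
            sched = Schedule.constant(background)
        else:
            enriched = make_enrichment_schedule(background, enrich,
                                                "alternating")
            sched = Schedule([(0, background, 1.0),
                              (start, enriched, influx_scale)])
        curves = []
        for seed in config.seeds:
            rng = np.random.default_rng(seed)
            net = NetworkState.empty(background.n_channels, params.spontaneous)
            net, traj = evolve(net, sched, total, params, rng,
                               record_every=config.record_every,
                               probe_ensemble=test)
            df = traj.to_dataframe()
            curves.append(df[df.columns[-1]].to_numpy())  # the single test pair
        return np.mean(curves, axis=0), df["step"].to_numpy()

    rel, steps = run(related, 1.0)
    unrel, _ = run(unrelated, 1.0)
    noneuro, _ = run(related, 0.0)
    basel, _ = run(None, 1.0)
    pre = steps < start
    post = steps >= (start + (total - start) // 2)
    report = {
        "config": config.resolved(), "steps": steps,
        "enrichment_start": start,
        "test_pair": [p.label for p in test],
        "related": rel, "unrelated": unrel,
        "no_neurogenesis": noneuro, "baseline": basel,
        "related_overlap": float(np.corrcoef(
            mix(related, [0.5, 0.5]).values, test.matrix.mean(axis=0))[0, 1]),
        "unrelated_overlap": float(np.corrcoef(
            mix(unrelated, [0.5, 0.5]).values, test.matrix.mean(axis=0))[0, 1]),
        "drop_related": float(rel[pre].mean() - rel[post].mean()),
        "drop_unrelated": float(unrel[pre].mean() - unrel[post].mean()),
        "drop_no_neurogenesis": float(noneuro[pre].mean()
                                      - noneuro[post].mean()),
    }
    _write_report(report, config.outdir)
    return report


def run_enrichment_protocols(config: ExperimentConfig) -> dict:
    """Alternating versus mixture enrichment for similar test mixtures.

    Components are racemic limonene and carvone; test stimuli are their
    35:65 and 65:35 mixtures.  For each protocol and seed the network evolves
    on background + enrichment, and the correlation between the two test
    mixtures is reported, along with the cross-component quadrant sums of
    the effective connectivity.  Run at ``connections_per_cell`` 8 (lateral
    inhibition) the protocols differ; at 1 (pure self-inhibition) they do
    not.
    """
    oset = synthetic_odor_set(config.stimulus_seed)
    background = StimulusEnsemble(
        [oset[o] for o in ("butanol", "hexanol", "heptanol", "acetic_acid")])
    limonene = mix([oset["limonene_plus"], oset["limonene_minus"]],
                   [0.5, 0.5], label="limonene")
    carvone = mix([oset["carvone_plus"], oset["carvone_minus"]],
                  [0.5, 0.5], label="carvone")
    fracs = config.extras.get("test_fractions", [0.35, 0.65])
    tests = StimulusEnsemble(
        [mix([limonene, carvone], [f, 1 - f], label=f"mix_{f:g}")
         for f in fracs])
    k_values = config.extras.get("k_values", [8, 1])
    lim_idx = np.flatnonzero(limonene.values > carvone.values)
    car_idx = np.flatnonzero(limonene.values <= carvone.values)
    strong_lim = np.flatnonzero(limonene.values > 0.35)
    strong_car = np.flatnonzero(carvone.values > 0.35)
    report: dict[str, Any] = {"config": config.resolved(),
                              "test_labels": tests.labels}
    # single-source granule cells see one mitral activity, so the K=1
    # control needs thresholds and weight on that scale
    k1_overrides = config.extras.get(
        "k1_survival", {"resilience_threshold": 0.05,
                        "survival_threshold": 0.3, "inh_weight": 0.05})
    for K in k_values:
        overrides = dict(k1_overrides) if K == 1 else {}
        params = config.params(connections_per_cell=K, **overrides)
        per_protocol: dict[str, list] = {}
        quad: dict[str, list] = {}
        cross_by_protocol: dict[str, float] = {}
        for protocol in ("alternating", "mixture"):
            ens = make_enrichment_schedule(background, [limonene, carvone],
                                           protocol)
            corrs, qsums, cross_ratios = [], [], []
            for seed in config.seeds:
                rng = np.random.default_rng(seed)
                net = NetworkState.empty(ens.n_channels, params.spontaneous)
                net, traj = evolve(net, ens, config.n_steps, params, rng,
                                   record_every=config.record_every,
                                   probe_ensemble=tests)
                corrs.append(float(_final_corr(traj)[0, 1]))
                W = effective_connectivity(net)
                qsums.append(quadrant_sums(W, (lim_idx, car_idx)))
                cross = (W[np.ix_(strong_lim, strong_car)].sum()
                         + W[np.ix_(strong_car, strong_lim)].sum())
                within = (W[np.ix_(strong_lim, strong_lim)].sum()
                          - np.diag(W)[strong_lim].sum()
                          + W[np.ix_(strong_car, strong_car)].sum()
                          - np.diag(W)[strong_car].sum())
                cross_ratios.append(cross / within if within > 0 else np.nan)
            per_protocol[protocol] = corrs
            quad[protocol] = np.mean(qsums, axis=0)
            cross_by_protocol[protocol] = float(np.nanmean(cross_ratios))
        alt = np.asarray(per_protocol["alternating"])
        mixp = np.asarray(per_protocol["mixture"])
        if np.allclose(alt, mixp, atol=1e-12):
            # degenerate case: identical outcomes (exact at K=1 when the
            # resilience is linear in the stimuli)
            p_less = p_two = 1.0
        else:
            p_less = float(mannwhitneyu(mixp, alt, alternative="less").pvalue)
            p_two = float(mannwhitneyu(mixp, alt,
                                       alternative="two-sided").pvalue)
        report[f"K{K}"] = {
            "alternating": alt, "mixture": mixp,
            "mean_alternating": float(alt.mean()),
            "mean_mixture": float(mixp.mean()),
            "rank_test_pvalue": p_less,
            "rank_test_pvalue_two_sided": p_two,
            "quadrants_alternating": quad["alternating"],
            "quadrants_mixture": quad["mixture"],
            "cross_within_ratio_alternating": cross_by_protocol["alternating"],
            "cross_within_ratio_mixture": cross_by_protocol["mixture"],
        }
    _write_report(report, config.outdir)
    return report


def run_population_analysis(config: ExperimentConfig) -> dict:
    """Phase-plane, threshold-scan and protocol analysis of the mean-field model."""
    pp = popmod.PopulationParams(**config.extras.get("population", {}))
    scan_thetas = config.extras.get(
        "thresholds", np.round(np.arange(0.0, 0.101, 0.005), 4))
    scan = popmod.threshold_scan(pp, scan_thetas, method="ode")
    fp = popmod.fixed_point_symmetric4(pp)
    ode_fp = popmod.integrate_populations(pp)
    comp = popmod.mixture_comparison(pp)
    p_mix_ode = popmod.integrate_mixture(pp)
    report = {
        "config": config.resolved(),
        "params": asdict(pp),
        "fixed_point_closed_form": asdict(fp),
        "fixed_point_ode": {"coactive": ode_fp[0], "interfering": ode_fp[1]},
        "optimal_threshold": popmod.optimal_threshold(pp),
        "extinction_threshold": popmod.extinction_threshold(pp),
        "threshold_scan": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in scan.items()},
        "mixture_comparison": asdict(comp),
        "p_mixture_ode": p_mix_ode,
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({k: scan[k] for k in
                      ("thresholds", "coactive", "interfering", "correlation")
                      }).to_csv(out / "threshold_scan.csv", index=False)
        _plot_phase_plane(pp, out / "phase_plane.png")
    _write_report(report, config.outdir)
    return report


def _plot_phase_plane(pp: "popmod.PopulationParams", path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fp = popmod.fixed_point_symmetric4(pp)
    a_hi = 1.5 * max(fp.coactive, 1.0)
    b_hi = 1.5 * max(fp.interfering, pp.influx * pp.dt, 1.0)
    a_grid = np.linspace(0, a_hi, 80)
    b_grid = np.linspace(0, b_hi, 80)
    b_null = popmod.nullclines_symmetric4(pp, a_grid, "interfering")
    a_null = popmod.nullclines_symmetric4(pp, b_grid, "coactive")
    sol = popmod.integrate_populations(pp, dense=True, rtol=1e-8, atol=1e-10)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(a_grid, b_null, "b-", label="interfering nullcline")
    ax.plot(a_null, b_grid, "r-", label="co-active nullcline")
    ax.plot(sol.y[0], sol.y[1], "k.-", ms=2, lw=0.5, label="trajectory")
    ax.plot([fp.coactive], [fp.interfering], "g*", ms=12, label="fixed point")
    ax.set_xlabel("co-active population a")
    ax.set_ylabel("interfering population b")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


EXPERIMENTS = {
    "decorrelation": run_decorrelation,
    "reciprocity": run_reciprocity_study,
    "novelty": run_novelty,
    "perceptual_learning": run_perceptual_learning,
    "enrichment_protocols": run_enrichment_protocols,
    "population_analysis": run_population_analysis,
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Dispatch a configured experiment by name."""
    try:
        fn = EXPERIMENTS[config.experiment]
    except KeyError:
        raise ValueError(f"unknown experiment {config.experiment!r}; "
                         f"choose from {sorted(EXPERIMENTS)}") from None
    return fn(config)
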