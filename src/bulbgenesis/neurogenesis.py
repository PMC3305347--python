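"""Structural plasticity: granule-cell influx, resilience-based survival, removal.

The network connectivity evolves on a time scale much slower than the
neuronal activities.  At each evolution step a fixed number of new granule
cells is added with random reciprocal wiring, the steady-state response to
every stimulus of the current ensemble is computed, and each granule cell is
removed independently with probability ``1 - P(R)``, where the resilience

    R_j = sum_mu [ g_j(mu) - theta_R ]_+

is the cell's thresholded activity summed over the stimulus ensemble and
``P`` is a logistic survival curve with soft threshold ``T_S`` and steepness
``beta``.  The balance between proliferation and apoptosis self-regulates
the population size; the selective removal of weakly (or indiscriminately)
active cells structures the effective inhibition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from bulbgenesis.network import (NetworkState, SteadyState, solve_steady_state,
                                 rewire, heterogenize_weights)
from bulbgenesis.metrics import correlation_matrix
from bulbgenesis.stimuli import Schedule, StimulusEnsemble

__all__ = [
    "SurvivalParams", "Trajectory", "EmptyCohortError", "resilience",
    "survival_probability", "evolution_step", "evolve", "mark_cohort",
    "response_fraction", "response_ratio", "detect_plateau",
]


class EmptyCohortError(RuntimeError):
    """Raised when a marked cohort has no surviving members."""


@dataclass
class SurvivalParams:
    """Free parameters of the survival rule and the evolution loop.

    Attributes
    ----------
    resilience_threshold : float
        Per-stimulus activity threshold ``theta_R``; only activity above it
        contributes to the resilience.
    survival_threshold : float
        Soft threshold ``T_S`` of the logistic survival probability.
    steepness : float
        Slope of the survival sigmoid at its midpoint.
    influx : int
        Granule cells added per evolution step.
    connections_per_cell : int
        ``K``, number of distinct mitral cells each granule cell contacts.
    inh_weight : float
        Uniform inhibitory synaptic strength ``w`` (excitatory strength is 1).
    spontaneous : float
        Spontaneous mitral activity ``s0``.
    """

    resilience_threshold: float
    survival_threshold: float
    steepness: float
    influx: int
    connections_per_cell: int
    inh_weight: float
    spontaneous: float = 0.0

    def __post_init__(self) -> None:
        if self.influx < 0 or int(self.influx) != self.influx:
            raise ValueError("influx must be a nonnegative integer")
        if self.connections_per_cell < 1:
            raise ValueError("connections_per_cell must be >= 1")
        if self.resilience_threshold < 0 or self.survival_threshold < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.inh_weight < 0:
            raise ValueError("inhibitory weight must be nonnegative")


def resilience(granule_activities: np.ndarray,
               resilience_threshold: float) -> np.ndarray:
    """Thresholded granule activity summed over the stimulus ensemble.

    ``granule_activities`` has shape (n_granule, n_stimuli).  The rectifier
    rewards peaky activity profiles: cells driven strongly by a few stimuli
    accumulate more resilience than cells with the same total activity spread
    evenly below threshold, which is what suppresses interfering connections.
    """
    acts = np.atleast_2d(np.asarray(granule_activities, dtype=float))
    return np.maximum(acts - resilience_threshold, 0.0).sum(axis=1)


def survival_probability(resilience_value, params: SurvivalParams) -> np.ndarray:
    """Logistic survival probability, midpoint at the soft survival threshold."""
    r = np.asarray(resilience_value, dtype=float)
    return expit(params.steepness * (r - params.survival_threshold))


@dataclass
class Trajectory:
    """Per-step records of one network evolution run."""

    steps: list[int] = field(default_factory=list)
    granule_count: list[int] = field(default_factory=list)
    removals: list[int] = field(default_factory=list)
    removal_rate: list[float] = field(default_factory=list)   # removals / influx
    mean_correlation: list[float] = field(default_factory=list)
    correlations: list[np.ndarray] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "step": self.steps,
            "granule_count": self.granule_count,
            "removals": self.removals,
            "removal_rate": self.removal_rate,
            "mean_correlation": self.mean_correlation,
        })
        if self.correlations:
            S = self.correlations[0].shape[0]
            for i in range(S):
                for j in range(i + 1, S):
                    df[f"corr_{self.labels[i]}__{self.labels[j]}"] = [
                        c[i, j] for c in self.correlations]
        return df

    def save(self, csv_path: str | Path,
             manifest_path: str | Path | None = None) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)
        if manifest_path is not None:
            Path(manifest_path).write_text(json.dumps(self.manifest, indent=2))

    @property
    def final_correlations(self) -> np.ndarray:
        return self.correlations[-1]


def evolution_step(network: NetworkState, ensemble: StimulusEnsemble,
                   params: SurvivalParams, rng: np.random.Generator,
                   step: int = 0, influx_scale: float = 1.0,
                   cohort: int = 0, rewire_fraction: float = 0.0,
                   weight_mode: str | None = None, weight_delta: float = 0.0,
                   gamma: float = 1.0,
                   ) -> tuple[NetworkState, SteadyState, dict]:
    """One step of the structural-plasticity loop.

    Adds ``influx`` new reciprocally wired granule cells (optionally rewired
    or weight-heterogenized at birth), solves the steady state for the full
    ensemble, evaluates every cell's resilience, and removes cells by
    independent Bernoulli draws with probability ``1 - P(R)``.  Newly added
    cells are assessed in the same step.
    """
    n_new = int(round(params.influx * influx_scale))
    if n_new > 0:
        born = NetworkState.empty(network.n_mitral, network.spontaneous)
        born = born.add_granule_cells(n_new, params.connections_per_cell,
                                      params.inh_weight, rng, step=step,
                                      cohort=cohort)
        if weight_mode is not None and weight_delta > 0:
            born = heterogenize_weights(born, weight_mode, weight_delta, rng)
        if rewire_fraction > 0:
            born = rewire(born, rewire_fraction, rng)
        network = NetworkState(
            network.n_mitral,
            np.vstack([network.exc_sources, born.exc_sources]),
            np.vstack([network.inh_targets, born.inh_targets]),
            np.vstack([network.inh_weights, born.inh_weights]),
            network.spontaneous,
            np.concatenate([network.birth_step, born.birth_step]),
            np.concatenate([network.cohort, born.cohort]),
            network.exc_weight,
        )
    state = solve_steady_state(network, ensemble, gamma=gamma)
    res = resilience(state.granule, params.resilience_threshold)
    p_surv = survival_probability(res, params)
    survive = rng.random(network.n_granule) < p_surv
    removed = int(np.count_nonzero(~survive))
    new_network = network.keep(survive)
    record = {
        "step": step,
        "granule_count": new_network.n_granule,
        "removals": removed,
        "removal_rate": removed / params.influx if params.influx else np.nan,
    }
    return new_network, state, record


def evolve(network: NetworkState, schedule: Schedule | StimulusEnsemble,
           n_steps: int, params: SurvivalParams, rng: np.random.Generator,
           record_every: int = 10, rewire_fraction: float = 0.0,
           weight_mode: str | None = None, weight_delta: float = 0.0,
           gamma: float = 1.0, cohort_window: tuple[int, int] | None = None,
           probe_ensemble: StimulusEnsemble | None = None,
           theta_ieg: float | None = None,
           ) -> tuple[NetworkState, Trajectory]:
    """Run the structural-plasticity loop for ``n_steps`` evolution steps.

    The schedule may switch the stimulus ensemble or scale the influx at
    given steps (enrichment onset, arrested neurogenesis).  Every
    ``record_every`` steps the mitral output correlations of the probe
    ensemble (defaults to the currently scheduled ensemble) are recorded;
    when ``cohort_window=(t0, t1)`` is given, granule cells integrated in
    ``t0 <= step < t1`` are tagged as cohort 1 and the fraction of surviving
    tagged cells responding above ``theta_ieg`` is recorded per stimulus.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if isinstance(schedule, StimulusEnsemble):
        schedule = Schedule.constant(schedule)
    traj = Trajectory()
    traj.manifest = {
        "params": asdict(params), "n_steps": n_steps,
        "record_every": record_every, "rewire_fraction": rewire_fraction,
        "weight_mode": weight_mode, "weight_delta": weight_delta,
        "gamma": gamma,
    }
    response_records: list[dict] = []
    for step in range(n_steps):
        ensemble, influx_scale = schedule.at(step)
        cohort = 1 if (cohort_window is not None
                       and cohort_window[0] <= step < cohort_window[1]) else 0
        network, state, record = evolution_step(
            network, ensemble, params, rng, step=step,
            influx_scale=influx_scale, cohort=cohort,
            rewire_fraction=rewire_fraction, weight_mode=weight_mode,
            weight_delta=weight_delta, gamma=gamma)
        if step % record_every == 0 or step == n_steps - 1:
            probe = probe_ensemble if probe_ensemble is not None else ensemble
            probe_state = (state if probe is ensemble
                           else solve_steady_state(network, probe, gamma=gamma))
            report = correlation_matrix(probe_state.mitral, labels=probe.labels)
            traj.steps.append(step)
            traj.granule_count.append(record["granule_count"])
            traj.removals.append(record["removals"])
            traj.removal_rate.append(record["removal_rate"])
            traj.mean_correlation.append(report.mean)
            traj.correlations.append(report.matrix)
            traj.labels = report.labels
            if cohort_window is not None and step >= cohort_window[1]:
                mask = network.cohort == 1
                if mask.any() and theta_ieg is not None:
                    fr = [response_fraction(probe_state, mask, theta_ieg, s)
                          for s in range(len(probe))]
                    response_records.append(
                        {"step": step, "n_marked": int(mask.sum()),
                         "fractions": fr})
    traj.manifest["response_records"] = response_records
    return network, traj


def mark_cohort(network: NetworkState,
                step_window: tuple[int, int]) -> NetworkState:
    """Tag granule cells integrated during ``[t0, t1)`` as cohort 1."""
    out = network.copy()
    t0, t1 = step_window
    mask = (out.birth_step >= t0) & (out.birth_step < t1)
    if not mask.any():
        raise EmptyCohortError("no surviving cells born in the window")
    out.cohort = np.where(mask, 1, 0)
    return out


def response_fraction(steady_state: SteadyState, cohort_mask: np.ndarray,
                      theta_ieg: float, stimulus: int) -> float:
    """Fraction of marked surviving cells responding above ``theta_ieg``.

    A granule cell counts as responding to the stimulus (a proxy for
    immediate-early-gene expression) if its steady-state activity exceeds
    the threshold.
    """
    cohort_mask = np.asarray(cohort_mask, dtype=bool)
    n = int(cohort_mask.sum())
    if n == 0:
        raise EmptyCohortError("cohort is extinct")
    acts = steady_state.granule[cohort_mask, stimulus]
    return float(np.count_nonzero(acts > theta_ieg) / n)


def response_ratio(fractions_after_marking: np.ndarray,
                   fractions_final: np.ndarray) -> np.ndarray:
    """Ratio rho of final to immediately-post-marking response fractions.

    ``rho < 1`` signals a stimulus whose responsive marked cells are being
    lost (novel odors); ``rho >= 1`` a stimulus retaining or recruiting them
    (familiar odors).
    """
    f0 = np.asarray(fractions_after_marking, dtype=float)
    f1 = np.asarray(fractions_final, dtype=float)
    if f0.shape != f1.shape:
        raise ValueError("fraction arrays must have equal shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(f0 > 0, f1 / f0, np.nan)


def detect_plateau(counts, window: int = 20,
                   slope_tol: float = 0.05) -> tuple[bool, float]:
    """Trailing-window slope test for a statistically steady population.

    Fits a line to the last ``window`` recorded granule counts; the plateau
    verdict requires the fitted per-record slope to stay below ``slope_tol``
    times the window mean divided by the window length (i.e. the projected
    drift over the window is a small fraction of the level).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < window:
        raise ValueError("not enough records for the requested window")
    tail = counts[-window:]
    x = np.arange(window, dtype=float)
    slope = float(np.polyfit(x, tail, 1)[0])
    level = float(tail.mean())
    drift = abs(slope) * window
    return bool(drift <= slope_tol * max(level, 1.0)), slope
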