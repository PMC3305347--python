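"""Mean-field description of granule-cell populations (two-connection networks).

In the weak-coupling limit (small inhibitory weight ``w``, large cell
numbers) the discrete turnover of granule cells is captured by differential
equations for the mean size ``n_ij`` of the population of cells connecting
mitral pair ``(i, j)``:

    dn_ij/dt = alpha - r(R_ij) * n_ij,      r(R) = (1 - P(R)) / dt,

where ``alpha`` is the per-population influx, ``P`` the logistic survival
probability evaluated on the population's resilience, and ``dt`` the
assessment interval (removal is one Bernoulli assessment per interval, so
the rate is bounded by ``1/dt``; the interval is absorbed into the rate).
The steady-state activities entering the resilience follow from the
effective connectivity generated by the populations themselves.

For the symmetric four-stimulus ensemble (see
:func:`bulbgenesis.stimuli.generate_symmetric4`) only two populations need
to be analyzed: the *co-active* population ``a`` (pairs (1,2) and (3,4),
connecting mitral cells that are strongly active together) and the
*interfering* population ``b`` (the four cross pairs, connecting cells that
are never strongly co-active).  In the steep-sigmoid limit the nullclines
are the curves on which a population's resilience equals the survival
threshold, and the fixed points have closed forms; the resilience threshold

    theta_opt = s0 * T_S / (2 E)

is the smallest value at which the interfering population collapses to its
turnover floor while the co-active inhibition is still maximal, and it
minimizes the within-pair output correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "PopulationParams", "FixedPoint", "MixtureComparison",
    "steady_activities_symmetric4", "resilience_symmetric4",
    "population_rhs", "integrate_populations", "nullclines_symmetric4",
    "fixed_point_symmetric4", "discrete_fixed_point_prediction",
    "extinction_threshold", "optimal_threshold",
    "pair_correlation_exact", "correlation_expansion", "threshold_scan",
    "mixture_comparison", "mixture_nullcline_size", "mixture_rhs",
    "integrate_mixture", "PairPopulationModel",
]


@dataclass
class PopulationParams:
    """Parameters of the mean-field population equations.

    ``influx`` is the influx per population (``alpha``), ``amplitude`` the
    strong-glomerulus drive ``E`` of the symmetric ensemble, ``similarity``
    the flank parameter ``delta`` of the *test* stimuli (training uses the
    simplified ``delta = 0`` ensemble), and ``dt`` the assessment interval.
    """

    influx: float = 0.1
    inh_weight: float = 0.05
    resilience_threshold: float = 0.02
    survival_threshold: float = 1.0
    steepness: float = 1e8
    amplitude: float = 1.0
    spontaneous: float = 0.1
    similarity: float = 0.2
    dt: float = 1.0

    def __post_init__(self) -> None:
        if min(self.influx, self.inh_weight, self.resilience_threshold,
               self.survival_threshold, self.spontaneous) < 0:
            raise ValueError("rates, weights and thresholds must be >= 0")
        if self.steepness <= 0 or self.amplitude <= 0 or self.dt <= 0:
            raise ValueError("steepness, amplitude and dt must be positive")


def steady_activities_symmetric4(a: float, b: float, params: PopulationParams
                                 ) -> tuple[float, float]:
    """Mitral steady state under one training stimulus, given populations.

    Returns ``(m_strong, m_weak)``: with populations ``a`` on the co-active
    pairs and ``b`` on the four cross pairs, the linear steady state under a
    training stimulus ``E*(1,1,0,0) + s0`` has two strongly and two weakly
    driven mitral cells with

        m_s - m_w = E / (1 + 2wa),
        m_s + m_w = (E + 2 s0) / (1 + 2wa + 4wb).
    """
    E, s0, w = params.amplitude, params.spontaneous, params.inh_weight
    d = E / (1.0 + 2.0 * w * a)
    s = (E + 2.0 * s0) / (1.0 + 2.0 * w * a + 4.0 * w * b)
    return 0.5 * (s + d), 0.5 * (s - d)


def resilience_symmetric4(a: float, b: float, params: PopulationParams
                          ) -> tuple[float, float]:
    """Resiliences (R_a, R_b) of the two populations over the 4-stimulus ensemble.

    A co-active cell sees activity ``2 m_s`` during its pair's two stimuli
    and ``2 m_w`` during the other two; an interfering cell sees
    ``m_s + m_w`` during all four.
    """
    th = params.resilience_threshold
    m_s, m_w = steady_activities_symmetric4(a, b, params)
    r_a = 2.0 * max(2 * m_s - th, 0.0) + 2.0 * max(2 * m_w - th, 0.0)
    r_b = 4.0 * max(m_s + m_w - th, 0.0)
    return r_a, r_b


def _removal_rate(res, params: PopulationParams):
    """Removal rate (1 - P(R)) / dt for resilience(s) ``res``."""
    return expit(-params.steepness * (np.asarray(res, dtype=float)
                                      - params.survival_threshold)) / params.dt


def population_rhs(t: float, y: Sequence[float],
                   params: PopulationParams) -> list[float]:
    """Time derivatives of the reduced (co-active, interfering) system."""
    a, b = max(y[0], 0.0), max(y[1], 0.0)
    r_a, r_b = resilience_symmetric4(a, b, params)
    ra, rb = _removal_rate([r_a, r_b], params)
    return [params.influx - ra * a, params.influx - rb * b]


def integrate_populations(params: PopulationParams,
                          y0: tuple[float, float] = (0.0, 0.0),
                          t_max: float | None = None,
                          rtol: float = 1e-12, atol: float = 1e-13,
                          dense: bool = False):
    """Forward-integrate the reduced population ODE to its steady state.

    Uses an implicit (Radau) solver; the steep survival sigmoid makes the
    system stiff.  Returns the final ``(a, b)`` state, or the full solution
    object when ``dense`` is True.
    """
    if t_max is None:
        # slowest relaxation rate near the fixed point is ~ alpha / n*
        t_max = 4000.0 * params.dt
    sol = solve_ivp(population_rhs, (0.0, t_max), list(y0), args=(params,),
                    method="Radau", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"population ODE integration failed: {sol.message}")
    if dense:
        return sol
    return float(sol.y[0, -1]), float(sol.y[1, -1])


def nullclines_symmetric4(params: PopulationParams, grid: np.ndarray,
                          population: str = "interfering") -> np.ndarray:
    """Steep-limit nullcline of one population as a function of the other.

    For each value in ``grid`` (the other population's size), solves
    ``R = T_S`` by bracketed bisection.  Values where the resilience stays
    below threshold for any population size map to ``nan`` (the nullcline
    has reached the axis).
    """
    T = params.survival_threshold
    if population == "interfering":
        f = lambda b, a: resilience_symmetric4(a, b, params)[1] - T
    elif population == "coactive":
        f = lambda a, b: resilience_symmetric4(a, b, params)[0] - T
    else:
        raise ValueError("population must be 'coactive' or 'interfering'")
    out = np.full(len(grid), np.nan)
    hi = 10.0 / params.inh_weight  # inhibition scale far beyond any nullcline
    for i, other in enumerate(np.asarray(grid, dtype=float)):
        lo_val = f(0.0, other)
        if lo_val <= 0:
            continue
        out[i] = brentq(f, 0.0, hi, args=(other,), xtol=1e-12)
    return out


@dataclass
class FixedPoint:
    """Steep-limit fixed point of the two-population system."""

    coactive: float
    interfering: float
    regime: str        # 'interior' | 'floor' | 'collapsed'


def extinction_threshold(params: PopulationParams) -> float:
    """Resilience threshold at which the interfering population reaches its floor.

    At finite influx the interfering population cannot drop below the
    turnover floor ``alpha * dt`` (cells removed at their first assessment);
    this threshold converges to :func:`optimal_threshold` as ``alpha -> 0``.
    """
    E, s0, T = params.amplitude, params.spontaneous, params.survival_threshold
    F = 4.0 * E / T
    floor_inh = 4.0 * params.inh_weight * params.influx * params.dt
    return (E + 2.0 * s0) / (F + floor_inh) - T / 4.0


def optimal_threshold(params: PopulationParams) -> float:
    """Closed-form optimal resilience threshold ``s0 * T_S / (2 E)``.

    The smallest threshold for which the interfering population vanishes (in
    the small-influx, steep-sigmoid idealization); the co-active population
    is maximal up to this point and decreases beyond it, so the within-pair
    output correlation is minimized here.
    """
    return (params.spontaneous * params.survival_threshold
            / (2.0 * params.amplitude))


def fixed_point_symmetric4(params: PopulationParams,
                           steepness_correction: bool = False) -> FixedPoint:
    """Closed-form steep-limit fixed point of the (a, b) system.

    Below the extinction threshold the interior fixed point is

        a* = (4E/T - 1) / (2w),
        b* = [ (E + 2 s0) / (theta + T/4) - 4E/T ] / (4w);

    above it the interfering population sits at the turnover floor
    ``alpha * dt`` and ``a*`` solves ``2 (sigma + d - theta) = T`` — a
    quadratic in the co-active inhibition.  The fixed point is continuous
    across the boundary.

    With ``steepness_correction=True`` the first-order finite-steepness
    correction is applied (interior regime): at the fixed point the
    resilience sits not exactly at the survival threshold but at
    ``T + ln(n / (alpha dt) - 1) / beta`` (from ``(1 - P) n = alpha dt``),
    and the closed-form equations are re-solved self-consistently; the
    corrected fixed point matches forward integration of the finite-beta
    population equations to high accuracy.
    """
    E, s0, w = params.amplitude, params.spontaneous, params.inh_weight
    T, th = params.survival_threshold, params.resilience_threshold
    alpha = params.influx * params.dt
    F = 4.0 * E / T
    if F <= 1.0:
        raise ValueError("no admissible fixed point: survival threshold "
                         "exceeds the maximal resilience scale (T >= 4E)")
    th_ext = extinction_threshold(params)
    if th <= th_ext:
        a = (F - 1.0) / (2.0 * w)
        b = ((E + 2.0 * s0) / (th + T / 4.0) - F) / (4.0 * w)
        if steepness_correction:
            beta = params.steepness
            for _ in range(20):
                eps_a = np.log(a / alpha - 1.0) / beta
                eps_b = np.log(b / alpha - 1.0) / beta
                d_t = T / 4.0 + eps_a / 2.0 - eps_b / 4.0
                sig_t = th + T / 4.0 + eps_b / 4.0
                a_new = (E / d_t - 1.0) / (2.0 * w)
                b_new = ((E + 2.0 * s0) / sig_t - 1.0 - 2.0 * w * a_new) / (4.0 * w)
                if abs(a_new - a) < 1e-10 and abs(b_new - b) < 1e-10:
                    a, b = a_new, b_new
                    break
                a, b = a_new, b_new
        return FixedPoint(a, b, "interior")
    # interfering population at the turnover floor
    c = 4.0 * w * alpha
    k = th + T / 2.0
    Ptot = E + 2.0 * s0
    disc = (k * c - Ptot - E) ** 2 + 4.0 * k * E * c
    x = (-(k * c - Ptot - E) + np.sqrt(disc)) / (2.0 * k)  # x = 1 + 2wa
    a = (x - 1.0) / (2.0 * w)
    if a <= alpha:
        return FixedPoint(alpha, alpha, "collapsed")
    return FixedPoint(a, alpha, "floor")


def discrete_fixed_point_prediction(params: PopulationParams) -> FixedPoint:
    """Mean-field prediction for the *discrete-time* stochastic simulation.

    The discrete model adds the influx and assesses the newborns within the
    same step, so its stationary post-removal count solves
    ``n = P (n + alpha dt)``, i.e. ``n = alpha dt P / (1 - P)`` — exactly
    ``alpha dt`` below the continuous-time fixed point at the same survival
    probability.  Combined with the first-order steepness correction this is
    the quantity a ``connections_per_cell = 2`` simulation on the
    delta = 0 training ensemble should reproduce (weak coupling, large
    populations).
    """
    fp = fixed_point_symmetric4(params, steepness_correction=True)
    shift = params.influx * params.dt
    return FixedPoint(fp.coactive - shift, fp.interfering - shift, fp.regime)


def pair_correlation_exact(a: float, b: float, params: PopulationParams
                           ) -> float:
    """Exact within-pair Pearson correlation of the 4-cell mitral outputs.

    For test stimuli ``E*(1,1,delta,0)`` and ``E*(1,1,0,delta)`` presented to
    the network with populations ``(a, b)`` the linear steady state gives

        r = (D^2 - 2 C^2) / (D^2 + 2 C^2),
        D = E (1 - delta/2) / (1 + 2wa),   C = E delta / (2 (1 + 2wb)).

    Derived by decomposing the stimuli into the symmetric and antisymmetric
    channel modes of the effective connectivity; independent of ``s0``
    because uniform shifts drop out of the Pearson correlation.
    """
    E, w, delta = params.amplitude, params.inh_weight, params.similarity
    D = E * (1.0 - delta / 2.0) / (1.0 + 2.0 * w * a)
    C = E * delta / 2.0 / (1.0 + 2.0 * w * b)
    return (D * D - 2.0 * C * C) / (D * D + 2.0 * C * C)


def correlation_expansion(a: float, b: float, params: PopulationParams
                          ) -> float:
    """Leading-order within-pair correlation for highly similar stimuli.

    Expansion of :func:`pair_correlation_exact` for small ``delta``:

        r ~ 1 - delta^2 [(1 + 2wa) / (1 + 2wb)]^2

    decreasing in the co-active inhibition ``a`` and increasing in the
    interfering strength ``b``; at ``a = b = 0`` it reduces to the
    uninhibited input correlation ``1 - delta^2``.
    """
    w, delta = params.inh_weight, params.similarity
    return 1.0 - delta ** 2 * ((1.0 + 2.0 * w * a) / (1.0 + 2.0 * w * b)) ** 2


def threshold_scan(params: PopulationParams, thresholds: Sequence[float],
                   method: str = "closed_form") -> dict:
    """Fixed points and within-pair correlation across resilience thresholds.

    ``method='closed_form'`` uses the steep-limit expressions;
    ``method='ode'`` forward-integrates the population equations for every
    threshold.  Returns arrays plus the correlation-minimizing threshold.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    a_arr = np.empty_like(thresholds)
    b_arr = np.empty_like(thresholds)
    r_arr = np.empty_like(thresholds)
    for i, th in enumerate(thresholds):
        p = replace(params, resilience_threshold=float(th))
        if method == "closed_form":
            fp = fixed_point_symmetric4(p)
            a, b = fp.coactive, fp.interfering
        elif method == "ode":
            a, b = integrate_populations(p, rtol=1e-10, atol=1e-12)
        else:
            raise ValueError(f"unknown method {method!r}")
        a_arr[i], b_arr[i] = a, b
        r_arr[i] = pair_correlation_exact(a, b, p)
    return {
        "thresholds": thresholds, "coactive": a_arr, "interfering": b_arr,
        "correlation": r_arr,
        "argmin_threshold": float(thresholds[np.argmin(r_arr)]),
        "optimal_threshold": optimal_threshold(params),
    }


@dataclass
class MixtureComparison:
    """Analytic comparison of the mixture and alternating enrichment protocols."""

    p_mixture: float
    p_pure_alt: float
    p_mixed_alt: float
    ordering_holds: bool


def mixture_nullcline_size(params: PopulationParams) -> float:
    """Steep-limit population size under the mixture protocol.

    With all four glomeruli driven equally at ``E/2`` all six populations are
    equal; their common size on the nullcline is

        p_mix = [ (E + 2 s0) / (theta + T/4) - 1 ] / (6w).
    """
    E, s0, w = params.amplitude, params.spontaneous, params.inh_weight
    T, th = params.survival_threshold, params.resilience_threshold
    return ((E + 2.0 * s0) / (th + T / 4.0) - 1.0) / (6.0 * w)


def mixture_comparison(params: PopulationParams) -> MixtureComparison:
    """Population ordering ``p_mixed_alt < p_mixture < p_pure_alt``.

    The alternating protocol (pure components as separate stimuli) yields
    the interior fixed point ``(a*, b*)`` of the symmetric system; the
    mixture protocol drives all four glomeruli equally, so all granule-cell
    populations share the single nullcline size ``p_mix``.  Because the total
    resilience of the mixed cells is matched across the protocols, ``p_mix``
    falls strictly between the alternating protocol's interfering (mixed)
    and co-active (pure) populations.  The ordering holds whenever the
    interior regime applies and ``(E + 2 s0)/(theta + T/4) < 12E/T - 2``.
    """
    fp = fixed_point_symmetric4(params)
    p_mix = mixture_nullcline_size(params)
    ok = (fp.regime == "interior"
          and fp.interfering < p_mix < fp.coactive)
    return MixtureComparison(p_mix, fp.coactive, fp.interfering, bool(ok))


def mixture_rhs(t: float, y: Sequence[float],
                params: PopulationParams) -> list[float]:
    """Mean-field dynamics of the common population under the mixture protocol."""
    p = max(y[0], 0.0)
    E, s0, w = params.amplitude, params.spontaneous, params.inh_weight
    th = params.resilience_threshold
    m = (E / 2.0 + s0) / (1.0 + 6.0 * w * p)
    res = 4.0 * max(2.0 * m - th, 0.0)
    return [params.influx - _removal_rate(res, params) * p]


def integrate_mixture(params: PopulationParams, t_max: float | None = None,
                      rtol: float = 1e-12) -> float:
    """Forward-integrate the mixture-protocol population to steady state."""
    if t_max is None:
        t_max = 4000.0 * params.dt
    sol = solve_ivp(mixture_rhs, (0.0, t_max), [0.0], args=(params,),
                    method="Radau", rtol=rtol, atol=1e-13)
    if not sol.success:
        raise RuntimeError(f"mixture ODE integration failed: {sol.message}")
    return float(sol.y[0, -1])


class PairPopulationModel:
    """Mean-field model for all ``M (M-1) / 2`` pair populations.

    General two-connection version of the reduced symmetric system: given an
    arbitrary ensemble matrix, tracks the mean size of every pair population
    ``n_ij``, with activities solved from the effective connectivity the
    populations generate.  Used to cross-check the symmetric-4 reduction and
    to explore asymmetric ensembles.
    """

    def __init__(self, ensemble_matrix: np.ndarray, params: PopulationParams):
        self.E = np.atleast_2d(np.asarray(ensemble_matrix, dtype=float))
        self.params = params
        self.n_mitral = self.E.shape[1]
        self.pairs = [(i, j) for i in range(self.n_mitral)
                      for j in range(i + 1, self.n_mitral)]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def connectivity(self, n: np.ndarray) -> np.ndarray:
        M = self.n_mitral
        W = np.zeros((M, M))
        for (i, j), size in zip(self.pairs, n):
            c = self.params.inh_weight * size
            W[i, i] += c
            W[j, j] += c
            W[i, j] += c
            W[j, i] += c
        return W

    def activities(self, n: np.ndarray) -> np.ndarray:
        """Mitral steady states (n_mitral, n_stimuli) for population sizes n."""
        W = self.connectivity(n)
        drive = self.E.T + self.params.spontaneous
        return np.linalg.solve(np.eye(self.n_mitral) + W, drive)

    def resiliences(self, n: np.ndarray) -> np.ndarray:
        m = self.activities(n)
        th = self.params.resilience_threshold
        out = np.empty(self.n_pairs)
        for k, (i, j) in enumerate(self.pairs):
            g = m[i] + m[j]
            out[k] = np.maximum(g - th, 0.0).sum()
        return out

    def rhs(self, t: float, n: np.ndarray) -> np.ndarray:
        n = np.maximum(n, 0.0)
        rates = _removal_rate(self.resiliences(n), self.params)
        return self.params.influx - rates * n

    def steady_state(self, t_max: float | None = None,
                     rtol: float = 1e-10) -> np.ndarray:
        if t_max is None:
            t_max = 4000.0 * self.params.dt
        sol = solve_ivp(self.rhs, (0.0, t_max), np.zeros(self.n_pairs),
                        method="Radau", rtol=rtol, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"pair-population ODE failed: {sol.message}")
        return sol.y[:, -1]
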