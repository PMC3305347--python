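# Methods

## The model

`bulbgenesis` simulates the structural plasticity of an olfactory-bulb-like
recurrent network in which the inhibitory interneurons — granule cells — are
continually replaced.  Principal cells (mitral cells) receive afferent
glomerular drive and disynaptic inhibition from granule cells through
reciprocal dendrodendritic synapses.  The neuronal dynamics are
threshold-linear and fast compared to the network restructuring, so only
their steady states matter: for stimulus `e` the mitral activities `m` and
granule activities `g` satisfy

    m_i = e_i + s0 - sum_j w_ji b_ji [g_j]_+
    g_j = sum_i c_ji [m_i]_+

with `c` the binary excitatory (mitral→granule) connections of unit
strength, `b` the inhibitory (granule→mitral) connections of strength
`w_ji`, and `s0` the spontaneous mitral activity.  Under full reciprocity
`b = c`.  With sufficient spontaneous activity essentially all rates are
positive, the rectifiers can be dropped, and the mitral steady state follows
from one linear solve per stimulus,

    (I + W) m = e + s0,     W = B_w^T C,

where `W` is the effective mitral–mitral connectivity: under uniform weights
and full reciprocity `W_ij = w x (number of granule cells connected to both
i and j)`, a Gram matrix — symmetric positive semi-definite.  The linear
solver is validated against a damped fixed-point iteration of the coupled
equations (to 1e-8 on networks up to 50 mitral / 500 granule cells); a
rectified mode (damped iteration, tolerance 1e-10) is available for regimes
where activities would go negative.  Linearized leaky-rate dynamics around
the steady state (unit relaxation rate; only the signs of the spectrum are
meaningful) are exposed for stability checks; all configurations exercised
by the test suite have strictly negative real parts.

The network evolves in discrete steps (one survival-assessment interval
each).  Per step: `influx` new granule cells are added, each wired
reciprocally to `K` distinct uniformly chosen mitral cells; the steady state
for every stimulus of the current ensemble is computed; each granule cell's
*resilience*

    R_j = sum_stimuli [ g_j - theta_R ]_+

is evaluated, and the cell survives with probability
`P(R) = logistic(beta (R - T_S))` (independent Bernoulli draws).  Newly
added cells are assessed within the same step.  The rectifier makes the
resilience favour peaky activity profiles over flat ones of the same total
(Jensen's inequality on a convex function), which is the mechanism that
suppresses "interfering" granule cells — cells connecting mitral cells that
are strongly active only during different stimuli.

## Mean-field population description

For two-connection networks (`K = 2`) the mean size `n_ij` of the granule
population connecting mitral pair `(i, j)` obeys

    dn_ij/dt = alpha - r(R_ij) n_ij,      r(R) = (1 - P(R)) / dt,

with `alpha` the per-population influx and activities computed from the
connectivity the populations generate.  The removal rate is bounded by
`1/dt` (one assessment per interval), so a population whose members all die
at first assessment settles at the turnover floor `alpha dt` rather than at
zero.

The analytical work uses a symmetric four-stimulus, four-glomerulus
ensemble: `E(1,1,d,0)`, `E(1,1,0,d)`, `E(d,0,1,1)`, `E(0,d,1,1)`.  The two
pairs are highly correlated for small `d`; training uses the simplified
`d = 0` ensemble.  By symmetry only two populations matter: co-active `a`
(pairs (1,2), (3,4)) and interfering `b` (the four cross pairs).  In the
steep-sigmoid limit the nullclines are `R = T_S`, and the fixed point has
closed forms:

* interior (`theta_R` below the extinction point):
  `a* = (4E/T_S - 1) / (2w)` — independent of `theta_R` —
  and `b* = [(E + 2 s0)/(theta_R + T_S/4) - 4E/T_S] / (4w)`, decreasing in
  `theta_R`;
* above the extinction point `b` sits at the turnover floor and `a*` solves
  a quadratic, decreasing in `theta_R`.

The smallest threshold extinguishing the interference is
`theta* = s0 T_S / (2E)` in the small-influx idealization
(`extinction_threshold` gives the finite-influx value, which converges to
`theta*` as `alpha -> 0`).  The within-pair correlation of the test stimuli
through the trained network is exactly

    r = (D^2 - 2 C^2) / (D^2 + 2 C^2),
    D = E (1 - d/2) / (1 + 2wa),   C = E d / (2 (1 + 2wb)),

(derived by decomposing the stimuli into the symmetry modes of `W`), with
the small-`d` expansion `r ~ 1 - d^2 [(1+2wa)/(1+2wb)]^2`: decreasing in the
co-active inhibition, increasing in the interfering strength, hence
minimized exactly at `theta*` — below it `b*` still carries interference,
above it `a*` starts to fall.

For the enrichment-protocol analysis the mixture protocol drives all four
glomeruli equally; all populations then share the nullcline size
`p_mix = [(E + 2 s0)/(theta_R + T_S/4) - 1] / (6w)`, which falls strictly
between `b*` and `a*` of the alternating protocol whenever
`(E + 2 s0)/(theta_R + T_S/4) < 12E/T_S - 2`; at equality all three
populations coincide (the protocols degenerate).

### Finite-steepness and finite-size corrections

Two documented corrections connect the idealized closed forms to
simulations:

1. *Finite steepness*: at the fixed point the resilience sits at
   `T_S + ln(n/(alpha dt) - 1)/beta`, not exactly at `T_S`; re-solving the
   closed forms self-consistently (`steepness_correction=True`) reproduces
   the finite-`beta` ODE fixed point to high accuracy.
2. *Discrete-time assessment*: the simulator adds the influx and assesses
   the newborns within the same step, so its stationary post-removal count
   solves `n = P (n + alpha dt)` — exactly `alpha dt` below the
   continuous-time fixed point (`discrete_fixed_point_prediction`).

The steep-`beta` and large-population limits do not commute in the
discrete model: at fixed population scale a very steep sigmoid turns
population fluctuations into mass-removal events (sawtooth dynamics far
below the deterministic fixed point).  The weak-coupling comparisons
therefore use a moderately steep sigmoid (`beta = 50`) at small weight
(`w = 0.002`, populations of order 100–600), where the discrete simulation
tracks the corrected mean-field prediction within Monte-Carlo error.

## Synthetic stimuli

Exact figure reproduction would require the archived rat glomerular
activation maps, which are not redistributable here; the package instead
generates *synthetic* natural-like odor maps (`synthetic_odor_set`): sums of
narrow Gaussian activation foci on a 14x28 glomerular sheet, down-sampled by
2x2 block maxima to 98 channels (the max rather than the mean preserves
focality).  The set emulates the qualitative structure of the real data:
two enantiomer-like pairs (within-pair Pearson > 0.9 via shared,
amplitude-jittered foci plus one weak private focus each, across-pair
overlap small), a homologous alcohol series with sliding shared foci, and a
distinct acid.  What the synthetic set does *not* emulate: the real maps'
spatial autocorrelation statistics, absolute channel counts (424 in the
archive), uptake nonlinearities, and inter-animal variability — so passing
tests demonstrate the mechanisms, not quantitative agreement with any
measured odor pair.  Real maps (grayscale images or numeric text matrices)
can be loaded through `load_pattern_image` / `load_pattern_text` and pushed
through the identical pipeline.

A geometry lesson is recorded here because it constrains applications: with
wide, strongly overlapping foci the common mode of a similar pair spreads
over many channels and even ideal co-active inhibition cannot decorrelate
the pair; focal maps (each focus covering ~1–2 channels) are required, which
matches the focality of the experimental uptake maps.

## Default parameters (study conditions)

Network runs on the synthetic odor set (98 channels), scaled down ~4x from
the 424-channel / ~10,000-cell system the model was originally formulated
for, keeping roughly ten granule cells per mitral cell at the plateau:

| parameter | default | meaning |
|---|---|---|
| `influx` | 25 cells/step | granule-cell supply per assessment interval |
| `connections_per_cell` (K) | 8 | mitral cells contacted per granule cell |
| `inh_weight` (w) | 0.008 | inhibitory synapse strength (excitatory = 1) |
| `spontaneous` (s0) | 0.2 | mitral baseline (stimulus amplitudes ~ 1) |
| `resilience_threshold` (theta_R) | 0.3 | per-stimulus activity threshold |
| `survival_threshold` (T_S) | 0.5 | soft threshold of the survival sigmoid |
| `steepness` (beta) | 10 | survival-sigmoid slope |

`theta_R = 0.3` sits in the interior regime: lowering it to 0 leaves the
mean decorrelation almost unchanged but visibly degrades the similar-pair
decorrelation, the model's key contrast.  The novelty experiments use
`beta = 2.5` (a differential young-cell response needs a survival curve
that is not too steep) and probe with `theta_IEG = theta_R`.  The `K = 1`
control of the enrichment comparison uses `theta_R = 0.05`, `T_S = 0.3`,
`w = 0.05`, because a single-source granule cell sees one mitral activity
rather than a sum of eight.  Runs of 600–1500 steps reach the statistical
plateau at these sizes; multi-run statistics use consecutive seeds from a
single base seed, and every simulation consumes exactly one seeded
generator (bit-identical reruns).

Enrichment protocols are compared at equal total stimulus exposure: the
mixture occupies as many presentation slots per assessment interval as the
pure odors it replaces.  This removes an overall-inhibition confound and
isolates the packaging of the drive — the quantity the comparison is about.
At `K = 1` the resilience is a linear functional of the stimuli wherever
the rectifier is inactive, so the two protocols are provably
indistinguishable there; the simulated control reproduces this exactly.

## Numerical choices

* Linear steady states: LAPACK solve of `(I + W) m = e + s0`; condition
  numbers above 1e12 raise.  Rectified mode: damped fixed-point iteration
  (damping 0.5, tolerance 1e-10, max 1e5 iterations).
* Population ODEs: stiff Radau integration (`rtol` down to 1e-12); the
  steep-limit comparisons use `beta = 1e7`–`1e8`, where forward integration
  agrees with the closed forms to better than 1e-6 relative.
* Nullclines: bracketed bisection (`brentq`, xtol 1e-12) on `R = T_S`.
* Rewiring rounding: `round(fraction x K)` targets moved per cell;
  collisions with the cell's remaining targets are resampled (a moved
  synapse may land on a previously vacated target).
* Zero-variance patterns: correlations are flagged undefined (`nan` plus a
  warning) and excluded from averages.
* Self/lateral rescaling (`gamma`): diagonal scaled by `gamma`, off-diagonal
  rescaled per row to preserve row sums exactly; infeasible combinations
  (negative off-diagonal scale) raise.
* Plateau detection: least-squares slope over a trailing window; the
  projected drift over the window must stay below 5% of the level.

## Known limitations

* Single-compartment, threshold-linear neurons; no spiking, no dendritic
  processing, no synaptic weight plasticity — inhibition changes only
  through cell turnover.
* The mean-field description covers `K = 2` only and requires large mean
  populations; small populations deviate (turnover floor, fluctuation
  shifts), which is why the discrete comparisons quote the corrected
  predictions above.
* Survival depends on activity only; age-dependent or top-down-modulated
  survival is out of scope.
* The linear coupling admits negative activities under strong inhibition;
  the rectified solver exists but the headline runs stay in regimes where
  the distortion is modest.
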