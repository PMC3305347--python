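"""Mitral-granule network state, steady-state solver, and connectivity tools.

The network couples ``M`` mitral cells to ``N`` granule cells through
reciprocal dendrodendritic synapses.  Within threshold-linear rate dynamics
the steady-state activities in response to stimulus ``e`` satisfy

    m_i = e_i + s0 - sum_j w_ji b_ji [g_j]_+
    g_j = sum_i c_ji [m_i]_+

where ``c`` marks excitatory mitral->granule connections (strength 1), ``b``
the inhibitory granule->mitral connections (strength ``w_ji``), and ``s0`` is
the spontaneous mitral activity.  Under full reciprocity ``b = c``.  With
sufficient spontaneous activity essentially all activities are positive and
the rectifiers can be dropped (linear coupling); the mitral steady state then
satisfies ``(I + W) m = e + s0`` with the effective mitral-mitral
connectivity ``W = B_w^T C`` — granule cells act as disynaptic lateral and
self-inhibition, and under uniform weights and reciprocity ``W`` is ``w``
times the Gram matrix of shared granule cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkState", "SteadyState", "solve_steady_state",
    "effective_connectivity", "rewire", "heterogenize_weights",
    "rescale_self_inhibition", "asymmetry_ratio", "stability_spectrum",
    "save_network", "load_network",
]


@dataclass
class NetworkState:
    """Connection structure and weights of the mitral-granule network.

    ``exc_sources[j, i]`` is True if granule cell ``j`` receives excitation
    from mitral cell ``i``; ``inh_targets[j, i]`` is True if it inhibits
    mitral cell ``i`` (equal to ``exc_sources`` under full reciprocity).
    ``inh_weights`` holds the per-synapse inhibitory strength on the support
    of ``inh_targets``; excitatory synapses have fixed strength 1.
    """

    n_mitral: int
    exc_sources: np.ndarray            # (N, M) bool
    inh_targets: np.ndarray            # (N, M) bool
    inh_weights: np.ndarray            # (N, M) float, nonzero only on targets
    spontaneous: float = 0.0
    birth_step: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    cohort: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    exc_weight: float = 1.0

    @classmethod
    def empty(cls, n_mitral: int, spontaneous: float = 0.0) -> "NetworkState":
        z = np.zeros((0, n_mitral))
        return cls(n_mitral, z.astype(bool), z.astype(bool), z.copy(),
                   spontaneous,
                   np.empty(0, dtype=int), np.empty(0, dtype=int))

    @property
    def n_granule(self) -> int:
        return self.exc_sources.shape[0]

    def validate(self, connections_per_cell: int | None = None) -> None:
        N, M = self.exc_sources.shape
        if M != self.n_mitral:
            raise ValueError("exc_sources width does not match n_mitral")
        for name, arr in (("inh_targets", self.inh_targets),
                          ("inh_weights", self.inh_weights)):
            if arr.shape != (N, M):
                raise ValueError(f"{name} shape mismatch")
        if np.any(self.inh_weights < 0):
            raise ValueError("inhibitory weights must be nonnegative")
        if np.any(self.inh_weights[~self.inh_targets] != 0):
            raise ValueError("weights outside inh_targets support")
        if connections_per_cell is not None and N > 0:
            k = self.exc_sources.sum(axis=1)
            if not np.all(k == connections_per_cell):
                raise ValueError("excitatory in-degree violates K")

    def add_granule_cells(self, n_new: int, connections_per_cell: int,
                          inh_weight: float, rng: np.random.Generator,
                          step: int = 0, cohort: int = 0) -> "NetworkState":
        """Return a network with ``n_new`` reciprocally wired granule cells.

        Each new cell connects to ``connections_per_cell`` distinct mitral
        cells chosen uniformly at random (no duplicate connections).
        """
        M = self.n_mitral
        K = connections_per_cell
        if K < 1 or K > M:
            raise ValueError("connections_per_cell must be in [1, n_mitral]")
        new_exc = np.zeros((n_new, M), dtype=bool)
        for j in range(n_new):
            new_exc[j, rng.choice(M, size=K, replace=False)] = True
        new_w = np.where(new_exc, float(inh_weight), 0.0)
        return NetworkState(
            M,
            np.vstack([self.exc_sources, new_exc]),
            np.vstack([self.inh_targets, new_exc.copy()]),
            np.vstack([self.inh_weights, new_w]),
            self.spontaneous,
            np.concatenate([self.birth_step, np.full(n_new, step, dtype=int)]),
            np.concatenate([self.cohort, np.full(n_new, cohort, dtype=int)]),
            self.exc_weight,
        )

    def keep(self, mask: np.ndarray) -> "NetworkState":
        """Network restricted to the granule cells where ``mask`` is True."""
        return NetworkState(
            self.n_mitral,
            self.exc_sources[mask], self.inh_targets[mask],
            self.inh_weights[mask], self.spontaneous,
            self.birth_step[mask], self.cohort[mask], self.exc_weight,
        )

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.n_mitral, self.exc_sources.copy(), self.inh_targets.copy(),
            self.inh_weights.copy(), self.spontaneous,
            self.birth_step.copy(), self.cohort.copy(), self.exc_weight,
        )


@dataclass
class SteadyState:
    """Steady-state activities for every stimulus of an ensemble.

    ``mitral`` has shape (n_mitral, n_stimuli); ``granule`` has shape
    (n_granule, n_stimuli).  ``residual`` is the maximum violation of the
    fixed-point equations.
    """

    mitral: np.ndarray
    granule: np.ndarray
    residual: float

    @property
    def n_stimuli(self) -> int:
        return self.mitral.shape[1]


def effective_connectivity(network: NetworkState, gamma: float = 1.0) -> np.ndarray:
    """Effective mitral-mitral inhibition ``W = B_w^T C`` (entry (i, j):
    total inhibitory weight onto ``i`` from granule cells excited by ``j``).

    With ``gamma != 1`` the self/lateral balance is rescaled via
    :func:`rescale_self_inhibition`.
    """
    W = network.exc_weight * (network.inh_weights.T
                              @ network.exc_sources.astype(float))
    if gamma != 1.0:
        W = rescale_self_inhibition(W, gamma)
    return W


def solve_steady_state(network: NetworkState, ensemble, coupling: str = "linear",
                       gamma: float = 1.0, tol: float = 1e-10,
                       max_iter: int = 100_000, damping: float = 0.5
                       ) -> SteadyState:
    """Solve the steady-state activities for every stimulus in the ensemble.

    ``coupling='linear'`` drops the rectifiers and reduces to one linear
    solve per stimulus in the mitral activities using the effective
    connectivity; ``coupling='rectified'`` runs a damped fixed-point
    iteration of the threshold-linear equations.  ``gamma`` rescales
    self- versus lateral inhibition of the effective connectivity (linear
    mode only).
    """
    E = np.atleast_2d(np.asarray(ensemble.matrix if hasattr(ensemble, "matrix")
                                 else ensemble, dtype=float))
    if E.shape[1] != network.n_mitral:
        raise ValueError("ensemble channels do not match network size")
    drive = E.T + network.spontaneous          # (M, S)
    C = network.exc_sources.astype(float)
    Bw = network.inh_weights

    if network.n_granule == 0:
        mitral = drive.copy()
        granule = np.zeros((0, drive.shape[1]))
        return SteadyState(mitral, granule, 0.0)

    if coupling == "linear":
        W = effective_connectivity(network, gamma=gamma)
        A = np.eye(network.n_mitral) + W
        try:
            mitral = np.linalg.solve(A, drive)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular effective-connectivity system: {exc}") from exc
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"ill-conditioned effective-connectivity system (cond={cond:.2e})")
        granule = network.exc_weight * (C @ mitral)
        if gamma == 1.0:
            resid = np.abs(mitral - (drive - Bw.T @ granule)).max()
        else:
            resid = np.abs(A @ mitral - drive).max()
        return SteadyState(mitral, granule, float(resid))

    if coupling != "rectified":
        raise ValueError(f"unknown coupling {coupling!r}")
    if gamma != 1.0:
        raise ValueError("gamma rescaling is defined for linear coupling only")

    relu = lambda x: np.maximum(x, 0.0)
    mitral = drive.copy()
    granule = network.exc_weight * (C @ relu(mitral))
    eta = damping
    for _ in range(int(max_iter)):
        new_m = drive - Bw.T @ relu(granule)
        new_g = network.exc_weight * (C @ relu(new_m))
        dm = np.abs(new_m - mitral).max()
        dg = np.abs(new_g - granule).max() if granule.size else 0.0
        mitral = (1 - eta) * mitral + eta * new_m
        granule = (1 - eta) * granule + eta * new_g
        if max(dm, dg) < tol:
            break
    else:
        raise RuntimeError(
            "rectified fixed-point iteration did not converge "
            "(unstable or strong-inhibition regime)")
    resid = np.abs(mitral - (drive - Bw.T @ relu(granule))).max()
    return SteadyState(mitral, granule, float(resid))


def rewire(network: NetworkState, fraction: float,
           rng: np.random.Generator) -> NetworkState:
    """Redirect a fraction of each granule cell's inhibitory connections.

    For every granule cell, ``round(fraction * K)`` of its inhibitory targets
    are replaced by uniformly chosen mitral cells (collisions with its other
    inhibitory targets are resampled).  Excitatory sources are unchanged, so
    the anatomical reciprocity of those synapses is broken.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = network.copy()
    if fraction == 0.0 or network.n_granule == 0:
        return out
    M = network.n_mitral
    for j in range(out.n_granule):
        targets = np.flatnonzero(out.inh_targets[j])
        n_move = int(round(fraction * targets.size))
        if n_move == 0:
            continue
        moved = rng.choice(targets, size=n_move, replace=False)
        keep = np.setdiff1d(targets, moved)
        weights = out.inh_weights[j, moved]
        current = set(keep.tolist())
        new_targets = []
        for _ in range(n_move):
            t = int(rng.integers(M))
            while t in current:
                t = int(rng.integers(M))
            current.add(t)
            new_targets.append(t)
        out.inh_targets[j, :] = False
        out.inh_targets[j, keep] = True
        out.inh_targets[j, new_targets] = True
        new_w = np.zeros(M)
        new_w[keep] = network.inh_weights[j, keep]
        new_w[new_targets] = weights
        out.inh_weights[j, :] = new_w
    return out


def heterogenize_weights(network: NetworkState, mode: str, delta: float,
                         rng: np.random.Generator) -> NetworkState:
    """Randomize inhibitory synaptic strengths around their mean.

    ``mode='two_point'`` draws each weight from ``{w - delta, w + delta}``
    with equal probability (at ``delta = w`` half the inhibitory synapses are
    completely ineffective); ``mode='uniform'`` draws uniformly on
    ``[w - delta, w + delta]``.  The expectation stays at the original
    weight.  Weights are perturbed independently per synapse, which breaks
    the symmetry of the effective connectivity.
    """
    if mode not in ("two_point", "uniform"):
        raise ValueError(f"unknown mode {mode!r}")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    out = network.copy()
    support = out.inh_targets
    w = out.inh_weights[support]
    if np.any(delta > w):
        raise ValueError("delta exceeds a synaptic weight (negative weights)")
    if mode == "two_point":
        signs = rng.choice([-1.0, 1.0], size=w.size)
        out.inh_weights[support] = w + delta * signs
    else:
        out.inh_weights[support] = rng.uniform(w - delta, w + delta)
    return out


def rescale_self_inhibition(W: np.ndarray, gamma: float) -> np.ndarray:
    """Trade self-inhibition against lateral inhibition at fixed row sums.

    The diagonal of ``W`` is multiplied by ``gamma``; each row's off-diagonal
    entries are rescaled by the row-specific factor restoring the original
    row sum.  ``gamma < 1`` strengthens lateral inhibition at the expense of
    self-inhibition.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    out = W.copy()
    diag = np.diag(W).copy()
    rowsum = W.sum(axis=1)
    off = rowsum - diag
    target_off = rowsum - gamma * diag
    factors = np.ones_like(off)
    nz = off > 0
    factors[nz] = target_off[nz] / off[nz]
    if np.any(target_off < -1e-12 * np.maximum(rowsum, 1.0)):
        raise ValueError("gamma demands negative off-diagonal scaling")
    out *= factors[:, None]
    np.fill_diagonal(out, gamma * diag)
    return out


def asymmetry_ratio(W: np.ndarray) -> float:
    """Frobenius-norm ratio of the antisymmetric to the symmetric part."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    S = 0.5 * (W + W.T)
    A = 0.5 * (W - W.T)
    ns = np.linalg.norm(S)
    if ns == 0.0:
        raise ZeroDivisionError("symmetric part of W vanishes")
    return float(np.linalg.norm(A) / ns)


def stability_spectrum(network: NetworkState) -> np.ndarray:
    """Eigenvalues of the linearized activity dynamics around a steady state.

    The steady states are embedded in leaky rate dynamics with unit
    relaxation rate,

        dm/dt = -m + e + s0 - B_w^T g,   dg/dt = -g + C m,

    whose Jacobian ``[[-I, -B_w^T], [C, -I]]`` is stimulus independent in the
    linear-coupling mode.  The signs of the real parts (the stability
    verdict) do not depend on the choice of time constant.
    """
    N, M = network.exc_sources.shape
    if N == 0:
        return np.full(M, -1.0 + 0j)
    C = network.exc_weight * network.exc_sources.astype(float)
    J = np.block([
        [-np.eye(M), -network.inh_weights.T],
        [C, -np.eye(N)],
    ])
    return np.linalg.eigvals(J)


def save_network(network: NetworkState, path: str | Path) -> None:
    """Serialize a network snapshot to an HDF5 container (sparse index lists)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["n_mitral"] = network.n_mitral
        f.attrs["n_granule"] = network.n_granule
        f.attrs["spontaneous"] = network.spontaneous
        f.attrs["exc_weight"] = network.exc_weight
        gj, gi = np.nonzero(network.exc_sources)
        f.create_dataset("exc/granule", data=gj)
        f.create_dataset("exc/mitral", data=gi)
        bj, bi = np.nonzero(network.inh_targets)
        f.create_dataset("inh/granule", data=bj)
        f.create_dataset("inh/mitral", data=bi)
        f.create_dataset("inh/weight", data=network.inh_weights[bj, bi])
        f.create_dataset("birth_step", data=network.birth_step)
        f.create_dataset("cohort", data=network.cohort)


def load_network(path: str | Path) -> NetworkState:
    """Load a network snapshot written by :func:`save_network`."""
    import h5py

    with h5py.File(path, "r") as f:
        M = int(f.attrs["n_mitral"])
        N = int(f.attrs["n_granule"])
        net = NetworkState(
            M,
            np.zeros((N, M), dtype=bool), np.zeros((N, M), dtype=bool),
            np.zeros((N, M)),
            float(f.attrs["spontaneous"]),
            f["birth_step"][...].astype(int), f["cohort"][...].astype(int),
            float(f.attrs["exc_weight"]),
        )
        net.exc_sources[f["exc/granule"][...], f["exc/mitral"][...]] = True
        bj, bi = f["inh/granule"][...], f["inh/mitral"][...]
        net.inh_targets[bj, bi] = True
        net.inh_weights[bj, bi] = f["inh/weight"][...]
    return net
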