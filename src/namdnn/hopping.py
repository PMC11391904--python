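"""Fewest-switches surface hopping (FSSH) driven by exact or ML surfaces.

Nuclei move classically (velocity Verlet) on the active adiabatic surface;
electronic coefficients evolve in the adiabatic basis,

    i ċ_j = E_j c_j − i Σ_k (v · C_jk) c_k,

integrated with a unitary short-step exponential over ``n_substeps``
sub-intervals per nuclear step, with E and v·C linearly interpolated
between the nuclear endpoints. Stochastic hops use the fewest-switches
probability g_{a→j} = max(0, 2 Δt Re(c_a* c_j (v·C_aj)) / |c_a|²); accepted
hops rescale the velocity along the classical NAC direction to conserve
total energy, and hops without enough projected kinetic energy are
frustrated. The total energy of every trajectory is monitored and the
trajectory is flagged invalid once the drift exceeds a configurable bound.

NAC signs follow the eigenvector sign convention of the provider, which is
arbitrary point to point; the propagator therefore re-aligns each coupling
vector with its direction at the previous step (per pair, per trajectory),
which keeps the electronic propagation consistent for exact and ML
surfaces alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import units
from .data import Geometry, StateSpace, unsmooth_nacs
from .heads import ExcitedStateModel
from .models import DiabaticModel, adiabatize_batch
from .representation import collate

__all__ = [
    "SHConfig", "SHState", "HopRecord", "TrajectoryLog",
    "ExactSurfaceProvider", "MLSurfaceProvider", "make_provider",
    "velocity_verlet_step", "propagate_coefficients", "hop_probabilities",
    "attempt_hop", "run_trajectory", "run_ensemble",
    "ensemble_populations", "fit_sequential_kinetics",
]


@dataclass
class SHConfig:
    dt_fs: float = 0.5
    n_substeps: int = 25
    t_max_fs: float = 100.0
    initial_state: int = 1
    decoherence: str = "energy_based"        # or "none"
    decoherence_c: float = 0.1               # Hartree
    frustrated_hop: str = "ignore"           # or "reflect"
    energy_drift_abort: float = 0.2 * units.EV   # ~0.0074 Hartree
    seed: int = 0
    gap_floor: float = 1e-8

    def __post_init__(self):
        if self.dt_fs <= 0 or self.n_substeps < 1:
            raise ValueError("dt must be > 0 and n_substeps >= 1")
        if self.decoherence not in ("none", "energy_based"):
            raise ValueError(f"unknown decoherence {self.decoherence!r}")
        if self.frustrated_hop not in ("ignore", "reflect"):
            raise ValueError(
                f"unknown frustrated_hop policy {self.frustrated_hop!r}")

    @property
    def dt(self) -> float:
        return self.dt_fs * units.FS

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max_fs / self.dt_fs))


@dataclass
class SHState:
    """Instantaneous state of one surface-hopping trajectory."""

    positions: np.ndarray      # [n, 3] Bohr
    velocities: np.ndarray     # [n, 3] Bohr per a.u. time
    masses: np.ndarray         # [n] electron masses
    active_state: int
    coefficients: np.ndarray   # complex [S], sum |c|^2 = 1
    time: float = 0.0          # a.u.

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        norm = np.sum(np.abs(self.coefficients) ** 2)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError("electronic coefficients must be normalized")
        if self.active_state >= self.coefficients.shape[0]:
            raise ValueError("active state outside the state space")

    def kinetic_energy(self) -> float:
        return 0.5 * float(
            np.sum(self.masses[:, None] * self.velocities ** 2))


@dataclass
class HopRecord:
    time: float                # fs
    from_state: int
    to_state: int
    probability: float
    random_draw: float
    outcome: str               # accepted | frustrated | none

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("hop probability outside [0, 1]")


@dataclass
class TrajectoryLog:
    times: np.ndarray          # [T+1] fs
    active: np.ndarray         # [T+1]
    energies: np.ndarray       # [T+1, S]
    coeff_populations: np.ndarray  # [T+1, S]
    total_energy: np.ndarray   # [T+1]
    hops: list
    valid_until: int           # first invalid step index (len(times) if none)
    positions: Optional[np.ndarray] = None  # [T+1, n, 3] if recorded

    @property
    def valid(self) -> bool:
        return self.valid_until >= len(self.times)


# ---------------------------------------------------------------------------
# surface providers
# ---------------------------------------------------------------------------

class ExactSurfaceProvider:
    """Adiabatic energies/forces/NACs straight from a diabatic model."""

    def __init__(self, model: DiabaticModel, gap_floor: float = 1e-8):
        self.model = model
        self.gap_floor = gap_floor
        self.masses = model.masses
        self.n_states = model.n_states

    def evaluate(self, positions: np.ndarray):
        props = adiabatize_batch(self.model, positions)
        sm, gaps = props["smooth_nacs"], props["gaps"]
        signs = np.where(gaps >= 0, 1.0, -1.0)
        div = signs * np.maximum(np.abs(gaps), self.gap_floor)
        nacs = sm / div[:, :, None, None]
        return props["energies"], props["forces"], nacs


class MLSurfaceProvider:
    """Energies, forces and classical NACs from a trained model."""

    def __init__(self, model: ExcitedStateModel, atomic_numbers, masses,
                 total_charge: int = 0):
        self.model = model
        self.atomic_numbers = np.asarray(atomic_numbers)
        self.masses = np.asarray(masses, dtype=float)
        self.total_charge = total_charge
        self.n_states = model.config.n_states
        self.space = model.state_space

    def evaluate(self, positions: np.ndarray):
        geos = [Geometry(self.atomic_numbers, p, self.total_charge)
                for p in positions]
        batch = collate(geos, self.model.config.representation.cutoff)
        self.model.set_requires(False)
        try:
            out = self.model.forward(batch, ("energies", "forces", "nacs"))
        finally:
            self.model.set_requires(True)
        B, n = positions.shape[0], positions.shape[1]
        S, P = self.n_states, self.space.n_pairs
        energies = out["energies"].value                       # [B,S]
        forces = out["forces"].value.reshape(S, B, n, 3).transpose(1, 0, 2, 3)
        sm = out["smooth_nacs"].value.reshape(P, B, n, 3).transpose(1, 0, 2, 3)
        nacs = np.stack([
            unsmooth_nacs(sm[b], energies[b], self.space,
                          self.model.config.gap_floor)
            for b in range(B)])
        return energies, forces, nacs


def make_provider(surface, **kwargs):
    if isinstance(surface, DiabaticModel):
        return ExactSurfaceProvider(surface, **kwargs)
    if isinstance(surface, ExcitedStateModel):
        return MLSurfaceProvider(surface, **kwargs)
    if hasattr(surface, "evaluate"):
        return surface
    raise TypeError(f"cannot build a surface provider from {type(surface)}")


# ---------------------------------------------------------------------------
# elementary steps (single-trajectory API)
# ---------------------------------------------------------------------------

def velocity_verlet_step(state: SHState, forces_provider: Callable,
                         dt: float) -> SHState:
    """One velocity-Verlet step on the active surface.

    ``forces_provider(positions) -> force [n, 3]`` on the active state.
    """
    m = state.masses[:, None]
    f0 = np.asarray(forces_provider(state.positions))
    if not np.all(np.isfinite(f0)):
        raise RuntimeError(
            f"non-finite forces at t={state.time}; geometry:\n"
            f"{state.positions}")
    a0 = f0 / m
    new_pos = state.positions + state.velocities * dt + 0.5 * a0 * dt ** 2
    f1 = np.asarray(forces_provider(new_pos))
    if not np.all(np.isfinite(f1)):
        raise RuntimeError(
            f"non-finite forces at t={state.time + dt}; geometry:\n{new_pos}")
    new_vel = state.velocities + 0.5 * (a0 + f1 / m) * dt
    return SHState(new_pos, new_vel, state.masses, state.active_state,
                   state.coefficients.copy(), state.time + dt)


def _unitary_substeps(c, e0, e1, vc0, vc1, dt, n_substeps):
    """Propagate coefficients with midpoint-interpolated H per substep.

    Batched: c [B,S] complex, e [B,S], vc [B,S,S] real antisymmetric.
    """
    sub = dt / n_substeps
    for k in range(n_substeps):
        f = (k + 0.5) / n_substeps
        e = (1 - f) * e0 + f * e1
        vc = (1 - f) * vc0 + f * vc1
        h = np.zeros(vc.shape, dtype=complex)
        idx = np.arange(e.shape[-1])
        h[..., idx, idx] = e
        h -= 1j * vc
        w, q = np.linalg.eigh(h)
        phase = np.exp(-1j * w * sub)
        u = np.einsum("...ij,...j,...kj->...ik", q, phase, q.conj())
        c = np.einsum("...ij,...j->...i", u, c)
    return c


def propagate_coefficients(coefficients, energies, nac_dot_velocity,
                           dt: float, n_substeps: int = 25) -> np.ndarray:
    """Propagate electronic coefficients across one nuclear step.

    ``energies`` and ``nac_dot_velocity`` are pairs (value at t, value at
    t+dt); the v·C matrix is real antisymmetric with [j, k] = v·C_jk.
    Norm-preserving by construction (each substep is unitary).
    """
    c = np.asarray(coefficients, dtype=complex)
    e0, e1 = (np.asarray(e, dtype=float) for e in energies)
    vc0, vc1 = (np.asarray(v, dtype=float) for v in nac_dot_velocity)
    squeeze = c.ndim == 1
    if squeeze:
        c, e0, e1, vc0, vc1 = (x[None] for x in (c, e0, e1, vc0, vc1))
    c = _unitary_substeps(c, e0, e1, vc0, vc1, dt, n_substeps)
    return c[0] if squeeze else c


def hop_probabilities(coefficients, active: int, nac_dot_velocity,
                      dt: float) -> np.ndarray:
    """Fewest-switches hop probabilities g_j out of the active state."""
    c = np.asarray(coefficients, dtype=complex)
    vc = np.asarray(nac_dot_velocity, dtype=float)
    pop_a = float(np.abs(c[active]) ** 2)
    if pop_a < 1e-12:
        warnings.warn("active-state population ~ 0; hop probabilities set "
                      "to zero", RuntimeWarning)
        return np.zeros(c.shape[0])
    flux = 2.0 * dt * np.real(np.conj(c[active]) * c * vc[active, :])
    g = np.maximum(flux / pop_a, 0.0)
    g[active] = 0.0
    total = g.sum()
    if total > 1.0:
        g /= total
    return g


def _rescale_velocities(velocities, masses, direction, delta_e, policy):
    """Energy-conserving rescaling along ``direction`` for a hop with
    energy change ``delta_e`` = E_new − E_old. Returns (velocities, ok)."""
    d = direction
    a2 = float(np.sum(d * d / masses[:, None]))
    if a2 < 1e-30:   # no coupling direction: accept only if iso-energetic
        return velocities, abs(delta_e) < 1e-12
    b = float(np.sum(velocities * d))
    disc = b * b - 2.0 * a2 * delta_e
    if disc < 0.0:
        if policy == "reflect":
            velocities = velocities - 2.0 * (b / a2) * d / masses[:, None]
        return velocities, False
    root = np.sqrt(disc)
    g1, g2 = (b - root) / a2, (b + root) / a2
    gamma = g1 if abs(g1) <= abs(g2) else g2
    return velocities - gamma * d / masses[:, None], True


def attempt_hop(state: SHState, probabilities: np.ndarray,
                energies: np.ndarray, nacs: np.ndarray, space: StateSpace,
                rng, frustrated_hop: str = "ignore"):
    """Draw a hop target by inverse CDF and apply momentum rescaling.

    Returns ``(new_state, HopRecord)``. ``nacs`` are classical coupling
    vectors per pair, [P, n, 3].
    """
    g = np.asarray(probabilities, dtype=float)
    if g.sum() > 1.0 + 1e-12:
        raise ValueError("cumulative hop probability exceeds 1")
    draw = float(rng.uniform())
    cum = np.cumsum(g)
    target = None
    for j in range(g.shape[0]):
        if g[j] > 0 and draw < cum[j]:
            target = j
            break
    time_fs = state.time / units.FS
    if target is None:
        return state, HopRecord(time_fs, state.active_state,
                                state.active_state, float(g.sum()), draw,
                                "none")
    a = state.active_state
    i, j = min(a, target), max(a, target)
    direction = nacs[space.pair_index(i, j)]
    delta_e = float(energies[target] - energies[a])
    new_vel, ok = _rescale_velocities(state.velocities.copy(), state.masses,
                                      direction, delta_e, frustrated_hop)
    outcome = "accepted" if ok else "frustrated"
    new_active = target if ok else a
    new_state = SHState(state.positions.copy(), new_vel, state.masses,
                        new_active, state.coefficients.copy(), state.time)
    return new_state, HopRecord(time_fs, a, target, float(g[target]), draw,
                                outcome)


# ---------------------------------------------------------------------------
# trajectory and ensemble drivers
# ---------------------------------------------------------------------------

def _vc_matrix(nacs, velocities, space: StateSpace):
    """v·C matrices [B,S,S] (antisymmetric) from pair NACs [B,P,n,3]."""
    B = nacs.shape[0]
    S = space.n_states
    vc = np.zeros((B, S, S))
    proj = np.einsum("bpnd,bnd->bp", nacs, velocities)
    for p, (i, j) in enumerate(space.pairs):
        vc[:, i, j] = proj[:, p]
        vc[:, j, i] = -proj[:, p]
    return vc


def _apply_decoherence(c, active, energies, ekin, dt, c_param):
    """Energy-based decoherence damping toward the active state."""
    B, S = c.shape
    idx = np.arange(B)
    e_act = energies[idx, active]
    gap = np.abs(energies - e_act[:, None])
    with np.errstate(divide="ignore"):
        tau = (1.0 + c_param / np.maximum(ekin, 1e-12)[:, None]) \
            / np.maximum(gap, 1e-12)
    damp = np.exp(-dt / tau)
    damp[idx, active] = 1.0
    damp[gap < 1e-12] = 1.0
    c = c * damp
    pop_other = np.sum(np.abs(c) ** 2, axis=1) - np.abs(c[idx, active]) ** 2
    pop_act = np.abs(c[idx, active]) ** 2
    scale = np.ones(B)
    mask = pop_act > 1e-30
    scale[mask] = np.sqrt((1.0 - pop_other[mask]) / pop_act[mask])
    c[idx, active] *= scale
    return c


def run_ensemble(surface, initial_positions, initial_velocities, masses,
                 config: SHConfig, record_positions: bool = False,
                 initial_coefficients: Optional[np.ndarray] = None) -> list:
    """Propagate an ensemble of FSSH trajectories in lockstep.

    All trajectories share the time grid, so the surface provider is
    evaluated on the whole batch at every step — the efficient path for ML
    surfaces. Returns one :class:`TrajectoryLog` per trajectory;
    reproducible for a fixed ``config.seed``.
    """
    provider = make_provider(surface)
    pos = np.array(initial_positions, dtype=float)
    vel = np.array(initial_velocities, dtype=float)
    if pos.ndim == 2:
        pos, vel = pos[None], vel[None]
    B, n, _ = pos.shape
    masses = np.asarray(masses, dtype=float)
    S = provider.n_states
    space = StateSpace(S)
    n_steps = config.n_steps
    dt = config.dt
    rng = np.random.default_rng(config.seed)

    active = np.full(B, config.initial_state, dtype=int)
    c = np.zeros((B, S), dtype=complex)
    c[:, config.initial_state] = 1.0
    if initial_coefficients is not None:
        c = np.array(initial_coefficients, dtype=complex)
        if c.ndim == 1:
            c = np.repeat(c[None], B, axis=0)
    alive = np.ones(B, dtype=bool)       # still propagated
    valid_until = np.full(B, n_steps + 1, dtype=int)
    idx = np.arange(B)

    energies = np.zeros((n_steps + 1, B, S))
    pops = np.zeros((n_steps + 1, B, S))
    act_hist = np.zeros((n_steps + 1, B), dtype=int)
    etot_hist = np.zeros((n_steps + 1, B))
    pos_hist = np.zeros((n_steps + 1, B, n, 3)) if record_positions else None
    hops: list = [[] for _ in range(B)]

    e, f, cnac = provider.evaluate(pos)
    finite = np.isfinite(e).all(axis=1) & \
        np.isfinite(f).all(axis=(1, 2, 3)) & np.isfinite(cnac).all(axis=(1, 2, 3))
    alive &= finite
    valid_until[~finite] = 0
    ekin = 0.5 * np.sum(masses[None, :, None] * vel ** 2, axis=(1, 2))
    e0_tot = ekin + e[idx, active]

    def snapshot(t):
        energies[t] = e
        pops[t] = np.abs(c) ** 2
        act_hist[t] = active
        etot_hist[t] = ekin + e[idx, active]
        if record_positions:
            pos_hist[t] = pos

    snapshot(0)

    for t in range(1, n_steps + 1):
        draws = rng.uniform(size=B)
        if not alive.any():
            snapshot(t)
            continue
        m3 = masses[None, :, None]
        f_act = f[idx, active]                       # [B,n,3]
        acc0 = f_act / m3
        new_pos = np.where(alive[:, None, None],
                           pos + vel * dt + 0.5 * acc0 * dt ** 2, pos)
        e1, f1, cnac1 = provider.evaluate(new_pos)
        finite = np.isfinite(e1).all(axis=1) & \
            np.isfinite(f1).all(axis=(1, 2, 3)) & \
            np.isfinite(cnac1).all(axis=(1, 2, 3))
        died = alive & ~finite
        valid_until[died] = np.minimum(valid_until[died], t)
        alive &= finite
        # keep stale-but-finite values for dead trajectories
        e1 = np.where(finite[:, None], e1, e)
        f1 = np.where(finite[:, None, None, None], f1, f)
        cnac1 = np.where(finite[:, None, None, None], cnac1, cnac)

        # phase continuity: align each NAC with its previous direction
        overlap = np.einsum("bpnd,bpnd->bp", cnac1, cnac)
        signs = np.where(overlap < 0, -1.0, 1.0)
        cnac1 = cnac1 * signs[:, :, None, None]

        acc1 = f1[idx, active] / m3
        new_vel = np.where(alive[:, None, None],
                           vel + 0.5 * (acc0 + acc1) * dt, vel)

        vc0 = _vc_matrix(cnac, vel, space)
        vc1 = _vc_matrix(cnac1, new_vel, space)
        c_new = _unitary_substeps(c, e, e1, vc0, vc1, dt, config.n_substeps)
        c = np.where(alive[:, None], c_new, c)

        ekin = 0.5 * np.sum(m3 * new_vel ** 2, axis=(1, 2))
        # hops
        pop_act = np.abs(c[idx, active]) ** 2
        flux = 2.0 * dt * np.real(
            np.conj(c[idx, active])[:, None] * c
            * vc1[idx, active, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.maximum(flux / pop_act[:, None], 0.0)
        g[pop_act < 1e-12] = 0.0
        g[idx, active] = 0.0
        tot = g.sum(axis=1)
        over = tot > 1.0
        g[over] /= tot[over, None]
        cum = np.cumsum(g, axis=1)
        for b in np.nonzero(alive)[0]:
            if tot[b] <= 0:
                continue
            target = None
            for j in range(S):
                if g[b, j] > 0 and draws[b] < cum[b, j]:
                    target = j
                    break
            if target is None:
                continue
            a = active[b]
            pair = space.pair_index(min(a, target), max(a, target))
            vres, ok = _rescale_velocities(
                new_vel[b], masses, cnac1[b, pair],
                float(e1[b, target] - e1[b, a]), config.frustrated_hop)
            new_vel[b] = vres
            if ok:
                active[b] = target
            hops[b].append(HopRecord(t * config.dt_fs, a, target,
                                     float(g[b, target]), float(draws[b]),
                                     "accepted" if ok else "frustrated"))
        ekin = 0.5 * np.sum(m3 * new_vel ** 2, axis=(1, 2))

        if config.decoherence == "energy_based":
            c_dec = _apply_decoherence(c.copy(), active, e1, ekin, dt,
                                       config.decoherence_c)
            c = np.where(alive[:, None], c_dec, c)

        pos, vel, e, f, cnac = new_pos, new_vel, e1, f1, cnac1
        etot = ekin + e[idx, active]
        drift = np.abs(etot - e0_tot)
        bad = alive & (drift > config.energy_drift_abort)
        valid_until[bad] = np.minimum(valid_until[bad], t)
        alive &= ~bad
        snapshot(t)

    times_fs = np.arange(n_steps + 1) * config.dt_fs
    logs = []
    for b in range(B):
        logs.append(TrajectoryLog(
            times=times_fs.copy(), active=act_hist[:, b].copy(),
            energies=energies[:, b].copy(),
            coeff_populations=pops[:, b].copy(),
            total_energy=etot_hist[:, b].copy(), hops=hops[b],
            valid_until=int(valid_until[b]),
            positions=pos_hist[:, b].copy() if record_positions else None))
    return logs


def run_trajectory(surface, initial_conditions, config: SHConfig,
                   masses=None, record_positions: bool = True
                   ) -> TrajectoryLog:
    """Run a single FSSH trajectory.

    ``initial_conditions`` is an :class:`SHState` or a (positions,
    velocities) pair (then ``masses`` is required unless the surface is a
    diabatic model or provider carrying masses).
    """
    coeffs = None
    if isinstance(initial_conditions, SHState):
        pos, vel = initial_conditions.positions, initial_conditions.velocities
        masses = initial_conditions.masses
        coeffs = initial_conditions.coefficients
        config = replace_initial(config, initial_conditions.active_state)
    else:
        pos, vel = initial_conditions
        if masses is None:
            masses = getattr(make_provider(surface), "masses", None)
        if masses is None:
            raise ValueError("masses are required")
    (log,) = run_ensemble(surface, pos[None], vel[None], masses, config,
                          record_positions=record_positions,
                          initial_coefficients=coeffs)
    return log


def replace_initial(config: SHConfig, state: int) -> SHConfig:
    from dataclasses import replace
    return replace(config, initial_state=state)


# ---------------------------------------------------------------------------
# ensemble analysis
# ---------------------------------------------------------------------------

def ensemble_populations(logs: Sequence[TrajectoryLog],
                         time_grid: Optional[np.ndarray] = None):
    """Active-state population fractions over time across an ensemble.

    Trajectories are excluded from every time point at or beyond their
    first invalid step. Returns ``(times, populations [T,S], se [T,S],
    n_valid [T])`` with populations masked (NaN) where no trajectory is
    valid; ``se`` is the binomial standard error.
    """
    if not logs:
        raise ValueError("no trajectories")
    times = logs[0].times if time_grid is None else np.asarray(time_grid)
    S = logs[0].energies.shape[1]
    T = len(times)
    counts = np.zeros((T, S))
    n_valid = np.zeros(T, dtype=int)
    for log in logs:
        # map requested times onto the log's grid
        t_idx = np.searchsorted(log.times, times)
        t_idx = np.clip(t_idx, 0, len(log.times) - 1)
        ok = t_idx < log.valid_until
        for t in np.nonzero(ok)[0]:
            counts[t, log.active[t_idx[t]]] += 1
            n_valid[t] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        populations = counts / n_valid[:, None]
        se = np.sqrt(populations * (1 - populations)
                     / np.maximum(n_valid, 1)[:, None])
    populations[n_valid == 0] = np.nan
    se[n_valid == 0] = np.nan
    return times, populations, se, n_valid


def sequential_populations(times, rates) -> np.ndarray:
    """Closed-form populations of the chain S_{m} -> S_{m-1} -> ... -> S_0.

    ``rates[k]`` is the decay rate of state k+1 into state k; everything
    starts in the top state. Returns [T, m+1] (columns are S_0 ... S_m).
    """
    times = np.asarray(times, dtype=float)
    m = len(rates)
    # distinct-rate Bateman solution; split exact ties by a tiny,
    # index-dependent perturbation (relative error O(1e-9))
    rates = np.array(rates, dtype=float)
    close = np.abs(rates[:, None] - rates[None, :]) \
        < 1e-9 * np.maximum(np.abs(rates[:, None]), 1e-30)
    np.fill_diagonal(close, False)
    if close.any():
        rates = rates * (1.0 + 1e-8 * np.arange(1, len(rates) + 1))
    P = np.zeros((len(times), m + 1))
    # chain states top..bottom: indices m, m-1, ..., 0
    # population of state k (1..m) given sequential decay with rates
    # lambda_k = rates[k-1] (decay of state k)
    lam = rates
    # Bateman for a chain starting in state m
    for s in range(m, 0, -1):
        # product formula for the s-th member (states m down to s)
        ks = lam[np.arange(s - 1, m)]       # rates of states s..m
        coef = np.prod(ks[1:]) if len(ks) > 1 else 1.0
        total = np.zeros_like(times)
        for i_, ki in enumerate(ks):
            denom = np.prod([kj - ki for j_, kj in enumerate(ks)
                             if j_ != i_]) if len(ks) > 1 else 1.0
            total += np.exp(-ki * times) / denom
        P[:, s] = coef * total
    P[:, 0] = 1.0 - P[:, 1:].sum(axis=1)
    return P


def fit_sequential_kinetics(populations: np.ndarray, times: np.ndarray,
                            n_states: Optional[int] = None) -> dict:
    """Fit first-order sequential kinetics S_{S-1} → … → S_0.

    Least-squares fit of the closed-form solution to all state populations
    jointly. Returns rates (1/unit of ``times``), lifetimes tau = 1/k, the
    residual RMS, and ``tau_infinite`` when the populations never decay.
    """
    populations = np.asarray(populations, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = np.all(np.isfinite(populations), axis=1)
    populations, times = populations[mask], times[mask]
    S = populations.shape[1] if n_states is None else n_states
    top = populations[:, S - 1]
    if top.max() - top.min() < 1e-8:
        if top.min() > 1.0 - 1e-6:
            return {"rates": np.zeros(S - 1), "lifetimes":
                    np.full(S - 1, np.inf), "residual": 0.0,
                    "tau_infinite": True}
        raise ValueError(
            "populations are flat but not fully in the initial state; "
            "sequential kinetics is not identifiable from this input")
    span = times[-1] - times[0]
    # crude initial guess: time of 1/e decay of the top state
    below = np.nonzero(top < np.exp(-1.0))[0]
    t0 = times[below[0]] if below.size else 0.5 * span
    k_init = np.full(S - 1, 1.0 / max(t0, 1e-6 * span))

    def resid(logk):
        model = sequential_populations(times, np.exp(logk))
        return (model - populations).ravel()

    sol = least_squares(resid, np.log(k_init), method="lm", xtol=1e-14,
                        ftol=1e-14)
    rates = np.exp(sol.x)
    res = float(np.sqrt(np.mean(sol.fun ** 2)))
    return {"rates": rates, "lifetimes": 1.0 / rates, "residual": res,
            "tau_infinite": False}
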