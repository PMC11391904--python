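"""Analytic multi-state diabatic model Hamiltonians.

These models play the role that ab initio reference calculations play for
real molecules: they provide exact adiabatic energies, forces, NAC vectors
and dipoles at any geometry, so the whole pipeline — dataset generation,
training, dynamics, spectra — can be validated against closed forms.

Each model lives on a small molecule of real atoms. Its diabatic potential
matrix V depends on internal coordinates (bond-length displacements), so
all derived Cartesian properties transform correctly under rotation and the
downstream networks see ordinary :class:`Geometry` objects. The two-state
2D model has a genuine conical intersection: the adiabatic gap vanishes at
the declared seam point and the raw NAC diverges like the inverse distance
to it, while the smoothed NAC stays bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import units
from .data import Dataset, Geometry, MultiStateSample, StateSpace

__all__ = [
    "DiabaticModel", "SamplingSpec", "DegeneracyError",
    "adiabatize", "adiabatize_batch",
    "make_avoided_crossing_1d", "make_conical_2d", "make_conical_3state",
    "generate_dataset", "sample_initial_conditions",
    "fix_eigenvector_signs",
]


class DegeneracyError(RuntimeError):
    """Raised when classical NACs are requested at an exact degeneracy."""


@dataclass
class WignerMode:
    """A declared harmonic mode of the ground-state well.

    ``pattern`` is the Cartesian displacement per unit of the mode
    coordinate; ``mass`` and ``omega`` set the ground-state widths
    sigma_q^2 = 1/(2 m omega), sigma_p^2 = m omega / 2 (atomic units).
    """

    pattern: np.ndarray   # [n_atoms, 3]
    mass: float           # electron masses
    omega: float          # Hartree / hbar


@dataclass
class DiabaticModel:
    """Few-state diabatic Hamiltonian on pseudo-molecular coordinates."""

    name: str
    n_states: int
    atomic_numbers: np.ndarray
    masses: np.ndarray                     # [n_atoms], electron masses
    reference_positions: np.ndarray        # [n_atoms, 3] ground-well minimum
    internals: Callable                    # positions [B,n,3] -> (q [B,m], J [B,m,n,3])
    potential: Callable                    # q [B,m] -> V [B,S,S]
    potential_gradient: Callable           # q [B,m] -> dV/dq [B,m,S,S]
    dipole_matrix: Callable                # q [B,m] -> d [B,S,S,3]
    geometry_from_internals: Callable      # q [m] -> positions [n,3]
    wigner_modes: list = field(default_factory=list)
    seam_point: Optional[np.ndarray] = None  # internals of the declared CI
    internal_ranges: list = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return int(self.atomic_numbers.shape[0])

    @property
    def state_space(self) -> StateSpace:
        return StateSpace(self.n_states)

    def geometry(self, q) -> Geometry:
        return Geometry(self.atomic_numbers,
                        self.geometry_from_internals(np.asarray(q, float)))


def fix_eigenvector_signs(U: np.ndarray) -> np.ndarray:
    """Sign convention: largest-|component| entry of each eigenvector > 0.

    Ties break toward the lowest index (``argmax`` returns the first
    maximum). Works on batched eigenvector stacks [..., S, S] with
    eigenvectors in columns.
    """
    U = np.array(U, copy=True)
    idx = np.argmax(np.abs(U), axis=-2)                     # [..., S]
    picked = np.take_along_axis(U, idx[..., None, :], axis=-2)[..., 0, :]
    U *= np.where(picked < 0, -1.0, 1.0)[..., None, :]
    return U


def adiabatize_batch(model: DiabaticModel, positions: np.ndarray,
                     singular_gap: float = 1e-10):
    """Exact adiabatic properties at a batch of geometries.

    Returns a dict of arrays: energies [B,S], forces [B,S,n,3],
    smooth_nacs [B,P,n,3], nacs [B,P,n,3] (NaN where the gap is below
    ``singular_gap``), permanent_dipoles [B,S,3], transition_dipoles
    [B,P,3], plus the gap matrix used.

    Energies are eigenvalues of V (ascending); forces follow from the
    Hellmann–Feynman theorem; the coupling between adiabatic states i and j
    is u_i^T (∇V) u_j / (E_j − E_i), whose numerator is exactly the
    smoothed NAC.
    """
    positions = np.asarray(positions, dtype=np.float64)
    squeeze = positions.ndim == 2
    if squeeze:
        positions = positions[None]
    q, jac = model.internals(positions)            # [B,m], [B,m,n,3]
    V = model.potential(q)                         # [B,S,S]
    dVq = model.potential_gradient(q)              # [B,m,S,S]
    energies, U = np.linalg.eigh(V)
    U = fix_eigenvector_signs(U)
    # Cartesian gradient of V: [B,S,S,n,3]
    gradV = np.einsum("bmst,bmnd->bstnd", dVq, jac)
    # transform into the adiabatic basis: A_ij = u_i^T gradV u_j
    A = np.einsum("bsi,bstnd,btj->bijnd", U, gradV, U)
    S = model.n_states
    forces = -A[:, np.arange(S), np.arange(S)]     # [B,S,n,3]
    space = model.state_space
    pairs = space.pairs
    sm = np.stack([A[:, i, j] for i, j in pairs], axis=1)   # [B,P,n,3]
    gaps = np.stack([energies[:, j] - energies[:, i] for i, j in pairs],
                    axis=1)                                  # [B,P]
    with np.errstate(divide="ignore", invalid="ignore"):
        nacs = sm / gaps[:, :, None, None]
    nacs[np.abs(gaps) < singular_gap] = np.nan
    dip = model.dipole_matrix(q)                   # [B,S,S,3]
    dip_ad = np.einsum("bsi,bstd,btj->bijd", U, dip, U)
    perm = dip_ad[:, np.arange(S), np.arange(S)]
    trans = np.stack([dip_ad[:, i, j] for i, j in pairs], axis=1)
    out = {"energies": energies, "forces": forces, "smooth_nacs": sm,
           "nacs": nacs, "permanent_dipoles": perm,
           "transition_dipoles": trans, "gaps": gaps}
    if squeeze:
        out = {k: v[0] for k, v in out.items()}
    return out


def adiabatize(model: DiabaticModel, geometry: Geometry,
               phase: Optional[np.ndarray] = None) -> MultiStateSample:
    """Exact :class:`MultiStateSample` at one geometry.

    ``phase`` optionally applies a per-state sign vector to the coupled
    properties (emulating the arbitrary wavefunction phases of raw
    quantum-chemistry output). Raises :class:`DegeneracyError` at an exact
    degeneracy, where the classical NAC is singular.
    """
    props = adiabatize_batch(model, geometry.positions)
    if np.any(~np.isfinite(props["nacs"])):
        raise DegeneracyError(
            "adiabatic states are degenerate here; the classical NAC is "
            "singular (the smoothed NAC remains finite)")
    nacs, sm, trans = props["nacs"], props["smooth_nacs"], \
        props["transition_dipoles"]
    if phase is not None:
        space = model.state_space
        signs = np.array([phase[i] * phase[j] for i, j in space.pairs])
        nacs = nacs * signs[:, None, None]
        sm = sm * signs[:, None, None]
        trans = trans * signs[:, None]
    return MultiStateSample(
        geometry=geometry, energies=props["energies"],
        forces=props["forces"], nacs=nacs, smooth_nacs=sm,
        permanent_dipoles=props["permanent_dipoles"],
        transition_dipoles=trans,
    ).validate(model.state_space)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _bond_internals(pairs, offsets):
    """Internal coordinates = bond lengths minus reference, batched."""
    pairs = [tuple(p) for p in pairs]
    offsets = np.asarray(offsets, dtype=np.float64)

    def fn(positions):
        B, n, _ = positions.shape
        m = len(pairs)
        q = np.empty((B, m))
        jac = np.zeros((B, m, n, 3))
        for k, (a, b) in enumerate(pairs):
            d = positions[:, a] - positions[:, b]
            r = np.linalg.norm(d, axis=-1)
            q[:, k] = r - offsets[k]
            u = d / r[:, None]
            jac[:, k, a] = u
            jac[:, k, b] = -u
        return q, jac

    return fn


def place_triangle(r_ab, r_ac, r_bc):
    """Positions of three atoms with given side lengths (A at origin,
    B on +x, C in the xy-plane with positive y)."""
    if not (r_ab + r_ac > r_bc and r_ab + r_bc > r_ac and r_ac + r_bc > r_ab):
        raise ValueError(
            f"side lengths ({r_ab:.3f}, {r_ac:.3f}, {r_bc:.3f}) violate "
            f"the triangle inequality")
    cx = (r_ab ** 2 + r_ac ** 2 - r_bc ** 2) / (2 * r_ab)
    cy = np.sqrt(max(r_ac ** 2 - cx ** 2, 0.0))
    return np.array([[0.0, 0.0, 0.0], [r_ab, 0.0, 0.0], [cx, cy, 0.0]])


# ---------------------------------------------------------------------------
# built-in models
# ---------------------------------------------------------------------------

def make_avoided_crossing_1d(a: float = 0.06, x0: float = 0.5,
                             c: float = 0.01, delta: float = 0.01,
                             bond: float = 2.5) -> DiabaticModel:
    """Two shifted harmonic diabats on one bond with a constant coupling.

    V11 = a/2 (x+x0)^2, V22 = a/2 (x−x0)^2 + Δ, V12 = c; in the c → 0
    limit this reduces to two crossing harmonic wells.
    """
    numbers = np.array([1, 9])                        # H-F like pair
    masses = np.array([1.008, 18.998]) * units.AMU
    internals = _bond_internals([(0, 1)], [bond])

    def potential(q):
        x = q[:, 0]
        V = np.empty((q.shape[0], 2, 2))
        V[:, 0, 0] = 0.5 * a * (x + x0) ** 2
        V[:, 1, 1] = 0.5 * a * (x - x0) ** 2 + delta
        V[:, 0, 1] = V[:, 1, 0] = c
        return V

    def gradient(q):
        x = q[:, 0]
        dV = np.zeros((q.shape[0], 1, 2, 2))
        dV[:, 0, 0, 0] = a * (x + x0)
        dV[:, 0, 1, 1] = a * (x - x0)
        return dV

    def dipoles(q):
        x = q[:, 0]
        d = np.zeros((q.shape[0], 2, 2, 3))
        d[:, 0, 0, 0] = 0.5 + 0.1 * x
        d[:, 1, 1, 0] = -0.3
        d[:, 0, 1] = d[:, 1, 0] = np.stack(
            [0.3 + 0 * x, 0.1 + 0 * x, 0 * x], axis=-1)
        return d

    def build(qv):
        pos = np.zeros((2, 3))
        pos[1, 0] = bond + qv[0]
        return pos

    omega = np.sqrt(a / masses[0])
    mode = WignerMode(
        pattern=np.array([[-1.0, 0, 0], [0, 0, 0]]), mass=masses[0],
        omega=omega)
    ref = build(np.array([-x0]))
    return DiabaticModel(
        name="ac1d", n_states=2, atomic_numbers=numbers, masses=masses,
        reference_positions=ref, internals=internals, potential=potential,
        potential_gradient=gradient, dipole_matrix=dipoles,
        geometry_from_internals=build, wigner_modes=[mode],
        seam_point=None, internal_ranges=[(-1.2, 1.2)])


def make_conical_2d(a: float = 0.058, b: float = 0.05, c: float = 0.010,
                    delta: float = 0.012, x0: float = 0.15,
                    k_spectator: float = 0.05,
                    bond: float = 2.5) -> DiabaticModel:
    """Two-state linear-vibronic-coupling model with a conical intersection.

    Internal coordinates on an equilateral three-atom frame (side ``bond``):
    x, y are the A–B and A–C bond displacements (tuning and coupling
    modes), s is the B–C displacement, a harmonic spectator common to both
    diabats. The adiabatic surfaces are degenerate exactly at
    (x*, y, s) = (Δ/(2 a x0), 0, 0), the declared seam point.
    """
    numbers = np.array([1, 6, 8])
    # the mobile atom carries a deuteron-pair-scale mass so that a 0.5 fs
    # nuclear step resolves the avoided-crossing region cleanly
    masses = np.array([4.0, 12.011, 15.999]) * units.AMU
    internals = _bond_internals([(0, 1), (0, 2), (1, 2)],
                                [bond, bond, bond])

    def potential(q):
        x, y, s = q[:, 0], q[:, 1], q[:, 2]
        common = 0.5 * b * y ** 2 + 0.5 * k_spectator * s ** 2
        V = np.empty((q.shape[0], 2, 2))
        V[:, 0, 0] = 0.5 * a * (x + x0) ** 2 + common
        V[:, 1, 1] = 0.5 * a * (x - x0) ** 2 + common + delta
        V[:, 0, 1] = V[:, 1, 0] = c * y
        return V

    def gradient(q):
        x, y, s = q[:, 0], q[:, 1], q[:, 2]
        dV = np.zeros((q.shape[0], 3, 2, 2))
        dV[:, 0, 0, 0] = a * (x + x0)
        dV[:, 0, 1, 1] = a * (x - x0)
        dV[:, 1, 0, 0] = dV[:, 1, 1, 1] = b * y
        dV[:, 1, 0, 1] = dV[:, 1, 1, 0] = c
        dV[:, 2, 0, 0] = dV[:, 2, 1, 1] = k_spectator * s
        return dV

    def dipoles(q):
        x, y, _ = q[:, 0], q[:, 1], q[:, 2]
        z = np.zeros_like(x)
        d = np.zeros((q.shape[0], 2, 2, 3))
        d[:, 0, 0] = np.stack([0.3 + 0.1 * x, 0.1 + 0.05 * y, z], axis=-1)
        d[:, 1, 1] = np.stack([-0.25 - 0.05 * x, 0.15 + z, z], axis=-1)
        d[:, 0, 1] = d[:, 1, 0] = np.stack(
            [0.2 + z, 0.4 + 0.1 * y, 0.1 + z], axis=-1)
        return d

    def build(qv):
        return place_triangle(bond + qv[0], bond + qv[1], bond + qv[2])

    modes = [
        WignerMode(np.array([[-1.0, 0, 0], [0, 0, 0], [0, 0, 0]]),
                   masses[0], np.sqrt(a / masses[0])),
        WignerMode(np.array([[0, -1.0, 0], [0, 0, 0], [0, 0, 0]]),
                   masses[0], np.sqrt(b / masses[0])),
        WignerMode(np.array([[0, 0, 0], [0, 0, 0], [0, 1.0, 0]]),
                   masses[2], np.sqrt(k_spectator / masses[2])),
    ]
    # the ground-state well of the lower diabat sits near x = -x0
    ref = build(np.array([-x0, 0.0, 0.0]))
    seam = np.array([delta / (2 * a * x0), 0.0, 0.0])
    model = DiabaticModel(
        name="ci2d", n_states=2, atomic_numbers=numbers, masses=masses,
        reference_positions=ref, internals=internals, potential=potential,
        potential_gradient=gradient, dipole_matrix=dipoles,
        geometry_from_internals=build, wigner_modes=modes,
        seam_point=seam,
        internal_ranges=[(-0.6, 0.9), (-0.6, 0.6), (-0.45, 0.45)])
    # the y mode pattern moves atom A perpendicular to A-B but the A-C bond
    # at the equilateral reference is at 60 degrees; the declared modes are
    # an idealization of the true normal modes (documented approximation).
    return model


def make_conical_3state(a: float = 0.058, b: float = 0.05, c01: float = 0.010,
                        c12: float = 0.008, delta1: float = 0.012,
                        delta2: float = 0.035, x0: float = 0.15,
                        k_spectator: float = 0.05,
                        bond: float = 2.5) -> DiabaticModel:
    """Three-state extension of the 2D model (adds a higher diabat coupled
    to the second one through the same coupling mode)."""
    base = make_conical_2d(a, b, c01, delta1, x0, k_spectator, bond)

    def potential(q):
        x, y, s = q[:, 0], q[:, 1], q[:, 2]
        common = 0.5 * b * y ** 2 + 0.5 * k_spectator * s ** 2
        V = np.zeros((q.shape[0], 3, 3))
        V[:, 0, 0] = 0.5 * a * (x + x0) ** 2 + common
        V[:, 1, 1] = 0.5 * a * (x - x0) ** 2 + common + delta1
        V[:, 2, 2] = 0.5 * a * x ** 2 + common + delta2
        V[:, 0, 1] = V[:, 1, 0] = c01 * y
        V[:, 1, 2] = V[:, 2, 1] = c12 * y
        return V

    def gradient(q):
        x, y, s = q[:, 0], q[:, 1], q[:, 2]
        dV = np.zeros((q.shape[0], 3, 3, 3))
        dV[:, 0, 0, 0] = a * (x + x0)
        dV[:, 0, 1, 1] = a * (x - x0)
        dV[:, 0, 2, 2] = a * x
        for j in range(3):
            dV[:, 1, j, j] = b * y
            dV[:, 2, j, j] = k_spectator * s
        dV[:, 1, 0, 1] = dV[:, 1, 1, 0] = c01
        dV[:, 1, 1, 2] = dV[:, 1, 2, 1] = c12
        return dV

    def dipoles(q):
        x, y, _ = q[:, 0], q[:, 1], q[:, 2]
        z = np.zeros_like(x)
        d = np.zeros((q.shape[0], 3, 3, 3))
        d[:, 0, 0] = np.stack([0.3 + 0.1 * x, 0.1 + z, z], axis=-1)
        d[:, 1, 1] = np.stack([-0.25 + z, 0.15 + z, z], axis=-1)
        d[:, 2, 2] = np.stack([0.1 + z, -0.2 + z, z], axis=-1)
        d[:, 0, 1] = d[:, 1, 0] = np.stack([0.2 + z, 0.4 + z, 0.1 + z], -1)
        d[:, 0, 2] = d[:, 2, 0] = np.stack([0.15 + z, -0.1 + z, z], -1)
        d[:, 1, 2] = d[:, 2, 1] = np.stack([0.05 + z, 0.25 + z, z], -1)
        return d

    return DiabaticModel(
        name="ci3s", n_states=3, atomic_numbers=base.atomic_numbers,
        masses=base.masses, reference_positions=base.reference_positions,
        internals=base.internals, potential=potential,
        potential_gradient=gradient, dipole_matrix=dipoles,
        geometry_from_internals=base.geometry_from_internals,
        wigner_modes=base.wigner_modes, seam_point=base.seam_point,
        internal_ranges=base.internal_ranges)


MODEL_BUILDERS = {
    "ac1d": make_avoided_crossing_1d,
    "ci2d": make_conical_2d,
    "ci3s": make_conical_3state,
}


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@dataclass
class SamplingSpec:
    scheme: str = "uniform_box"     # grid | harmonic_wigner | uniform_box
    n_samples: int = 1000
    seed: int = 0
    phase_corruption: float = 0.0   # probability of a random phase vector
    ranges: Optional[list] = None   # per-internal (lo, hi); model default
    grid_shape: Optional[tuple] = None

    def __post_init__(self):
        if not 0.0 <= self.phase_corruption <= 1.0:
            raise ValueError("phase_corruption must be a probability")
        if self.scheme not in ("grid", "harmonic_wigner", "uniform_box"):
            raise ValueError(f"unknown sampling scheme {self.scheme!r}")


def _internal_samples(model: DiabaticModel, spec: SamplingSpec,
                      rng) -> np.ndarray:
    m = len(model.internal_ranges)
    ranges = spec.ranges or model.internal_ranges
    if spec.scheme == "uniform_box":
        lo = np.array([r[0] for r in ranges])
        hi = np.array([r[1] for r in ranges])
        return rng.uniform(lo, hi, size=(spec.n_samples, m))
    if spec.scheme == "grid":
        shape = spec.grid_shape or (
            int(np.ceil(spec.n_samples ** (1 / min(m, 2)))),) * min(m, 2)
        axes = [np.linspace(*ranges[k], shape[k]) for k in range(len(shape))]
        mesh = np.meshgrid(*axes, indexing="ij")
        q = np.zeros((mesh[0].size, m))
        for k, g in enumerate(mesh):
            q[:, k] = g.ravel()
        return q
    # harmonic_wigner: displace the reference along the declared modes
    qs = np.zeros((spec.n_samples, m))
    positions = np.repeat(model.reference_positions[None], spec.n_samples, 0)
    for mode in model.wigner_modes:
        sigma_q = np.sqrt(1.0 / (2.0 * mode.mass * mode.omega))
        amp = rng.normal(0.0, sigma_q, size=spec.n_samples)
        positions += amp[:, None, None] * mode.pattern[None]
    q, _ = model.internals(positions)
    return q


def generate_dataset(model: DiabaticModel, spec: SamplingSpec) -> Dataset:
    """Exact-oracle dataset; deterministic per seed.

    With probability ``phase_corruption`` per sample, a random phase vector
    (p_0 = +1, other signs uniform) multiplies that sample's NACs, smoothed
    NACs and transition dipoles jointly — emulating the arbitrary
    wavefunction phases of raw quantum-chemistry output. Points falling
    within 1e-8 Hartree of a state degeneracy are resampled/skipped.
    """
    rng = np.random.default_rng(spec.seed)
    q = _internal_samples(model, spec, rng)
    samples = []
    space = model.state_space
    for qv in q:
        geo = model.geometry(qv)
        phase = None
        if spec.phase_corruption > 0 and rng.random() < spec.phase_corruption:
            phase = np.concatenate(
                [[1.0], rng.choice([-1.0, 1.0], size=model.n_states - 1)])
        try:
            samples.append(adiabatize(model, geo, phase=phase))
        except DegeneracyError:
            continue
    return Dataset(samples, space, {"all": "au"},
                   provenance=f"synthetic:{model.name}:{spec.scheme}:"
                              f"seed={spec.seed}")


def sample_initial_conditions(model: DiabaticModel, n: int, seed: int):
    """Harmonic Wigner sample of the declared ground-state well.

    Positions and momenta of each declared mode are drawn from the quantum
    harmonic ground state (sigma_q^2 = 1/(2 m omega), sigma_p^2 =
    m omega / 2). Returns (positions [n, n_atoms, 3], velocities
    [n, n_atoms, 3]) in atomic units.
    """
    rng = np.random.default_rng(seed)
    positions = np.repeat(model.reference_positions[None], n, axis=0)
    velocities = np.zeros_like(positions)
    for mode in model.wigner_modes:
        sigma_q = np.sqrt(1.0 / (2.0 * mode.mass * mode.omega))
        sigma_p = np.sqrt(mode.mass * mode.omega / 2.0)
        qamp = rng.normal(0.0, sigma_q, size=n)
        pamp = rng.normal(0.0, sigma_p, size=n)
        positions += qamp[:, None, None] * mode.pattern[None]
        velocities += (pamp / mode.mass)[:, None, None] * mode.pattern[None]
    return positions, velocities
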