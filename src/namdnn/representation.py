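"""Atomistic feature builders.

Two continuous-filter message-passing representations are provided:

* ``invariant`` — per-atom scalar features built from interatomic distances
  only (SchNet-style continuous-filter convolutions); scalars are invariant
  under rotations, translations and reflections.
* ``equivariant`` — per-atom scalar *and* vector features (paiNN-style);
  the vector channels transform as Cartesian vectors under rotation, which
  lets property heads emit vectorial observables directly.

Both operate on a :class:`Batch` of molecules so that training and ensemble
prediction run through a single vectorized graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .data import Geometry

__all__ = [
    "RepresentationConfig", "AtomFeatures", "NeighborList", "Batch",
    "build_neighborhood", "radial_basis", "collate",
    "init_representation_params", "encode", "forward_representation",
]


@dataclass
class RepresentationConfig:
    kind: str = "equivariant"          # "invariant" | "equivariant"
    n_features: int = 32
    n_interactions: int = 3
    cutoff: float = 10.0               # Bohr
    n_radial_basis: int = 20
    seed: int = 0
    max_z: int = 20                    # size of the element embedding table

    def __post_init__(self):
        if self.kind not in ("invariant", "equivariant"):
            raise ValueError(f"unknown representation kind {self.kind!r}")
        if self.n_features <= 0 or self.n_interactions < 1 or self.cutoff <= 0:
            raise ValueError("invalid representation configuration")


@dataclass
class AtomFeatures:
    """Per-atom scalar (invariant) and optional vector (equivariant) features."""

    scalars: ad.Tensor                 # [N, F]
    vectors: Optional[ad.Tensor]       # [N, 3, F] or None


@dataclass
class NeighborList:
    i: np.ndarray                      # source atom of each ordered pair
    j: np.ndarray                      # neighbor atom
    displacements: np.ndarray          # r_j - r_i, [E, 3]
    distances: np.ndarray              # [E]


def build_neighborhood(geometry: Geometry, cutoff: float) -> NeighborList:
    """All ordered pairs (a, b), a != b, with |r_b - r_a| <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = geometry.positions
    n = geometry.n_atoms
    diff = pos[None, :, :] - pos[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    mask = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    i, j = np.nonzero(mask)
    return NeighborList(i, j, diff[i, j], dist[i, j])


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    """Several molecules packed into flat per-atom / per-edge arrays."""

    atomic_numbers: np.ndarray         # [N]
    positions: ad.Tensor               # [N, 3], differentiable leaf
    mol_id: np.ndarray                 # [N]
    n_mol: int
    edge_i: np.ndarray                 # [E]
    edge_j: np.ndarray                 # [E]
    atom_counts: np.ndarray            # [n_mol]
    total_charges: np.ndarray          # [n_mol]

    @property
    def n_atoms(self) -> int:
        return int(self.atomic_numbers.shape[0])

    def atom_slices(self):
        offsets = np.concatenate([[0], np.cumsum(self.atom_counts)])
        return [slice(int(offsets[k]), int(offsets[k + 1]))
                for k in range(self.n_mol)]


def collate(geometries: Sequence[Geometry], cutoff: float) -> Batch:
    numbers, mol_id, edges_i, edges_j = [], [], [], []
    charges, counts, positions = [], [], []
    offset = 0
    for m, geo in enumerate(geometries):
        nl = build_neighborhood(geo, cutoff)
        numbers.append(geo.atomic_numbers)
        positions.append(geo.positions)
        mol_id.append(np.full(geo.n_atoms, m))
        edges_i.append(nl.i + offset)
        edges_j.append(nl.j + offset)
        charges.append(geo.total_charge)
        counts.append(geo.n_atoms)
        offset += geo.n_atoms
    return Batch(
        atomic_numbers=np.concatenate(numbers),
        positions=ad.parameter(np.concatenate(positions, axis=0)),
        mol_id=np.concatenate(mol_id),
        n_mol=len(geometries),
        edge_i=np.concatenate(edges_i) if edges_i else np.zeros(0, np.intp),
        edge_j=np.concatenate(edges_j) if edges_j else np.zeros(0, np.intp),
        atom_counts=np.array(counts),
        total_charges=np.array(charges),
    )


# ---------------------------------------------------------------------------
# radial basis
# ---------------------------------------------------------------------------

def _rbf_tensors(dist: ad.Tensor, config: RepresentationConfig):
    """Gaussian radial basis times a cosine cutoff envelope, on the tape.

    Returns (basis [E, n_rb], envelope [E, 1]); both vanish identically at
    and beyond the cutoff (edges are only built inside it).
    """
    nb = config.n_radial_basis
    centers = np.linspace(0.0, config.cutoff, nb)
    width = config.cutoff / max(nb - 1, 1)
    d = ad.reshape(dist, (dist.shape[0], 1))
    z = (d - ad.tensor(centers[None, :])) * (1.0 / width)
    basis = ad.exp(ad.mul(-0.5, ad.square(z)))
    env = ad.mul(0.5, ad.cos(d * (np.pi / config.cutoff)) + 1.0)
    return ad.mul(basis, env), env


def radial_basis(distances, config: RepresentationConfig) -> np.ndarray:
    """Envelope-damped Gaussian radial basis values for given distances."""
    distances = np.atleast_1d(np.asarray(distances, dtype=np.float64))
    with ad.no_grad():
        basis, _ = _rbf_tensors(ad.tensor(distances), config)
    out = basis.value
    out[distances >= config.cutoff] = 0.0
    return out


def cutoff_envelope(distances, config: RepresentationConfig) -> np.ndarray:
    distances = np.asarray(distances, dtype=np.float64)
    env = 0.5 * (np.cos(np.pi * distances / config.cutoff) + 1.0)
    return np.where(distances < config.cutoff, env, 0.0)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _dense_init(rng, n_in, n_out, params, name):
    params[name + ".W"] = ad.parameter(
        rng.normal(size=(n_in, n_out)) / np.sqrt(n_in))
    params[name + ".b"] = ad.parameter(np.zeros(n_out))


def dense(params: dict, name: str, x: ad.Tensor) -> ad.Tensor:
    return ad.matmul(x, params[name + ".W"]) + params[name + ".b"]


def init_representation_params(config: RepresentationConfig,
                               rng=None) -> dict:
    """Seeded parameter initialization for either representation kind."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    F, nb = config.n_features, config.n_radial_basis
    params: dict = {
        "embedding": ad.parameter(rng.normal(size=(config.max_z + 1, F))),
    }
    for t in range(config.n_interactions):
        p = f"int{t}"
        if config.kind == "invariant":
            _dense_init(rng, nb, F, params, f"{p}.filter1")
            _dense_init(rng, F, F, params, f"{p}.filter2")
            _dense_init(rng, F, F, params, f"{p}.in2f")
            _dense_init(rng, F, F, params, f"{p}.out1")
            _dense_init(rng, F, F, params, f"{p}.out2")
        else:
            _dense_init(rng, F, F, params, f"{p}.msg1")
            _dense_init(rng, F, 3 * F, params, f"{p}.msg2")
            _dense_init(rng, nb, 3 * F, params, f"{p}.filter")
            params[f"{p}.U"] = ad.parameter(
                rng.normal(size=(F, F)) / np.sqrt(F))
            params[f"{p}.V"] = ad.parameter(
                rng.normal(size=(F, F)) / np.sqrt(F))
            _dense_init(rng, 2 * F, F, params, f"{p}.upd1")
            _dense_init(rng, F, 3 * F, params, f"{p}.upd2")
    return params


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _edge_geometry(batch: Batch):
    ri = ad.gather(batch.positions, batch.edge_i)
    rj = ad.gather(batch.positions, batch.edge_j)
    disp = rj - ri
    dist = ad.norm(disp, axis=1)
    unit = disp / ad.reshape(dist, (dist.shape[0], 1))
    return disp, dist, unit


def _invariant_forward(batch: Batch, config, params) -> AtomFeatures:
    F = config.n_features
    N = batch.n_atoms
    z_idx = np.clip(batch.atomic_numbers, 0, config.max_z)
    x = ad.gather(params["embedding"], z_idx)
    if batch.edge_i.size:
        _, dist, _ = _edge_geometry(batch)
        rbf, _ = _rbf_tensors(dist, config)
    for t in range(config.n_interactions):
        p = f"int{t}"
        if not batch.edge_i.size:
            break
        w = dense(params, f"{p}.filter2",
                  ad.ssp(dense(params, f"{p}.filter1", rbf)))
        xj = ad.gather(dense(params, f"{p}.in2f", x), batch.edge_j)
        agg = ad.segment_sum(ad.mul(xj, w), batch.edge_i, N)
        x = x + dense(params, f"{p}.out2",
                      ad.ssp(dense(params, f"{p}.out1", agg)))
    return AtomFeatures(scalars=x, vectors=None)


def _equivariant_forward(batch: Batch, config, params) -> AtomFeatures:
    F = config.n_features
    N = batch.n_atoms
    z_idx = np.clip(batch.atomic_numbers, 0, config.max_z)
    s = ad.gather(params["embedding"], z_idx)
    v = ad.tensor(np.zeros((N, 3, F)))
    has_edges = bool(batch.edge_i.size)
    if has_edges:
        _, dist, unit = _edge_geometry(batch)
        rbf, _ = _rbf_tensors(dist, config)
        E = batch.edge_i.shape[0]
    for t in range(config.n_interactions):
        p = f"int{t}"
        if has_edges:
            # message block
            phi = dense(params, f"{p}.msg2",
                        ad.ssp(dense(params, f"{p}.msg1", s)))
            prod = ad.mul(ad.gather(phi, batch.edge_j),
                          dense(params, f"{p}.filter", rbf))
            ds = prod[:, :F]
            dvv = ad.reshape(prod[:, F:2 * F], (E, 1, F))
            dvs = ad.reshape(prod[:, 2 * F:], (E, 1, F))
            vj = ad.gather(v, batch.edge_j)
            dv = ad.mul(vj, dvv) + ad.mul(
                ad.reshape(unit, (E, 3, 1)), dvs)
            s = s + ad.segment_sum(ds, batch.edge_i, N)
            v = v + ad.segment_sum(dv, batch.edge_i, N)
        # update block (purely per-atom, runs even for isolated atoms)
        vu = ad.matmul(v, params[f"{p}.U"])
        vv = ad.matmul(v, params[f"{p}.V"])
        vv_norm = ad.sqrt(ad.tsum(ad.square(vv), axis=1) + 1e-12)
        a = dense(params, f"{p}.upd2",
                  ad.ssp(dense(params, f"{p}.upd1",
                               ad.concatenate([s, vv_norm], axis=1))))
        a_ss = a[:, :F]
        a_sv = a[:, F:2 * F]
        a_vv = ad.reshape(a[:, 2 * F:], (N, 1, F))
        dot = ad.tsum(ad.mul(vu, vv), axis=1)
        s = s + a_ss + ad.mul(a_sv, dot)
        v = v + ad.mul(a_vv, vu)
    return AtomFeatures(scalars=s, vectors=v)


def forward_representation(batch: Batch, config: RepresentationConfig,
                           params: dict) -> AtomFeatures:
    if config.kind == "invariant":
        return _invariant_forward(batch, config, params)
    return _equivariant_forward(batch, config, params)


def encode(geometry: Geometry, config: RepresentationConfig,
           params: dict) -> AtomFeatures:
    """Atom features for a single geometry (see :class:`AtomFeatures`)."""
    batch = collate([geometry], config.cutoff)
    return forward_representation(batch, config, params)
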