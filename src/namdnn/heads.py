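"""Property heads and the multi-state model.

Maps atom features to observables of S electronic states:

* energies — per-state sums of atomwise contributions (invariant),
* forces — exact negative gradients of the predicted energies,
* smoothed NAC vectors ``C̃_ij`` — either gated combinations of equivariant
  vector features (one 3-vector per atom per state pair), or gradients of a
  per-pair invariant "virtual" scalar (the only option for the invariant
  representation),
* dipoles — latent atomic charges times positions relative to the geometric
  centroid; transition charges are re-centred to zero net charge (making
  transition dipoles rigorously translation invariant), permanent charges to
  the total molecular charge.

The smoothed couplings are the trained quantity; classical NACs are derived
at prediction time by dividing out the (floored) energy gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .data import (Geometry, StateSpace, GAP_FLOOR_DEFAULT, unsmooth_nacs)
from .representation import (RepresentationConfig, Batch, collate, dense,
                             forward_representation,
                             init_representation_params, _dense_init)

__all__ = [
    "HeadConfig", "ModelConfig", "Prediction", "ExcitedStateModel",
    "CapabilityError", "ConfigurationError",
    "predict_all", "to_classical_nacs",
]


class ConfigurationError(ValueError):
    pass


class CapabilityError(RuntimeError):
    """A property was requested that the model was not trained for."""


@dataclass
class HeadConfig:
    energies: bool = True
    forces: bool = True
    nacs: bool = True
    dipoles: bool = False
    nac_mode: str = "equivariant_direct"   # or "virtual_derivative"
    n_hidden: int = 32

    def __post_init__(self):
        if self.forces and not self.energies:
            raise ConfigurationError("force head requires the energy head")
        if self.nac_mode not in ("equivariant_direct", "virtual_derivative"):
            raise ConfigurationError(f"unknown nac_mode {self.nac_mode!r}")

    @property
    def active(self) -> tuple:
        return tuple(k for k in ("energies", "forces", "nacs", "dipoles")
                     if getattr(self, k))


@dataclass
class ModelConfig:
    n_states: int
    representation: RepresentationConfig = field(
        default_factory=RepresentationConfig)
    heads: HeadConfig = field(default_factory=HeadConfig)
    gap_floor: float = GAP_FLOOR_DEFAULT

    def __post_init__(self):
        if (self.heads.nacs and self.heads.nac_mode == "equivariant_direct"
                and self.representation.kind == "invariant"):
            raise ConfigurationError(
                "equivariant_direct NAC head requires the equivariant "
                "representation; use nac_mode='virtual_derivative'")

    @property
    def state_space(self) -> StateSpace:
        return StateSpace(self.n_states)


@dataclass
class Prediction:
    """Per-molecule predicted property blocks (atomic units)."""

    energies: Optional[np.ndarray] = None            # [S]
    forces: Optional[np.ndarray] = None              # [S, n, 3]
    smooth_nacs: Optional[np.ndarray] = None         # [P, n, 3]
    nacs: Optional[np.ndarray] = None                # [P, n, 3]
    permanent_dipoles: Optional[np.ndarray] = None   # [S, 3]
    transition_dipoles: Optional[np.ndarray] = None  # [P, 3]
    state_charges: Optional[np.ndarray] = None       # [S, n]
    transition_charges: Optional[np.ndarray] = None  # [P, n]


def _mlp_init(rng, n_in, n_hidden, n_out, params, name, zero_out=True):
    _dense_init(rng, n_in, n_hidden, params, name + ".h")
    _dense_init(rng, n_hidden, n_out, params, name + ".o")
    if zero_out:
        # heads start at the reference offsets: stabilizes early training
        params[name + ".o.W"].value[:] = 0.0


def _mlp(params, name, x):
    return dense(params, name + ".o", ad.ssp(dense(params, name + ".h", x)))


class ExcitedStateModel:
    """Multi-state neural network potential with selectable heads."""

    def __init__(self, config: ModelConfig, params: dict,
                 energy_offsets: Optional[np.ndarray] = None):
        self.config = config
        self.params = params
        s = config.n_states
        self.energy_offsets = (np.zeros(s) if energy_offsets is None
                               else np.asarray(energy_offsets, float))

    # -- construction ------------------------------------------------------
    @classmethod
    def create(cls, config: ModelConfig, seed: Optional[int] = None,
               head_init: str = "zero") -> "ExcitedStateModel":
        """``head_init='zero'`` starts every head at its reference offset;
        ``'random'`` gives non-trivial outputs from the start."""
        rng = np.random.default_rng(
            config.representation.seed if seed is None else seed)
        params = init_representation_params(config.representation, rng)
        F = config.representation.n_features
        H = config.heads.n_hidden
        s, p = config.n_states, config.state_space.n_pairs
        zero = head_init == "zero"
        if config.heads.energies:
            _mlp_init(rng, F, H, s, params, "energy", zero)
        if config.heads.nacs:
            if config.heads.nac_mode == "equivariant_direct":
                _mlp_init(rng, F, H, F * p, params, "nac_gate", zero)
            else:
                _mlp_init(rng, F, H, p, params, "nac_virtual", zero)
        if config.heads.dipoles:
            _mlp_init(rng, F, H, s + p, params, "charges", zero)
        return cls(config, params)

    @property
    def state_space(self) -> StateSpace:
        return self.config.state_space

    def parameters(self):
        return self.params

    def set_requires(self, flag: bool):
        for t in self.params.values():
            t.requires = flag

    # -- forward -----------------------------------------------------------
    def forward(self, batch: Batch, properties: Optional[Sequence[str]] = None,
                create_graph: bool = False) -> dict:
        """One batched forward pass serving all requested heads.

        Returns a dict of tape tensors:
        ``energies`` [B,S], ``forces`` [S,N,3], ``smooth_nacs`` [P,N,3],
        ``permanent_dipoles`` [B,S,3], ``transition_dipoles`` [B,P,3],
        plus latent charges when the dipole head is active.
        """
        cfg = self.config
        heads = cfg.heads
        if properties is None:
            properties = heads.active
        head_of = {"energies": "energies", "forces": "forces",
                   "nacs": "nacs", "smooth_nacs": "nacs",
                   "dipoles": "dipoles", "permanent_dipoles": "dipoles",
                   "transition_dipoles": "dipoles"}
        missing = [p for p in properties if not getattr(heads, head_of[p])]
        if missing:
            raise CapabilityError(
                f"model has no head(s) for {missing}; trained heads: "
                f"{list(heads.active)}")
        feats = forward_representation(batch, cfg.representation, self.params)
        s_feat, v_feat = feats.scalars, feats.vectors
        N = batch.n_atoms
        S, P = cfg.n_states, cfg.state_space.n_pairs
        out: dict = {}

        need_forces = "forces" in properties
        need_energy = "energies" in properties or need_forces
        if need_energy:
            atom_e = _mlp(self.params, "energy", s_feat)          # [N,S]
            e_res = ad.segment_sum(atom_e, batch.mol_id, batch.n_mol)
            out["energies"] = e_res + ad.tensor(self.energy_offsets[None, :])
        if need_forces:
            cols = []
            for j in range(S):
                ej = ad.tsum(out["energies"][:, j])
                (g,) = ad.grad(ej, [batch.positions],
                               create_graph=create_graph)
                cols.append(ad.neg(g))
            out["forces"] = ad.stack(cols, axis=0)                # [S,N,3]

        if "nacs" in properties or "smooth_nacs" in properties:
            if heads.nac_mode == "equivariant_direct":
                F = cfg.representation.n_features
                gate = ad.reshape(_mlp(self.params, "nac_gate", s_feat),
                                  (N, F, P))
                nac = ad.matmul(v_feat, gate)                     # [N,3,P]
                out["smooth_nacs"] = ad.transpose(nac, (2, 0, 1))
            else:
                virt = _mlp(self.params, "nac_virtual", s_feat)   # [N,P]
                vmol = ad.segment_sum(virt, batch.mol_id, batch.n_mol)
                rows = []
                for q in range(P):
                    vq = ad.tsum(vmol[:, q])
                    (g,) = ad.grad(vq, [batch.positions],
                                   create_graph=create_graph)
                    rows.append(g)
                out["smooth_nacs"] = ad.stack(rows, axis=0)       # [P,N,3]

        if "dipoles" in properties or "permanent_dipoles" in properties \
                or "transition_dipoles" in properties:
            q_all = _mlp(self.params, "charges", s_feat)          # [N,S+P]
            counts = batch.atom_counts.astype(float)
            inv_counts = ad.tensor((1.0 / counts)[:, None])
            q_mean = ad.mul(
                ad.segment_sum(q_all, batch.mol_id, batch.n_mol), inv_counts)
            corr = ad.gather(q_mean, batch.mol_id)
            q_centered = q_all - corr                             # zero-sum
            # permanent charges must sum to the total molecular charge
            q_target = (batch.total_charges / counts)[:, None]    # [B,1]
            shift = ad.gather(ad.tensor(np.repeat(q_target, S, axis=1)),
                              batch.mol_id)
            q_perm = q_centered[:, :S] + shift                    # [N,S]
            q_trans = q_centered[:, S:]                           # [N,P]
            centroid = ad.mul(
                ad.segment_sum(batch.positions, batch.mol_id, batch.n_mol),
                inv_counts)
            rel = batch.positions - ad.gather(centroid, batch.mol_id)
            out["permanent_dipoles"] = _charge_dipole(
                q_perm, rel, batch, S)                            # [B,S,3]
            out["transition_dipoles"] = _charge_dipole(
                q_trans, rel, batch, P)                           # [B,P,3]
            out["state_charges"] = q_perm
            out["transition_charges"] = q_trans
        return out

    # -- prediction ----------------------------------------------------------
    def predict(self, geometries, properties: Optional[Sequence[str]] = None,
                classical_nacs: bool = False):
        """Predict properties for one geometry or a list of geometries."""
        single = isinstance(geometries, Geometry)
        geos = [geometries] if single else list(geometries)
        batch = collate(geos, self.config.representation.cutoff)
        self.set_requires(False)
        try:
            out = self.forward(batch, properties)
        finally:
            self.set_requires(True)
        preds = self._split(out, batch)
        if classical_nacs:
            for pr in preds:
                to_classical_nacs(pr, self.state_space, self.config.gap_floor)
        return preds[0] if single else preds

    def _split(self, out: dict, batch: Batch) -> list:
        preds = []
        for m, sl in enumerate(batch.atom_slices()):
            pr = Prediction()
            if "energies" in out:
                pr.energies = out["energies"].value[m].copy()
            if "forces" in out:
                pr.forces = out["forces"].value[:, sl, :].copy()
            if "smooth_nacs" in out:
                pr.smooth_nacs = out["smooth_nacs"].value[:, sl, :].copy()
            if "permanent_dipoles" in out:
                pr.permanent_dipoles = out["permanent_dipoles"].value[m].copy()
                pr.transition_dipoles = out["transition_dipoles"].value[m].copy()
                pr.state_charges = out["state_charges"].value[sl].T.copy()
                pr.transition_charges = out["transition_charges"].value[sl].T.copy()
            preds.append(pr)
        return preds

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        cfg = {
            "n_states": self.config.n_states,
            "gap_floor": self.config.gap_floor,
            "representation": asdict(self.config.representation),
            "heads": asdict(self.config.heads),
            "units": "atomic",
            "schema_version": 1,
        }
        arrays = {f"param::{k}": v.value for k, v in self.params.items()}
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8),
            __offsets__=self.energy_offsets, **arrays)

    @classmethod
    def load(cls, path) -> "ExcitedStateModel":
        with np.load(path) as zf:
            cfg = json.loads(bytes(zf["__config__"].tobytes()).decode())
            if cfg.get("schema_version") != 1:
                raise ConfigurationError("unsupported checkpoint schema")
            config = ModelConfig(
                n_states=cfg["n_states"], gap_floor=cfg["gap_floor"],
                representation=RepresentationConfig(**cfg["representation"]),
                heads=HeadConfig(**cfg["heads"]))
            params = {k[len("param::"):]: ad.parameter(zf[k])
                      for k in zf.files if k.startswith("param::")}
            offsets = zf["__offsets__"]
        return cls(config, params, offsets)


def _charge_dipole(q: ad.Tensor, rel: ad.Tensor, batch: Batch,
                   n_channels: int) -> ad.Tensor:
    """mu[b, c, :] = sum_a q[a, c] * (R_a - centroid_b)."""
    N = q.shape[0]
    qr = ad.mul(ad.reshape(q, (N, n_channels, 1)),
                ad.reshape(rel, (N, 1, 3)))
    return ad.segment_sum(qr, batch.mol_id, batch.n_mol)


# ---------------------------------------------------------------------------
# convenience operations
# ---------------------------------------------------------------------------

def predict_all(geometry: Geometry, model: ExcitedStateModel) -> Prediction:
    """All trained properties for one geometry, from a single forward pass."""
    return model.predict(geometry)


def to_classical_nacs(prediction: Prediction, space: StateSpace,
                      gap_floor: float = GAP_FLOOR_DEFAULT) -> np.ndarray:
    """Derive classical NACs from predicted smoothed NACs and energies."""
    if prediction.smooth_nacs is None or prediction.energies is None:
        raise CapabilityError(
            "classical NACs require predicted smooth_nacs and energies")
    prediction.nacs = unsmooth_nacs(prediction.smooth_nacs,
                                    prediction.energies, space, gap_floor)
    return prediction.nacs
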