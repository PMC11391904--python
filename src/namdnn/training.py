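"""Loss functions (including phase-free variants) and the training loop.

Quantum-chemistry reference data carries an arbitrary per-state sign: each
electronic wavefunction is defined only up to a global phase p_j ∈ {−1, +1},
so every pair property (NAC vector, transition dipole) of pair (i, j) may
appear multiplied by p_i·p_j. Two phase-free losses handle this:

* ``pairwise`` — minimizes over an independent ±1 sign per state pair
  (fast; relaxes the constraint that signs originate from per-state phases),
* ``phase_vector`` — minimizes over all 2^(S−1) consistent phase vectors.

NAC and transition dipole of the same pair always share one sign. The
minimizing sign is held constant during differentiation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .data import Dataset, StateSpace, fit_energy_reference
from .heads import ExcitedStateModel
from .representation import collate

__all__ = [
    "LossWeights", "TrainConfig", "TrainingHistory",
    "property_loss", "pairwise_phase_loss", "phase_vector_loss",
    "combined_loss", "train", "evaluate",
    "phase_vectors", "pair_signs", "best_phase_alignment",
]

PHASE_MODES = ("none", "pairwise", "phase_vector")


@dataclass
class LossWeights:
    """Trade-off weights t_P of the combined loss, one per property.

    ``None`` marks a weight as undefined; using a head whose weight is
    undefined is an error.
    """

    energies: Optional[float] = 1.0
    forces: Optional[float] = 1.0
    nacs: Optional[float] = 1.0
    dipoles: Optional[float] = 1.0

    def __post_init__(self):
        vals = [v for v in (self.energies, self.forces, self.nacs,
                            self.dipoles) if v is not None]
        if any(v < 0 for v in vals) or not any(v > 0 for v in vals):
            raise ValueError("weights must be >= 0 with at least one positive")

    def require(self, prop: str) -> float:
        v = getattr(self, prop)
        if v is None:
            raise ValueError(f"property {prop!r} is active but its loss "
                             f"weight is undefined")
        return v


@dataclass
class TrainConfig:
    epochs: int = 1000
    patience: int = 300          # epochs of non-improving validation loss
    lr: float = 1e-3
    batch_size: int = 128
    seed: int = 0
    phase_mode: str = "phase_vector"
    weights: LossWeights = field(default_factory=LossWeights)
    atomistic: bool = False      # per-atom normalization inside phase losses
    lr_decay: float = 0.7        # multiplicative plateau decay (1 = off)
    lr_patience: int = 60
    min_lr: float = 1e-5

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.phase_mode not in PHASE_MODES:
            raise ValueError(f"phase_mode must be one of {PHASE_MODES}")


# ---------------------------------------------------------------------------
# phase machinery
# ---------------------------------------------------------------------------

def phase_vectors(n_states: int) -> np.ndarray:
    """All 2^(S-1) per-state sign vectors with p_0 = +1, shape [K, S]."""
    if n_states > 12:
        raise ValueError(
            "phase-vector enumeration is exponential in the state count; "
            "use the pairwise phase loss for S > 12")
    tails = itertools.product((1.0, -1.0), repeat=n_states - 1)
    return np.array([(1.0,) + t for t in tails])


def pair_signs(p: np.ndarray, space: StateSpace) -> np.ndarray:
    """Sign p_i * p_j for every ordered pair, shape [..., n_pairs]."""
    p = np.asarray(p, dtype=np.float64)
    return np.stack([p[..., i] * p[..., j] for i, j in space.pairs], axis=-1)


def _as_group(pred, ref) -> tuple:
    """Normalize (pred, ref) into aligned dicts of pair-first arrays."""
    if not isinstance(pred, Mapping):
        pred, ref = {"prop": pred}, {"prop": ref}
    out_p, out_r = {}, {}
    for key in pred:
        a = pred[key].value if isinstance(pred[key], ad.Tensor) else pred[key]
        b = np.asarray(ref[key], dtype=np.float64)
        a = np.asarray(a, dtype=np.float64)
        if a.shape != b.shape:
            raise ValueError(
                f"{key}: prediction shape {a.shape} != reference {b.shape}")
        out_p[key], out_r[key] = a, b
    return out_p, out_r


def _pair_sq_errors(pred: Mapping, ref: Mapping, sign: int,
                    weights: Optional[Mapping] = None) -> np.ndarray:
    """Squared errors summed over everything but the pair axis (axis 0)."""
    total = None
    for key, a in pred.items():
        w = 1.0 if weights is None else weights.get(key, 1.0)
        d = sign * a - ref[key]
        se = w * np.sum(d * d, axis=tuple(range(1, d.ndim)))
        total = se if total is None else total + se
    return total


def _component_count(group: Mapping) -> int:
    return int(sum(np.asarray(v).size for v in group.values()))


def property_loss(pred, ref) -> float:
    """Plain mean squared error over all components."""
    p, r = _as_group(pred, ref)
    num = sum(float(np.sum((p[k] - r[k]) ** 2)) for k in p)
    return num / _component_count(p)


def pairwise_phase_loss(pred, ref) -> float:
    """MSE with an independent optimal ±1 sign per state pair.

    ``pred``/``ref`` are pair-first arrays ([P, ...]) or dicts of such
    arrays for coupled properties sharing the per-pair sign.
    """
    p, r = _as_group(pred, ref)
    plus = _pair_sq_errors(p, r, +1)
    minus = _pair_sq_errors(p, r, -1)
    return float(np.sum(np.minimum(plus, minus))) / _component_count(p)


def phase_vector_loss(pred, ref, space: StateSpace) -> float:
    """MSE minimized over all consistent phase vectors p ∈ {±1}^S, p_0=+1."""
    p, r = _as_group(pred, ref)
    plus = _pair_sq_errors(p, r, +1)    # [P]
    minus = _pair_sq_errors(p, r, -1)
    signs = pair_signs(phase_vectors(space.n_states), space)   # [K, P]
    totals = np.where(signs > 0, plus[None, :], minus[None, :]).sum(axis=1)
    return float(totals.min()) / _component_count(p)


def best_phase_alignment(pred: Mapping, ref: Mapping, space: StateSpace,
                         mode: str = "phase_vector",
                         weights: Optional[Mapping] = None) -> np.ndarray:
    """Optimal per-pair signs to apply to the reference, shape [P]."""
    p, r = _as_group(pred, ref)
    plus = _pair_sq_errors(p, r, +1, weights)
    minus = _pair_sq_errors(p, r, -1, weights)
    if mode == "pairwise":
        return np.where(plus <= minus, 1.0, -1.0)
    signs = pair_signs(phase_vectors(space.n_states), space)
    totals = np.where(signs > 0, plus[None, :], minus[None, :]).sum(axis=1)
    return signs[int(np.argmin(totals))]


# ---------------------------------------------------------------------------
# combined loss on tape tensors
# ---------------------------------------------------------------------------

def _mse_tensor(pred: ad.Tensor, ref: np.ndarray) -> ad.Tensor:
    diff = ad.sub(pred, ad.tensor(ref))
    return ad.tmean(ad.square(diff))


def combined_loss(outputs: Mapping, refs: Mapping, weights: LossWeights,
                  phase_mode: str, space: StateSpace,
                  batch=None, atomistic: bool = False) -> ad.Tensor:
    """Weighted sum Σ_P t_P L_P with phase-free coupled-property terms.

    ``outputs`` are tape tensors from :meth:`ExcitedStateModel.forward`;
    ``refs`` are matching numpy arrays. Coupled properties (smoothed NACs
    and transition dipoles) are compared against sign-aligned references;
    the optimal signs are chosen per molecule and held constant under
    differentiation.
    """
    if phase_mode not in PHASE_MODES:
        raise ValueError(f"phase_mode must be one of {PHASE_MODES}")
    w = weights
    terms = []
    if "energies" in outputs:
        terms.append(ad.mul(w.require("energies"),
                            _mse_tensor(outputs["energies"], refs["energies"])))
    if "forces" in outputs:
        terms.append(ad.mul(w.require("forces"),
                            _mse_tensor(outputs["forces"], refs["forces"])))

    coupled_pred, coupled_ref, coupled_w = {}, {}, {}
    if "smooth_nacs" in outputs:
        coupled_pred["smooth_nacs"] = outputs["smooth_nacs"]
        coupled_ref["smooth_nacs"] = refs["smooth_nacs"]
        coupled_w["smooth_nacs"] = w.require("nacs")
    if "transition_dipoles" in outputs:
        coupled_pred["transition_dipoles"] = outputs["transition_dipoles"]
        coupled_ref["transition_dipoles"] = refs["transition_dipoles"]
        coupled_w["transition_dipoles"] = w.require("dipoles")
    if coupled_pred:
        aligned = _align_batch_refs(coupled_pred, coupled_ref, space,
                                    phase_mode, coupled_w, batch, atomistic)
        for key, pred_t in coupled_pred.items():
            weight = coupled_w[key]
            ref = aligned[key]
            if atomistic and key == "smooth_nacs" and batch is not None:
                inv = 1.0 / batch.atom_counts[batch.mol_id].astype(float)
                diff = ad.sub(pred_t, ad.tensor(ref))
                se = ad.mul(ad.square(diff), ad.tensor(inv[None, :, None]))
                terms.append(ad.mul(weight,
                                    ad.mul(ad.tsum(se),
                                           1.0 / (ref.shape[0] * batch.n_mol * 3))))
            else:
                terms.append(ad.mul(weight, _mse_tensor(pred_t, ref)))
    if "permanent_dipoles" in outputs:
        terms.append(ad.mul(w.require("dipoles"),
                            _mse_tensor(outputs["permanent_dipoles"],
                                        refs["permanent_dipoles"])))
    if not terms:
        raise ValueError("no active loss terms")
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    return total


def _align_batch_refs(pred: Mapping, ref: Mapping, space: StateSpace,
                      phase_mode: str, weights: Mapping, batch,
                      atomistic: bool) -> dict:
    """Sign-align coupled reference blocks per molecule of the batch."""
    if phase_mode == "none" or batch is None:
        return {k: np.asarray(v) for k, v in ref.items()}
    aligned = {k: np.array(v, dtype=np.float64, copy=True)
               for k, v in ref.items()}
    slices = batch.atom_slices()
    for m, sl in enumerate(slices):
        per_mol_pred, per_mol_ref = {}, {}
        if "smooth_nacs" in pred:
            per_mol_pred["smooth_nacs"] = pred["smooth_nacs"].value[:, sl, :]
            per_mol_ref["smooth_nacs"] = aligned["smooth_nacs"][:, sl, :]
        if "transition_dipoles" in pred:
            per_mol_pred["transition_dipoles"] = \
                pred["transition_dipoles"].value[m]
            per_mol_ref["transition_dipoles"] = \
                aligned["transition_dipoles"][m]
        signs = best_phase_alignment(per_mol_pred, per_mol_ref, space,
                                     "pairwise" if phase_mode == "pairwise"
                                     else "phase_vector", weights)
        if "smooth_nacs" in aligned:
            aligned["smooth_nacs"][:, sl, :] *= signs[:, None, None]
        if "transition_dipoles" in aligned:
            aligned["transition_dipoles"][m] *= signs[:, None]
    return aligned


# ---------------------------------------------------------------------------
# reference assembly
# ---------------------------------------------------------------------------

def _batch_refs(samples, space: StateSpace) -> dict:
    refs: dict = {}
    first = samples[0]
    if first.energies is not None:
        refs["energies"] = np.stack([s.energies for s in samples])
    if first.forces is not None:
        refs["forces"] = np.concatenate([s.forces for s in samples], axis=1)
    if first.smooth_nacs is not None:
        refs["smooth_nacs"] = np.concatenate(
            [s.smooth_nacs for s in samples], axis=1)
    if first.permanent_dipoles is not None:
        refs["permanent_dipoles"] = np.stack(
            [s.permanent_dipoles for s in samples])
    if first.transition_dipoles is not None:
        refs["transition_dipoles"] = np.stack(
            [s.transition_dipoles for s in samples])
    return refs


def _trainable_properties(model: ExcitedStateModel, samples) -> list:
    heads = model.config.heads
    first = samples[0]
    props = []
    if heads.energies and first.energies is not None:
        props.append("energies")
    if heads.forces and first.forces is not None:
        props.append("forces")
    if heads.nacs and first.smooth_nacs is not None:
        props.append("nacs")
    if heads.dipoles and first.permanent_dipoles is not None:
        props.append("dipoles")
    return props


# ---------------------------------------------------------------------------
# optimizer and loop
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[ad.Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, grads: Sequence[np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = np.inf
    stopped_early: bool = False


def train(model: ExcitedStateModel, train_ds: Dataset, val_ds: Dataset,
          config: TrainConfig, fit_offsets: bool = True,
          verbose: bool = False) -> TrainingHistory:
    """Minibatch Adam training with plateau LR decay and early stopping.

    Keeps the parameters of the epoch with the best validation loss; stops
    when the validation loss has not improved for ``patience`` epochs or at
    the epoch cap. Fully reproducible for a fixed seed.
    """
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("empty training or validation split")
    space = model.state_space
    if fit_offsets and train_ds[0].energies is not None:
        model.energy_offsets = fit_energy_reference(train_ds).offsets
    props = _trainable_properties(model, train_ds.samples)
    cutoff = model.config.representation.cutoff
    rng = np.random.default_rng(config.seed)

    # pre-collate validation set once
    val_batch = collate([s.geometry for s in val_ds.samples], cutoff)
    val_refs = _batch_refs(val_ds.samples, space)

    param_items = sorted(model.params.items())
    params = [t for _, t in param_items]
    opt = Adam(params, lr=config.lr)
    history = TrainingHistory()
    best_values = [p.value.copy() for p in params]
    since_best = 0
    since_decay = 0
    n = len(train_ds)
    indices = np.arange(n)

    for epoch in range(config.epochs):
        rng.shuffle(indices)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = indices[start:start + config.batch_size]
            samples = [train_ds.samples[i] for i in idx]
            batch = collate([s.geometry for s in samples], cutoff)
            refs = _batch_refs(samples, space)
            out = model.forward(batch, props, create_graph=True)
            loss = combined_loss(out, refs, config.weights, config.phase_mode,
                                 space, batch, config.atomistic)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting at index {start} (samples {idx[:5]}...)")
            grads = ad.grad(loss, params)
            opt.step([g.value for g in grads])
            epoch_loss += loss.item() * len(idx)
            seen += len(idx)

        # validation: no parameter gradients, but force/NAC heads still
        # differentiate through positions
        model.set_requires(False)
        try:
            val_out = model.forward(val_batch, props)
            val_loss = combined_loss(val_out, val_refs, config.weights,
                                     config.phase_mode, space, val_batch,
                                     config.atomistic).item()
        finally:
            model.set_requires(True)
        history.epochs.append(epoch)
        history.train_loss.append(epoch_loss / seen)
        history.val_loss.append(val_loss)
        history.lr.append(opt.lr)
        if verbose and epoch % 25 == 0:
            print(f"epoch {epoch:5d} train {epoch_loss / seen:.3e} "
                  f"val {val_loss:.3e} lr {opt.lr:.2e}")

        if val_loss < history.best_val - 1e-12:
            history.best_val = val_loss
            history.best_epoch = epoch
            best_values = [p.value.copy() for p in params]
            since_best = 0
            since_decay = 0
        else:
            since_best += 1
            since_decay += 1
            if since_best >= config.patience:
                history.stopped_early = True
                break
            if (config.lr_decay < 1.0 and since_decay >= config.lr_patience
                    and opt.lr > config.min_lr):
                opt.lr = max(opt.lr * config.lr_decay, config.min_lr)
                since_decay = 0

    for p, best in zip(params, best_values):
        p.value = best
    return history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(model: ExcitedStateModel, dataset: Dataset,
             batch_size: int = 256) -> dict:
    """Per-property MAE and RMSE over all components.

    Coupled properties (smoothed NACs, transition dipoles) are scored
    modulo the best phase vector per sample, since their reference signs
    are arbitrary.
    """
    space = model.state_space
    props = _trainable_properties(model, dataset.samples)
    cutoff = model.config.representation.cutoff
    acc: dict = {}

    def push(name, diff):
        a = acc.setdefault(name, [0.0, 0.0, 0])
        a[0] += float(np.sum(np.abs(diff)))
        a[1] += float(np.sum(diff * diff))
        a[2] += diff.size

    for start in range(0, len(dataset), batch_size):
        samples = dataset.samples[start:start + batch_size]
        preds = model.predict([s.geometry for s in samples], props)
        for s, pr in zip(samples, preds):
            if "energies" in props:
                push("energies", pr.energies - s.energies)
            if "forces" in props:
                push("forces", pr.forces - s.forces)
            coupled_pred, coupled_ref = {}, {}
            if "nacs" in props:
                coupled_pred["smooth_nacs"] = pr.smooth_nacs
                coupled_ref["smooth_nacs"] = s.smooth_nacs
            if "dipoles" in props and s.transition_dipoles is not None:
                coupled_pred["transition_dipoles"] = pr.transition_dipoles
                coupled_ref["transition_dipoles"] = s.transition_dipoles
            if coupled_pred:
                signs = best_phase_alignment(coupled_pred, coupled_ref, space)
                if "smooth_nacs" in coupled_pred:
                    push("smooth_nacs", pr.smooth_nacs
                         - signs[:, None, None] * s.smooth_nacs)
                if "transition_dipoles" in coupled_pred:
                    push("transition_dipoles", pr.transition_dipoles
                         - signs[:, None] * s.transition_dipoles)
            if "dipoles" in props and s.permanent_dipoles is not None:
                push("permanent_dipoles",
                     pr.permanent_dipoles - s.permanent_dipoles)
    return {name: {"mae": a[0] / a[2], "rmse": float(np.sqrt(a[1] / a[2])),
                   "n": a[2]}
            for name, a in acc.items()}
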