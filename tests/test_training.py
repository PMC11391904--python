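"""Phase-free losses, the combined objective, optimization and scoring."""

import itertools

import numpy as np
import pytest

import namdnn.autodiff as ad
from namdnn.data import StateSpace, split_dataset
from namdnn.representation import collate
from namdnn.training import (LossWeights, TrainConfig, combined_loss,
                             evaluate, pairwise_phase_loss, phase_vectors,
                             pair_signs, phase_vector_loss, property_loss,
                             train)
from conftest import tiny_model

S2, S3 = StateSpace(2), StateSpace(3)
RNG = np.random.default_rng(12)


class TestPropertyLoss:
    def test_zero_iff_equal_and_unit_example(self):
        x = RNG.normal(size=(2, 5))
        assert property_loss(x, x) == 0.0
        assert property_loss(np.ones(1), np.zeros(1)) == pytest.approx(1.0)

    def test_agrees_with_bruteforce_mean_of_squares(self):
        a, b = RNG.normal(size=(3, 4, 5)), RNG.normal(size=(3, 4, 5))
        want = np.mean((a - b) ** 2)
        assert property_loss(a, b) == pytest.approx(want, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            property_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestPairwisePhaseLoss:
    def test_zero_under_random_per_pair_sign_flips(self):
        pred = RNG.normal(size=(3, 4, 3))
        signs = np.array([1.0, -1.0, -1.0])
        ref = pred * signs[:, None, None]
        assert pairwise_phase_loss(pred, ref) == pytest.approx(0.0, abs=1e-30)

    def test_single_pair_full_flip_is_free(self):
        pred = RNG.normal(size=(1, 5, 3))
        assert pairwise_phase_loss(pred, -pred) == pytest.approx(0.0,
                                                                 abs=1e-30)

    def test_matches_bruteforce_joint_minimum(self):
        pred = RNG.normal(size=(3, 2, 3))
        ref = RNG.normal(size=(3, 2, 3))
        best = np.inf
        for signs in itertools.product((1, -1), repeat=3):
            s = np.array(signs, dtype=float)[:, None, None]
            best = min(best, np.mean((s * pred - ref) ** 2))
        assert pairwise_phase_loss(pred, ref) == pytest.approx(best,
                                                               rel=1e-12)

    def test_coupled_group_shares_one_sign_per_pair(self):
        nac = RNG.normal(size=(1, 4, 3))
        mu = RNG.normal(size=(1, 3))
        # flipping only the dipole reference must cost something
        loss_joint = pairwise_phase_loss(
            {"nacs": nac, "mu": mu}, {"nacs": nac, "mu": -mu})
        assert loss_joint > 0


class TestPhaseVectorLoss:
    def test_zero_for_any_phase_vector_applied_to_references(self):
        for space in (S2, S3, StateSpace(4)):
            pred = RNG.normal(size=(space.n_pairs, 3, 3))
            for p in phase_vectors(space.n_states):
                signs = pair_signs(p, space)
                ref = pred * signs[:, None, None]
                assert phase_vector_loss(pred, ref, space) == pytest.approx(
                    0.0, abs=1e-30)

    def test_inconsistent_single_pair_flip_distinguishes_losses(self):
        pred = RNG.normal(size=(3, 4, 3))   # S = 3
        ref = pred.copy()
        ref[0] = -ref[0]                    # flip only pair (0, 1)
        assert pairwise_phase_loss(pred, ref) == pytest.approx(0.0,
                                                               abs=1e-30)
        assert phase_vector_loss(pred, ref, S3) > 1e-3

    def test_two_states_pairwise_equals_phase_vector(self):
        pred = RNG.normal(size=(1, 6, 3))
        ref = RNG.normal(size=(1, 6, 3))
        assert phase_vector_loss(pred, ref, S2) == pytest.approx(
            pairwise_phase_loss(pred, ref), rel=1e-12)

    def test_large_state_count_suggests_pairwise(self):
        with pytest.raises(ValueError, match="pairwise"):
            phase_vectors(13)

    def test_ordering_pairwise_le_phase_vector_le_mse(self):
        for k in range(1000):
            rng = np.random.default_rng(k)
            s = int(rng.integers(2, 5))
            space = StateSpace(s)
            pred = rng.normal(size=(space.n_pairs, 2))
            ref = rng.normal(size=(space.n_pairs, 2))
            lp = pairwise_phase_loss(pred, ref)
            lv = phase_vector_loss(pred, ref, space)
            lm = property_loss(pred, ref)
            assert lp <= lv + 1e-12 and lv <= lm + 1e-12


class TestCombinedLoss:
    def _setup(self, phase_flip=None):
        model = tiny_model(n_features=8)
        ds_geos = [  # two tiny molecules
            _geo(seed) for seed in (1, 2)]
        batch = collate(ds_geos, model.config.representation.cutoff)
        out = model.forward(batch)
        refs = {
            "energies": out["energies"].value.copy(),
            "forces": out["forces"].value.copy(),
            "smooth_nacs": out["smooth_nacs"].value.copy(),
            "permanent_dipoles": out["permanent_dipoles"].value.copy(),
            "transition_dipoles": out["transition_dipoles"].value.copy(),
        }
        if phase_flip is not None:
            refs["smooth_nacs"] = refs["smooth_nacs"] * phase_flip
            refs["transition_dipoles"] = refs["transition_dipoles"] \
                * phase_flip
        return model, batch, out, refs

    def test_energy_only_weights_reduce_to_energy_mse(self):
        model, batch, out, refs = self._setup()
        refs["energies"] = refs["energies"] + 0.3
        w = LossWeights(energies=1.0, forces=0.0, nacs=0.0, dipoles=0.0)
        loss = combined_loss(out, refs, w, "phase_vector",
                             model.state_space, batch)
        assert loss.item() == pytest.approx(0.09, rel=1e-10)

    def test_linear_in_each_weight(self):
        model, batch, out, refs = self._setup()
        refs["forces"] = refs["forces"] + 0.1
        l1 = combined_loss(out, refs, LossWeights(forces=1.0), "none",
                           model.state_space, batch).item()
        l2 = combined_loss(out, refs, LossWeights(forces=2.0), "none",
                           model.state_space, batch).item()
        base = combined_loss(out, refs, LossWeights(forces=0.0), "none",
                             model.state_space, batch).item()
        assert l2 - base == pytest.approx(2 * (l1 - base), rel=1e-9)

    def test_phase_flipped_references_cost_nothing(self):
        model, batch, out, refs = self._setup(phase_flip=-1.0)
        loss = combined_loss(out, refs, LossWeights(), "phase_vector",
                             model.state_space, batch)
        assert loss.item() == pytest.approx(0.0, abs=1e-24)

    def test_undefined_weight_for_active_property_rejected(self):
        model, batch, out, refs = self._setup()
        with pytest.raises(ValueError, match="undefined"):
            combined_loss(out, refs, LossWeights(forces=None), "none",
                          model.state_space, batch)

    def test_gradient_matches_finite_differences(self):
        model, batch, out, refs = self._setup()
        refs = {k: v + 0.05 for k, v in refs.items()}
        params = sorted(model.params.items())
        names = [n for n, _ in params]
        tensors = [t for _, t in params]

        def loss_value():
            o = model.forward(batch, create_graph=True)
            return combined_loss(o, refs, LossWeights(), "phase_vector",
                                 model.state_space, batch)

        grads = ad.grad(loss_value(), tensors)
        rng = np.random.default_rng(0)
        for _ in range(5):
            k = int(rng.integers(len(tensors)))
            t = tensors[k]
            idx = tuple(rng.integers(s) for s in t.shape)
            eps = 1e-5
            orig = t.value[idx]
            t.value[idx] = orig + eps
            lp = loss_value().item()
            t.value[idx] = orig - eps
            lm = loss_value().item()
            t.value[idx] = orig
            fd = (lp - lm) / (2 * eps)
            got = grads[k].value[idx]
            assert abs(fd - got) <= 1e-4 * max(abs(fd), 1e-8), names[k]


def _geo(seed):
    from namdnn.data import Geometry
    rng = np.random.default_rng(seed)
    base = np.array([[0.0, 0, 0], [2.5, 0, 0], [1.2, 2.2, 0]])
    return Geometry(np.array([1, 6, 8]), base + 0.2 * rng.normal(size=(3, 3)))


class TestWeights:
    def test_validation(self):
        with pytest.raises(ValueError):
            LossWeights(energies=-1.0)
        with pytest.raises(ValueError):
            LossWeights(energies=0.0, forces=0.0, nacs=0.0, dipoles=0.0)

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(patience=0)
        with pytest.raises(ValueError):
            TrainConfig(phase_mode="magic")


class TestTrainLoop:
    def _small_splits(self, ci2d):
        from namdnn.models import SamplingSpec, generate_dataset
        ds = generate_dataset(ci2d, SamplingSpec(n_samples=60, seed=3))
        return split_dataset(ds, (0.7, 0.15, 0.15), seed=0)

    def test_constant_target_learned_quickly(self, ci2d, small_dataset):
        # constant energies: trivially learnable through the bias terms
        tr, va, _ = split_dataset(small_dataset, (0.7, 0.15, 0.15), seed=0)
        import copy
        tr = tr.subset(range(20))
        va = va.subset(range(10))
        for part in (tr, va):
            for s in part.samples:
                s.energies = np.array([-0.25, 0.5])
                s.forces = np.zeros_like(s.forces)
                s.smooth_nacs = np.zeros_like(s.smooth_nacs)
                s.nacs = np.zeros_like(s.nacs)
        model = tiny_model(dipoles=False, n_features=8, head_init="zero")
        cfg = TrainConfig(epochs=200, patience=300, lr=5e-3, batch_size=20,
                          seed=0, phase_mode="none")
        history = train(model, tr, va, cfg)
        assert history.best_val < 1e-6

    def test_patience_triggers_after_exact_count(self, ci2d, small_dataset):
        tr, va, _ = split_dataset(small_dataset, (0.7, 0.15, 0.15), seed=0)
        model = tiny_model(dipoles=False, n_features=8)
        # frozen model: zero learning rate, loss never improves after epoch 0
        cfg = TrainConfig(epochs=100, patience=5, lr=0.0, batch_size=32,
                          seed=0, lr_decay=1.0)
        history = train(model, tr.subset(range(16)), va.subset(range(8)), cfg)
        assert history.stopped_early
        assert len(history.epochs) == 1 + cfg.patience
        assert history.best_epoch == 0

    def test_same_seed_identical_histories(self, small_dataset):
        tr, va, _ = split_dataset(small_dataset, (0.7, 0.15, 0.15), seed=0)
        tr, va = tr.subset(range(24)), va.subset(range(8))
        runs = []
        for _ in range(2):
            model = tiny_model(dipoles=False, n_features=8)
            cfg = TrainConfig(epochs=5, patience=300, lr=3e-3, batch_size=12,
                              seed=11)
            runs.append(train(model, tr, va, cfg))
        assert runs[0].train_loss == runs[1].train_loss
        assert runs[0].val_loss == runs[1].val_loss

    def test_best_checkpoint_is_never_a_worse_epoch(self, small_dataset):
        tr, va, _ = split_dataset(small_dataset, (0.7, 0.15, 0.15), seed=0)
        model = tiny_model(dipoles=False, n_features=8)
        cfg = TrainConfig(epochs=8, patience=300, lr=5e-3, batch_size=16,
                          seed=1)
        h = train(model, tr.subset(range(32)), va.subset(range(8)), cfg)
        assert h.best_val == min(h.val_loss)

    def test_empty_split_rejected(self, small_dataset):
        model = tiny_model(dipoles=False)
        with pytest.raises(ValueError):
            train(model, small_dataset.subset([]), small_dataset,
                  TrainConfig())


class TestEvaluate:
    def test_agrees_with_bruteforce_on_small_set(self, small_dataset):
        model = tiny_model(dipoles=False, n_features=8)
        subset = small_dataset.subset(range(20))
        table = evaluate(model, subset)
        # independent recomputation, sample by sample, phase-aligned
        diffs = {"energies": [], "forces": [], "smooth_nacs": []}
        for s in subset.samples:
            pr = model.predict(s.geometry)
            diffs["energies"].append(pr.energies - s.energies)
            diffs["forces"].append(pr.forces - s.forces)
            d_plus = pr.smooth_nacs - s.smooth_nacs
            d_minus = pr.smooth_nacs + s.smooth_nacs
            pick = d_plus if np.sum(d_plus ** 2) <= np.sum(d_minus ** 2) \
                else d_minus
            diffs["smooth_nacs"].append(pick)
        for name, dl in diffs.items():
            flat = np.concatenate([d.ravel() for d in dl])
            assert table[name]["mae"] == pytest.approx(
                np.mean(np.abs(flat)), rel=1e-12)
            assert table[name]["rmse"] == pytest.approx(
                np.sqrt(np.mean(flat ** 2)), rel=1e-12)

    def test_rmse_at_least_mae(self, small_dataset):
        model = tiny_model(dipoles=False, n_features=8)
        table = evaluate(model, small_dataset.subset(range(10)))
        for row in table.values():
            assert row["rmse"] >= row["mae"] - 1e-15
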