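"""Stage-1 transfer: pairing, alignment, loss, meta updates, freezing."""

import numpy as np
import pytest

from vfmgl import nn
from vfmgl.data import ArrayDataset
from vfmgl.hgkt import (MetaNet, Stage1Config, align_features,
                        enumerate_pairs, meta_update_weights, per_pair_losses,
                        score_and_freeze, stage1_train, transfer_loss)
from vfmgl.model_zoo import (FeatureBundle, ModelSpec, build_model,
                             extract_features)
from vfmgl.nn import Tensor


@pytest.fixture(scope="module")
def vit_spec():
    return ModelSpec("classification", "tiny-vit", (32, 32, 3), 2)


@pytest.fixture(scope="module")
def student_spec():
    return ModelSpec("classification", "residual-18", (32, 32, 3), 2, width=2)


class TestEnumeratePairs:
    def test_full_bipartite_uniform(self, vit_spec, student_spec):
        plan = enumerate_pairs(vit_spec, student_spec)
        assert len(plan.pairs) == 4 * 4
        np.testing.assert_allclose(plan.weights, 0.25)

    def test_single_pair_weight_one(self):
        t = ModelSpec("classification", "tiny-vit", (32, 32, 3), 2,
                      layer_names=["block1"])
        s = ModelSpec("classification", "residual-18", (32, 32, 3), 2,
                      layer_names=["stage4"])
        plan = enumerate_pairs(t, s)
        assert plan.pairs == [("block1", "stage4")]
        assert plan.weights[0] == 1.0

    @pytest.mark.parametrize("nt,ns", [(1, 3), (3, 1), (4, 9)])
    def test_normalized_weights_sum_to_one_per_student_layer(self, nt, ns):
        t = ModelSpec("classification", "tiny-vit", (32, 32, 3), 2,
                      layer_names=[f"block{i+1}" for i in range(nt)])
        s = ModelSpec("segmentation", "u-shaped", (32, 32, 3), 1,
                      layer_names=ModelSpec("segmentation", "u-shaped",
                                            (32, 32, 3), 1).layer_names[:ns])
        plan = enumerate_pairs(t, s)
        norm = plan.normalized_weights()
        for layer in plan.student_layers:
            assert norm[plan.pairs_into(layer)].sum() == pytest.approx(1.0)

    def test_empty_layer_list_raises(self, vit_spec, student_spec):
        bad = ModelSpec("classification", "residual-18", (32, 32, 3), 2)
        bad.layer_names = []
        with pytest.raises(ValueError, match="hookable"):
            enumerate_pairs(vit_spec, bad)


class TestAlignFeatures:
    def _token_bundle(self, data, gh, gw):
        return FeatureBundle({"block1": Tensor(data)}, grid=(gh, gw),
                             has_class_token=False, layer_names=("block1",))

    def test_identity_projector_same_grid_is_pure_reshape(self, rng):
        dim = gh = gw = 4
        tok = rng.normal(size=(2, gh * gw, dim))
        bundle = self._token_bundle(tok, gh, gw)
        eye = nn.Parameter(np.eye(dim).reshape(dim, dim, 1, 1))
        out = align_features(bundle, ("block1", "stage1"), eye, (dim, gh, gw))
        expect = tok.transpose(0, 2, 1).reshape(2, dim, gh, gw)
        np.testing.assert_allclose(out.data, expect, atol=1e-12)

    def test_constant_tokens_stay_constant(self, rng):
        tok = np.ones((1, 16, 6)) * 3.5
        bundle = self._token_bundle(tok, 4, 4)
        proj = nn.Parameter(rng.normal(size=(5, 6, 1, 1)))
        out = align_features(bundle, ("block1", "s"), proj, (5, 9, 9))
        for c in range(5):
            assert np.ptp(out.data[0, c]) < 1e-12

    @pytest.mark.parametrize("gh,gw,c,h,w", [
        (4, 4, 3, 8, 8), (2, 2, 7, 5, 11), (8, 8, 2, 3, 3)])
    def test_output_matches_student_geometry(self, rng, gh, gw, c, h, w):
        dim = 6
        bundle = self._token_bundle(rng.normal(size=(2, gh * gw, dim)), gh, gw)
        proj = nn.Parameter(rng.normal(size=(c, dim, 1, 1)))
        out = align_features(bundle, ("block1", "s"), proj, (c, h, w))
        assert out.shape == (2, c, h, w)

    def test_token_grid_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="token count"):
            self._token_bundle(rng.normal(size=(1, 15, 4)), 4, 4)

    def test_gradient_flows_to_projector_only(self, tiny_teacher, rng):
        x = rng.normal(size=(2, 3, 32, 32))
        bundle = extract_features(tiny_teacher, x)
        proj = nn.Parameter(rng.normal(size=(3, 96, 1, 1)))
        out = align_features(bundle, ("block2", "s"), proj, (3, 6, 6))
        (out * out).mean().backward()
        assert proj.grad is not None


class TestTransferLoss:
    def test_zero_when_student_copies_aligned_teacher(
            self, tiny_teacher, student_spec, rng):
        student = build_model(student_spec, seed=0)
        x = rng.normal(size=(2, 3, 32, 32))
        t_feats = extract_features(tiny_teacher, x)
        s_feats = student.forward_features(Tensor(x))
        plan = enumerate_pairs(tiny_teacher.spec, student.spec)
        per_pair_losses(s_feats, t_feats, plan)  # builds projectors
        # weight one incoming pair per student layer; copy those aligned maps
        plan.weights = np.zeros(len(plan.pairs))
        copied = {}
        for i, (t, s) in enumerate(plan.pairs):
            if t == "block4":
                plan.weights[i] = 1.0
                aligned = align_features(t_feats, (t, s), plan.projectors[i],
                                         s_feats.features[s].shape[1:])
                copied[s] = aligned.detach()
        bundle = FeatureBundle(copied,
                               layer_names=tuple(student.spec.layer_names))
        assert transfer_loss(bundle, t_feats, plan).item() < 1e-20

    def test_single_weighted_pair_equals_its_mse(
            self, tiny_teacher, student_spec, rng):
        student = build_model(student_spec, seed=1)
        x = rng.normal(size=(2, 3, 32, 32))
        t_feats = extract_features(tiny_teacher, x)
        s_feats = student.forward_features(Tensor(x))
        plan = enumerate_pairs(tiny_teacher.spec, student.spec)
        losses = per_pair_losses(s_feats, t_feats, plan)
        plan.weights = np.zeros(len(plan.pairs))
        plan.weights[5] = 1.0
        total = transfer_loss(s_feats, t_feats, plan)
        assert total.item() == pytest.approx(losses[5].item())

    def test_two_pair_weighted_mean(self, tiny_teacher, student_spec, rng):
        student = build_model(student_spec, seed=2)
        x = rng.normal(size=(2, 3, 32, 32))
        t_feats = extract_features(tiny_teacher, x)
        s_feats = student.forward_features(Tensor(x))
        plan = enumerate_pairs(tiny_teacher.spec, student.spec)
        losses = [l.item() for l in per_pair_losses(s_feats, t_feats, plan)]
        plan.weights = np.zeros(len(plan.pairs))
        plan.weights[0], plan.weights[7] = 0.3, 0.7
        expect = 0.3 * losses[0] + 0.7 * losses[7]
        assert transfer_loss(s_feats, t_feats, plan).item() == \
            pytest.approx(expect)

    def test_invariant_to_common_positive_rescaling(
            self, tiny_teacher, student_spec, rng):
        student = build_model(student_spec, seed=3)
        x = rng.normal(size=(2, 3, 32, 32))
        t_feats = extract_features(tiny_teacher, x)
        s_feats = student.forward_features(Tensor(x))
        plan = enumerate_pairs(tiny_teacher.spec, student.spec)
        base = transfer_loss(s_feats, t_feats, plan).item()
        scaled = FeatureBundle(
            {k: v * 7.3 for k, v in s_feats.features.items()},
            layer_names=s_feats.layer_names)
        assert transfer_loss(scaled, t_feats, plan).item() == \
            pytest.approx(base, rel=1e-6)


class TestMetaUpdates:
    def _setup(self, tiny_teacher, student_spec, rng, seed=0):
        student = build_model(student_spec, seed=seed)
        plan = enumerate_pairs(tiny_teacher.spec, student.spec)
        plan.meta = MetaNet(4, seed=seed)
        x = rng.normal(size=(8, 3, 32, 32))
        y = rng.integers(0, 2, 8)
        xv = rng.normal(size=(8, 3, 32, 32))
        yv = rng.integers(0, 2, 8)
        return student, plan, (x, y, xv, yv)

    def test_zero_meta_lr_leaves_plan_unchanged(
            self, tiny_teacher, student_spec, rng):
        student, plan, batch = self._setup(tiny_teacher, student_spec, rng)
        before = plan.weights.copy()
        meta_update_weights(plan, student, tiny_teacher, batch, lr_meta=0.0)
        np.testing.assert_array_equal(plan.weights, before)

    def test_meta_step_preserves_simplex_and_student(
            self, tiny_teacher, student_spec, rng):
        student, plan, batch = self._setup(tiny_teacher, student_spec, rng, 1)
        params_before = {n: p.data.copy()
                         for n, p in student.named_parameters()}
        buffers_before = {n: b.copy() for n, b in student.named_buffers()}
        meta_update_weights(plan, student, tiny_teacher, batch,
                            lr_meta=0.001)
        assert np.all(plan.weights >= 0)
        norm = plan.normalized_weights()
        for layer in plan.student_layers:
            assert norm[plan.pairs_into(layer)].sum() == pytest.approx(1.0)
        for n, p in student.named_parameters():
            np.testing.assert_array_equal(p.data, params_before[n])
        for n, b in student.named_buffers():
            np.testing.assert_array_equal(b, buffers_before[n])

    def test_metanet_zero_head_emits_uniform(self):
        net = MetaNet(5, seed=0)
        w = net(Tensor(np.random.default_rng(0).normal(size=(7, 3))))
        np.testing.assert_allclose(w.data, 1 / 5)


class TestStage1Training:
    def test_empty_dataset_raises(self, tiny_teacher, tiny_student):
        plan = enumerate_pairs(tiny_teacher.spec, tiny_student.spec)
        empty = ArrayDataset(np.zeros((0, 3, 32, 32)), np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            stage1_train(empty, tiny_teacher, tiny_student, plan,
                         Stage1Config(epochs=1))

    def test_fixed_seed_reproduces_final_weights(
            self, tiny_teacher, student_spec):
        from vfmgl.synthetic import SyntheticConfig, generate_federation
        fed = generate_federation(SyntheticConfig(
            n_centers=1, n_samples=16, image_size=32, split_ratios=(1.0,),
            seed=5))
        ds = next(iter(fed.values()))["train"]

        def train_once():
            student = build_model(student_spec, seed=7)
            plan = enumerate_pairs(tiny_teacher.spec, student.spec)
            cfg = Stage1Config(epochs=1, lr=0.02, batch_size=8, seed=42)
            return stage1_train(ds, tiny_teacher, student, plan, cfg)

        s1, p1, h1 = train_once()
        s2, p2, h2 = train_once()
        assert h1 == h2
        np.testing.assert_array_equal(p1.weights, p2.weights)
        for (n, a), (_, b) in zip(s1.named_parameters(),
                                  s2.named_parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_training_loss_decreases_over_five_epochs(
            self, tiny_teacher, student_spec):
        from vfmgl.synthetic import SyntheticConfig, generate_federation
        fed = generate_federation(SyntheticConfig(
            n_centers=1, n_samples=32, image_size=32, split_ratios=(1.0,),
            seed=42))
        ds = next(iter(fed.values()))["train"]
        student = build_model(student_spec, seed=42)
        plan = enumerate_pairs(tiny_teacher.spec, student.spec)
        cfg = Stage1Config(epochs=5, batch_size=8, seed=42)  # default lr
        _, _, history = stage1_train(ds, tiny_teacher, student, plan, cfg)
        assert all(b < a for a, b in zip(history, history[1:]))


class TestScoreAndFreeze:
    def _plan(self, weights):
        t = ModelSpec("classification", "tiny-vit", (32, 32, 3), 2)
        s = ModelSpec("classification", "residual-18", (32, 32, 3), 2)
        plan = enumerate_pairs(t, s)
        plan.weights = np.asarray(weights, dtype=float)
        return plan

    def test_uniform_weights_full_fraction_freezes_all(self):
        plan = self._plan(np.full(16, 0.25))
        crit = score_and_freeze(plan, top_fraction=1.0)
        assert all(crit.frozen.values())
        assert sum(crit.scores.values()) == pytest.approx(1.0)

    def test_concentrated_mass_freezes_that_stage_only(self):
        w = np.zeros(16)
        w[[i for i, (t, s) in enumerate(
            self._plan(np.zeros(16)).pairs) if s == "stage3"]] = 1.0
        crit = score_and_freeze(self._plan(w), top_fraction=0.25)
        assert crit.frozen_layers() == ["stage3"]

    def test_ties_break_toward_earlier_layer(self):
        crit = score_and_freeze(self._plan(np.full(16, 0.25)),
                                top_fraction=0.5)
        assert crit.frozen_layers() == ["stage1", "stage2"]

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError, match="top_fraction"):
            score_and_freeze(self._plan(np.full(16, 0.25)), top_fraction=0.0)

    def test_plan_json_is_auditable(self):
        plan = self._plan(np.full(16, 0.25))
        crit = score_and_freeze(plan, 0.5)
        import json
        doc = json.loads(plan.to_json(crit))
        assert len(doc["pairs"]) == 16
        assert set(doc["frozen"]) == set(plan.student_layers)
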