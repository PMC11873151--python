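"""Batch-level data deduction and logit distillation."""

import numpy as np
import pytest

from vfmgl.data import ArrayDataset, Batch
from vfmgl.ddbl_kd import (BatchHeterogeneityScore, Stage2Config, _mean_kl,
                           kd_loss, score_batches, select_low_heterogeneity,
                           stage2_train)
from vfmgl.model_zoo import build_model
from vfmgl.nn import Tensor
from vfmgl.nn.functional import cross_entropy


def scores_from(divs, rates=None):
    rates = rates or [0.0] * len(divs)
    return [BatchHeterogeneityScore(i, d, r)
            for i, (d, r) in enumerate(zip(divs, rates))]


class TestScoreBatches:
    def test_identical_models_give_zero_divergence(
            self, tiny_student_spec, rng):
        a = build_model(tiny_student_spec, seed=3)
        b = build_model(tiny_student_spec, seed=3)
        batches = [Batch(i, rng.normal(size=(4, 3, 32, 32)),
                         rng.integers(0, 2, 4)) for i in range(3)]
        for s in score_batches(a, b, batches):
            assert s.divergence == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_two_class_kl(self):
        p = np.array([[0.9, 0.1]])
        q = np.array([[0.5, 0.5]])
        expect = 0.9 * np.log(0.9 / 0.5) + 0.1 * np.log(0.1 / 0.5)
        assert _mean_kl(p, q) == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(0.368, abs=5e-4)

    def test_duplicated_batch_scores_identically(
            self, tiny_student_spec, rng):
        a = build_model(tiny_student_spec, seed=1)
        b = build_model(tiny_student_spec, seed=2)
        imgs = rng.normal(size=(4, 3, 32, 32))
        batches = [Batch(0, imgs, np.zeros(4, int)),
                   Batch(1, imgs.copy(), np.zeros(4, int))]
        s = score_batches(a, b, batches)
        assert s[0].divergence == pytest.approx(s[1].divergence, abs=1e-15)

    def test_rate_tracks_previous_pass(self, tiny_student_spec, rng):
        a = build_model(tiny_student_spec, seed=1)
        b = build_model(tiny_student_spec, seed=2)
        batches = [Batch(0, rng.normal(size=(4, 3, 32, 32)),
                         np.zeros(4, int))]
        first = score_batches(a, b, batches)
        assert first[0].divergence_rate == 0.0
        prev = [BatchHeterogeneityScore(0, first[0].divergence + 0.5)]
        second = score_batches(a, b, batches, previous=prev)
        assert second[0].divergence_rate == pytest.approx(-0.5)


class TestSelection:
    def test_keep_all(self):
        assert select_low_heterogeneity(scores_from([3.0, 1.0, 2.0]), 1.0) \
            == [0, 1, 2]

    def test_lowest_divergence_kept(self):
        sc = scores_from([0.1, 5.0, 0.2, 4.0])
        assert select_low_heterogeneity(sc, 0.5) == [0, 2]
        assert [s.selected for s in sc] == [True, False, True, False]

    def test_tie_break_by_rate_then_id(self):
        sc = scores_from([1.0, 1.0, 1.0], rates=[0.9, -0.1, 0.5])
        assert select_low_heterogeneity(sc, 1 / 3) == [1]

    def test_selection_is_idempotent(self):
        sc = scores_from([0.3, 0.1, 0.6, 0.2, 0.9])
        first = select_low_heterogeneity(sc, 0.6)
        again = select_low_heterogeneity(
            [s for s in sc if s.batch_id in first], 1.0)
        assert again == first

    def test_empty_scores_raise(self):
        with pytest.raises(ValueError, match="empty"):
            select_low_heterogeneity([], 0.5)

    def test_bad_fraction_raises(self):
        with pytest.raises(ValueError, match="keep_fraction"):
            select_low_heterogeneity(scores_from([1.0]), 0.0)


class TestKDLoss:
    def test_identical_logits_reduce_to_weighted_task_loss(self, rng):
        logits = Tensor(rng.normal(size=(6, 2)))
        labels = rng.integers(0, 2, 6)
        loss = kd_loss(logits, logits.detach(), labels, T=2.0, alpha=0.5)
        task = cross_entropy(logits, labels)
        assert loss.item() == pytest.approx(0.5 * task.item())

    def test_alpha_one_is_pure_task_loss(self, rng):
        s = Tensor(rng.normal(size=(5, 3)))
        t = Tensor(rng.normal(size=(5, 3)))
        labels = rng.integers(0, 3, 5)
        assert kd_loss(s, t, labels, T=3.0, alpha=1.0).item() == \
            pytest.approx(cross_entropy(s, labels).item())

    def test_hand_computed_distillation_term(self):
        s = Tensor(np.array([[2.0, 0.0]]))
        t = Tensor(np.array([[0.0, 0.0]]))
        loss = kd_loss(s, t, np.array([0]), T=1.0, alpha=0.0)
        ps = np.array([0.5, 0.5])
        qs = np.exp([2.0, 0.0]) / np.exp([2.0, 0.0]).sum()
        expect = (ps * np.log(ps / qs)).sum()
        assert loss.item() == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(0.433, abs=1e-3)

    def test_continuous_and_linear_in_alpha(self, rng):
        s = Tensor(rng.normal(size=(4, 2)))
        t = Tensor(rng.normal(size=(4, 2)))
        labels = rng.integers(0, 2, 4)
        at = lambda a: kd_loss(s, t, labels, T=2.0, alpha=a).item()
        mid = 0.5 * (at(0.0) + at(1.0))
        assert at(0.5) == pytest.approx(mid, rel=1e-9)

    def test_segmentation_distillation_pixelwise(self, rng):
        s = Tensor(rng.normal(size=(2, 1, 8, 8)))
        masks = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        same = kd_loss(s, s.detach(), masks, T=2.0, alpha=0.0,
                       task="segmentation")
        assert same.item() == pytest.approx(0.0, abs=1e-12)
        diff = kd_loss(s, Tensor(rng.normal(size=(2, 1, 8, 8))), masks,
                       T=2.0, alpha=0.0, task="segmentation")
        assert diff.item() > 0

    def test_invalid_args_raise(self, rng):
        s = Tensor(rng.normal(size=(2, 2)))
        with pytest.raises(ValueError, match="temperature"):
            kd_loss(s, s, np.zeros(2, int), T=0.0, alpha=0.5)
        with pytest.raises(ValueError, match="alpha"):
            kd_loss(s, s, np.zeros(2, int), T=1.0, alpha=1.5)
        with pytest.raises(ValueError, match="shape"):
            kd_loss(s, Tensor(np.zeros((3, 2))), np.zeros(2, int), 1.0, 0.5)


class TestStage2Train:
    def _data(self, rng, n=16):
        return ArrayDataset(rng.random((n, 3, 32, 32)),
                            rng.integers(0, 2, n))

    def test_keep_fraction_leaving_no_batches_raises(
            self, tiny_student_spec, rng):
        local = build_model(tiny_student_spec, seed=0)
        shared = build_model(tiny_student_spec, seed=1)
        cfg = Stage2Config(batch_size=8, keep_fraction=0.05)
        with pytest.raises(ValueError, match="keep_fraction"):
            stage2_train(local, shared, self._data(rng), frozenset(), cfg)

    def test_fully_frozen_client_parameters_unchanged_loss_logged(
            self, tiny_student_spec, rng):
        local = build_model(tiny_student_spec, seed=0)
        shared = build_model(tiny_student_spec, seed=1)
        frozen = frozenset(["conv1", "bn1", "fc",
                            "layer1", "layer2", "layer3", "layer4"])
        before = {n: p.data.copy() for n, p in local.named_parameters()}
        cfg = Stage2Config(batch_size=8, keep_fraction=1.0, epochs=1)
        _, scores, losses = stage2_train(local, shared, self._data(rng),
                                         frozen, cfg)
        for n, p in local.named_parameters():
            np.testing.assert_array_equal(p.data, before[n])
        assert losses and all(np.isfinite(losses))

    def test_partial_freeze_keeps_frozen_stage_bit_identical(
            self, tiny_student_spec, rng):
        local = build_model(tiny_student_spec, seed=0)
        shared = build_model(tiny_student_spec, seed=1)
        before = {n: p.data.copy() for n, p in local.named_parameters()}
        cfg = Stage2Config(batch_size=8, keep_fraction=1.0, epochs=1, lr=0.05)
        stage2_train(local, shared, self._data(rng),
                     frozenset(["layer1", "layer2"]), cfg)
        changed = 0
        for n, p in local.named_parameters():
            if n.startswith(("layer1.", "layer2.")):
                np.testing.assert_array_equal(p.data, before[n])
            elif not np.array_equal(p.data, before[n]):
                changed += 1
        assert changed > 0
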