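"""Composite loss, schedule construction, fine-tuning contracts."""

import numpy as np
import pytest

from psnseg.backbone import build_reference_net
from psnseg.io import CheckpointRef, load_checkpoint
from psnseg.preprocess import PreprocessConfig
from psnseg.training import (
    TrainConfig,
    TrainTestStep,
    composite_loss,
    composite_loss_with_grad,
    fine_tune,
    largest_component,
    psn_adaptive_schedule,
    psn_sequence_schedule,
    pretrain,
    run_schedule,
)


@pytest.fixture()
def ckpt(tmp_path):
    return CheckpointRef(tmp_path / "ckpt_pretrain.npz", "pretrain")


class TestCompositeLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.zeros((6, 6, 6), np.uint8)
        t[2:4, 2:4, 2:4] = 1
        scores = np.zeros((2, 6, 6, 6), np.float32)
        scores[1][t > 0] = 40.0
        scores[0][t == 0] = 40.0
        assert composite_loss(scores, t) < 1e-4

    def test_uniform_scores_ce_is_ln2(self):
        t = (np.random.default_rng(0).random((5, 5, 5)) > 0.5).astype(np.uint8)
        scores = np.zeros((2, 5, 5, 5), np.float32)
        _, _, _, ce = composite_loss_with_grad(scores, t)
        assert ce == pytest.approx(np.log(2.0), abs=1e-12)

    def test_decomposition_into_single_terms(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(2, 6, 6, 6)).astype(np.float32)
        t = (rng.random((6, 6, 6)) > 0.7).astype(np.uint8)
        total, _, dice_term, ce_term = composite_loss_with_grad(scores, t, 0.5, 0.5)
        only_dice = composite_loss_with_grad(scores, t, 1.0, 0.0)[0]
        only_ce = composite_loss_with_grad(scores, t, 0.0, 1.0)[0]
        assert dice_term == pytest.approx(only_dice)
        assert ce_term == pytest.approx(only_ce)
        assert total == pytest.approx(0.5 * only_dice + 0.5 * only_ce)

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            scores = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
            t = (rng.random((4, 4, 4)) > 0.5).astype(np.uint8)
            assert composite_loss(scores, t) >= 0.0

    def test_non_binary_target_rejected(self):
        scores = np.zeros((2, 3, 3, 3), np.float32)
        with pytest.raises(ValueError, match="binary"):
            composite_loss(scores, np.full((3, 3, 3), 0.5))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TrainConfig(dice_weight=0.7, ce_weight=0.5)


class TestSchedules:
    def test_adaptive_five_fractions(self, ckpt):
        steps = psn_adaptive_schedule([1, 2, 3, 4, 5], ckpt)
        got = [(s.train_fractions, s.test_fractions) for s in steps]
        assert got == [
            ((1,), (2, 3, 4, 5)),
            ((1, 2), (3, 4, 5)),
            ((1, 2, 3), (4, 5)),
            ((1, 2, 3, 4), (5,)),
        ]
        assert all(s.init is ckpt for s in steps)

    def test_sequence_five_fractions(self, ckpt):
        steps = psn_sequence_schedule([1, 2, 3, 4, 5], ckpt)
        assert [s.train_fractions for s in steps] == [(1,), (2,), (3,), (4,)]
        assert [s.test_fractions for s in steps] == [(2,), (3,), (4,), (5,)]
        assert steps[0].init is ckpt
        assert all(s.init is None for s in steps[1:])  # chained

    def test_two_fractions_schedules_coincide(self, ckpt):
        a = psn_adaptive_schedule([1, 2], ckpt)
        s = psn_sequence_schedule([1, 2], ckpt)
        assert len(a) == len(s) == 1
        assert a[0].train_fractions == s[0].train_fractions == (1,)
        assert a[0].test_fractions == s[0].test_fractions == (2,)

    def test_single_fraction_empty_schedule(self, ckpt):
        assert psn_adaptive_schedule([1], ckpt) == []
        assert psn_sequence_schedule([1], ckpt) == []

    def test_non_contiguous_rejected(self, ckpt):
        for bad in ([1, 2, 4], [2, 3, 4], [1, 1, 2]):
            with pytest.raises(ValueError):
                psn_adaptive_schedule(bad, ckpt)
            with pytest.raises(ValueError):
                psn_sequence_schedule(bad, ckpt)

    def test_no_test_fraction_in_training_set(self, ckpt):
        for steps in (
            psn_adaptive_schedule(range(1, 8), ckpt),
            psn_sequence_schedule(range(1, 8), ckpt),
        ):
            for s in steps:
                assert max(s.train_fractions) < min(s.test_fractions)

    def test_illegal_step_rejected(self):
        with pytest.raises(ValueError, match="illegal|disjoint"):
            TrainTestStep("p0", (1, 3), (2,))


class TestFineTune:
    @staticmethod
    def _setup(tiny_cohort):
        pre = PreprocessConfig(
            target_spacing_mm=(3.0, 3.0, 3.0), crop_size=(16, 16, 16)
        )
        return pre, tiny_cohort.patient_ids("test")[0]

    def test_zero_epochs_checkpoint_equals_init(self, tiny_cohort, tmp_path):
        pre, pid = self._setup(tiny_cohort)
        cfg = TrainConfig(finetune_epochs=0, seed=1)
        net = build_reference_net(4, 2, seed=1)
        before = {k: v.copy() for k, v in net.parameters().items()}
        step = TrainTestStep(pid, (1,), (2,))
        ref = fine_tune(step, tiny_cohort, net, cfg, pre, tmp_path)
        after, _ = load_checkpoint(ref.path)
        for k in before:
            np.testing.assert_array_equal(after[k], before[k])

    def test_deterministic_replay_identical_checkpoint(self, tiny_cohort, tmp_path):
        pre, pid = self._setup(tiny_cohort)
        cfg = TrainConfig(finetune_epochs=2, patches_per_volume_per_epoch=2, seed=5)
        outs = []
        for run in ("a", "b"):
            net = build_reference_net(4, 2, seed=5)
            step = TrainTestStep(pid, (1,), (2,))
            ref = fine_tune(step, tiny_cohort, net, cfg, pre, tmp_path / run)
            outs.append(ref.path.read_bytes())
        assert outs[0] == outs[1]

    def test_first_step_identical_across_schedules(self, tiny_cohort, tmp_path):
        """Same data + same init: step 1 of the cumulative and the chained
        schedule must produce bit-identical checkpoints in deterministic mode."""
        from psnseg.io import save_checkpoint

        pre, pid = self._setup(tiny_cohort)
        cfg = TrainConfig(finetune_epochs=2, patches_per_volume_per_epoch=2, seed=9)
        net = build_reference_net(4, 2, seed=9)
        pretrain_ref = CheckpointRef(tmp_path / "ckpt_pretrain.npz", "pretrain")
        save_checkpoint(net.parameters(), pretrain_ref)
        blobs = {}
        for stage, schedule in (
            ("adaptive", psn_adaptive_schedule),
            ("sequence", psn_sequence_schedule),
        ):
            steps = schedule([1, 2, 3], pretrain_ref, patient_id=pid)
            model = build_reference_net(4, 2, seed=123)  # init overwritten by ckpt
            run_schedule(
                steps[:1], tiny_cohort, model, cfg, pre, tmp_path / stage, stage=stage
            )
            blobs[stage] = _params_bytes(steps[0].out.path)
        assert blobs["adaptive"] == blobs["sequence"]

    def test_pretrain_loss_log_finite_and_deterministic(self, tiny_cohort, tmp_path):
        import json

        pre, _ = self._setup(tiny_cohort)
        cfg = TrainConfig(pretrain_iterations=10, seed=2)
        params = []
        for run in ("a", "b"):
            net = build_reference_net(4, 2, seed=2)
            ref = pretrain(tiny_cohort, net, cfg, pre, tmp_path / run)
            log = [json.loads(l) for l in open(str(ref.path) + ".log.jsonl")]
            assert len(log) == 10
            assert all(np.isfinite(e["loss"]) for e in log)
            params.append(ref.path.read_bytes())
        assert params[0] == params[1]


def _params_bytes(path):
    params, _ = load_checkpoint(path)
    return b"".join(params[k].tobytes() for k in sorted(params))


class TestLargestComponent:
    def test_keeps_biggest_island(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[1:5, 1:5, 1:5] = 1
        m[8, 8, 8] = 1
        out = largest_component(m)
        assert out.sum() == 64
        assert out[8, 8, 8] == 0

    def test_single_component_unchanged(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[2:5, 2:5, 2:5] = 1
        np.testing.assert_array_equal(largest_component(m), m)
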