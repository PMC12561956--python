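"""Loss, stopping rule and training-loop tests."""

import numpy as np
import pytest

from litemrinet import (LiteMRINet, TrainConfig, nn, evaluate, should_stop,
                        total_loss, train_model)
from litemrinet.metrics import MetricReport
from litemrinet.training import EpochRecord, TrainHistory, cross_entropy


def _report(miou):
    return MetricReport(miou=miou, f1=0.5, oa=0.5, precision=0.5, recall=0.5)


def make_history(mious, losses):
    h = TrainHistory()
    for i, (m, l) in enumerate(zip(mious, losses), start=1):
        h.records.append(EpochRecord(i, 1.0, l, _report(m), i))
    return h


class TestLoss:
    def test_confident_correct_logits_near_zero(self, rng):
        mask = (rng.random((4, 4)) < 0.5).astype(np.int64)
        logits = np.zeros((4, 4, 2), dtype=np.float64)
        logits[mask == 1, 1] = 10.0
        logits[mask == 0, 0] = 10.0
        loss = total_loss(nn.Tensor(logits), mask, [], 0.0)
        assert float(loss.data) <= 1e-3

    def test_uniform_logits_give_ln2_per_pixel(self):
        logits = nn.Tensor(np.zeros((5, 5, 2)))
        mask = np.zeros((5, 5), dtype=np.int64)
        loss = total_loss(logits, mask, [], 0.0)
        assert float(loss.data) == pytest.approx(np.log(2))

    def test_l2_of_single_weight_vector(self):
        w = nn.Parameter(np.array([3.0, 4.0]), penalized=True)
        mask = np.zeros((2, 2), dtype=np.int64)
        logits = np.zeros((2, 2, 2))
        logits[:, :, 0] = 20.0  # perfect background prediction
        loss = total_loss(nn.Tensor(logits), mask, [w], 1.0)
        assert float(loss.data) == pytest.approx(25.0, abs=1e-6)

    def test_decomposition_exact_for_any_logits(self, rng, tiny_model_config):
        model = LiteMRINet(tiny_model_config, seed=0)
        logits = nn.Tensor(rng.normal(size=(16, 16, 2)))
        mask = (rng.random((16, 16)) < 0.2).astype(np.int64)
        lam = 0.37
        with_l2 = float(total_loss(logits, mask, model, lam).data)
        without = float(total_loss(logits, mask, model, 0.0).data)
        sum_sq = sum(float((p.data ** 2).sum()) for p in model.parameters()
                     if p.penalized)
        assert with_l2 - without == pytest.approx(lam * sum_sq, rel=1e-6)

    def test_biases_and_norm_parameters_exempt(self, tiny_model_config):
        model = LiteMRINet(tiny_model_config, seed=0)
        penalized = {n for n, p in model.named_parameters() if p.penalized}
        assert not any(n.endswith(("bias", "gamma", "beta", "embedding"))
                       for n in penalized)
        assert any(n.endswith("weight") for n in penalized)

    def test_nonfinite_logits_raise_naming_batch(self):
        bad = np.zeros((2, 3, 3, 2))
        bad[1] = np.nan
        with pytest.raises(FloatingPointError, match="1"):
            cross_entropy(nn.Tensor(bad), np.zeros((2, 3, 3), dtype=np.int64))


class TestShouldStop:
    def test_guard_blocks_before_100_epochs(self):
        h = make_history([0.5] * 50, list(np.linspace(1, 0.5, 50)))
        assert not should_stop(h, 50)

    def test_metric_patience_triggers(self):
        # metric last improved at epoch 109, loss still decreasing
        mious = list(np.linspace(0.1, 0.8, 109)) + [0.8] * 11
        losses = list(np.linspace(2.0, 0.1, 120))
        h = make_history(mious, losses)
        assert should_stop(h, 120)
        assert not should_stop(h, 118)  # only 9 epochs since improvement

    def test_loss_patience_triggers(self):
        # metric improved at 115, loss flat since epoch 99
        mious = list(np.linspace(0.1, 0.7, 115)) + [0.7] * 5
        losses = list(np.linspace(2.0, 0.2, 99)) + [0.2] * 21
        h = make_history(mious, losses)
        assert should_stop(h, 120)

    def test_both_improving_continues(self):
        h = make_history(list(np.linspace(0.1, 0.9, 150)),
                         list(np.linspace(2.0, 0.1, 150)))
        assert not should_stop(h, 150)

    def test_ties_are_not_improvements(self):
        mious = [0.5] * 120  # never strictly improves after epoch 1
        losses = list(np.linspace(2.0, 0.1, 120))
        h = make_history(mious, losses)
        assert should_stop(h, 120)

    def test_purity(self):
        h = make_history([0.5] * 120, [1.0] * 120)
        assert should_stop(h, 120) == should_stop(h, 120)


class TestTrainLoop:
    def test_single_epoch_cap(self, tiny_model_config, tiny_dataset):
        tcfg = TrainConfig(max_epochs=1, batch_size=2, seed=0)
        history, _ = train_model(tiny_model_config, tcfg,
                                 tiny_dataset[:4], tiny_dataset[4:])
        assert len(history.records) == 1

    def test_seeded_determinism_of_first_epoch(self, tiny_model_config,
                                               tiny_dataset):
        losses = []
        for _ in range(2):
            tcfg = TrainConfig(max_epochs=1, batch_size=2, seed=11)
            history, _ = train_model(tiny_model_config, tcfg,
                                     tiny_dataset[:4], tiny_dataset[4:])
            losses.append(history.records[0].train_loss)
        assert losses[0] == losses[1]

    def test_run_directory_artifacts(self, tmp_path, tiny_model_config,
                                     tiny_dataset):
        tcfg = TrainConfig(max_epochs=2, batch_size=2, seed=0)
        train_model(tiny_model_config, tcfg, tiny_dataset[:4], tiny_dataset[4:],
                    run_dir=tmp_path)
        assert (tmp_path / "model_config.yaml").exists()
        assert (tmp_path / "history.csv").exists()
        assert (tmp_path / "best_checkpoint.npz").exists()
        assert (tmp_path / "report.txt").exists()

    def test_empty_dataset_rejected(self, tiny_model_config):
        with pytest.raises(ValueError):
            train_model(tiny_model_config, TrainConfig(), [], [])


class TestEvaluate:
    def test_background_only_model_has_zero_recall(self, tiny_model_config,
                                                   tiny_dataset):
        model = LiteMRINet(tiny_model_config, seed=0)
        # force channel-0 dominance through the head bias
        model.decoder.head.bias.data[:] = (50.0, -50.0)
        report = evaluate(model, tiny_dataset)
        assert report.recall == 0.0
        assert "recall" in report.degenerate or report.recall == 0.0

    def test_evaluate_twice_identical(self, tiny_model_config, tiny_dataset):
        model = LiteMRINet(tiny_model_config, seed=0)
        assert evaluate(model, tiny_dataset) == evaluate(model, tiny_dataset)

    def test_per_image_aggregate_differs_from_global(self, tiny_model_config,
                                                     tiny_dataset):
        model = LiteMRINet(tiny_model_config, seed=0)
        g = evaluate(model, tiny_dataset, aggregate="global")
        p = evaluate(model, tiny_dataset, aggregate="per_image")
        assert 0 <= p.miou <= 1 and 0 <= g.miou <= 1

    def test_missing_mask_skipped_with_count(self, tmp_path, tiny_model_config,
                                             tiny_synth_config):
        from litemrinet import generate_dataset
        from litemrinet.training import evaluate_paths
        generate_dataset(3, tiny_synth_config, seed=1, out_dir=tmp_path)
        (tmp_path / "mask_0001.png").unlink()
        pairs = [(tmp_path / f"img_{i:04d}.png", tmp_path / f"mask_{i:04d}.png")
                 for i in range(3)]
        model = LiteMRINet(tiny_model_config, seed=0)
        report, skipped = evaluate_paths(model, pairs, target_size=16)
        assert skipped == 1
        assert 0 <= report.oa <= 1
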