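"""Training protocol: loss, optimizer settings, epoch loop and stopping rule.

The loss is two-class softmax cross-entropy over the 2-channel head
(mathematically the binary cross-entropy of the tumor-class probability)
plus an L2 penalty ``lambda * sum(w^2)`` over convolution / attention /
feed-forward kernels (biases and normalization parameters exempt).

Training uses Adam with learning rate 1e-4 and a numerical-stability
epsilon of 3e-3, batch size 4, at most 300 epochs, evaluating on the
test set after every epoch.  Training stops when either the test mIoU
has not improved for 10 consecutive epochs or the test loss has not
decreased for 20 consecutive epochs — but only once more than 100
epochs have run.  Improvement is strict.
"""

from __future__ import annotations

import copy
import csv
import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .metrics import MetricReport, accumulate, compute_metrics, confusion_counts
from .model import LiteMRINet, ModelConfig, load_checkpoint, save_checkpoint
from .synthetic import SamplePair, load_pair

__all__ = ["TrainConfig", "EpochRecord", "TrainHistory", "total_loss",
           "cross_entropy", "train_model", "should_stop", "evaluate",
           "evaluate_paths"]

logger = logging.getLogger("litemrinet")


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    adam_eps: float = 3e-3
    batch_size: int = 4
    max_epochs: int = 300
    min_epochs_before_stop: int = 100
    metric_patience: int = 10
    loss_patience: int = 20
    l2_coefficient: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.adam_eps <= 0 or self.batch_size <= 0:
            raise ValueError("rates and batch size must be positive")
        if self.l2_coefficient < 0:
            raise ValueError("l2_coefficient must be nonnegative")
        if (self.max_epochs > self.min_epochs_before_stop
                and max(self.metric_patience, self.loss_patience) >= self.max_epochs):
            # short guarded runs (max_epochs <= guard) never consult patience
            raise ValueError("patiences must be smaller than max_epochs")


@dataclasses.dataclass
class EpochRecord:
    epoch: int              # 1-based
    train_loss: float
    test_loss: float
    test_metrics: MetricReport
    steps: int              # cumulative gradient steps


@dataclasses.dataclass
class TrainHistory:
    records: list[EpochRecord] = dataclasses.field(default_factory=list)

    @property
    def best_metric_epoch(self) -> int | None:
        """Epoch of the last *strict* improvement in test mIoU."""
        best, at = -np.inf, None
        for r in self.records:
            if r.test_metrics.miou > best:
                best, at = r.test_metrics.miou, r.epoch
        return at

    @property
    def best_loss_epoch(self) -> int | None:
        """Epoch of the last strict decrease in test loss."""
        best, at = np.inf, None
        for r in self.records:
            if r.test_loss < best:
                best, at = r.test_loss, r.epoch
        return at


def cross_entropy(logits: nn.Tensor, mask: np.ndarray) -> nn.Tensor:
    """Mean per-pixel softmax cross-entropy against an integer mask."""
    mask = np.asarray(mask)
    if logits.shape[:-1] != mask.shape:
        raise ValueError(f"logits {logits.shape} do not match mask {mask.shape}")
    k = logits.shape[-1]
    if not np.isfinite(logits.data).all():
        bad = np.argwhere(~np.isfinite(logits.data).reshape(logits.shape[0], -1).all(axis=1))
        raise FloatingPointError(f"non-finite logits in batch index {bad.ravel().tolist()}")
    shifted = logits - logits.data.max(axis=-1, keepdims=True)
    lse = shifted.exp().sum(axis=-1, keepdims=True).log()
    logp = shifted - lse
    onehot = np.eye(k, dtype=logits.dtype)[mask.astype(np.int64)]
    return -(logp * onehot).sum() * (1.0 / mask.size)


def l2_penalty(params) -> nn.Tensor:
    """Sum of squares over penalized weights (kernels only)."""
    if isinstance(params, nn.Module):
        params = params.parameters()
    terms = [(p**2).sum() for p in params
             if not isinstance(p, nn.Parameter) or p.penalized]
    total = None
    for t in terms:
        total = t if total is None else total + t
    return total if total is not None else nn.Tensor(np.float32(0.0))


def total_loss(logits: nn.Tensor, mask: np.ndarray, params,
               l2_coefficient: float = 0.0) -> nn.Tensor:
    """Cross-entropy plus ``l2_coefficient * sum(w^2)`` over penalized weights."""
    if l2_coefficient < 0:
        raise ValueError("l2_coefficient must be nonnegative")
    ce = cross_entropy(logits, mask)
    if l2_coefficient == 0:
        return ce
    return ce + l2_coefficient * l2_penalty(params)


def should_stop(history: TrainHistory, epoch: int,
                cfg: TrainConfig | None = None) -> bool:
    """The dual stopping rule.

    True iff ``epoch`` exceeds the 100-epoch guard AND (the monitored
    test mIoU has gone ``metric_patience`` consecutive epochs without
    strict improvement OR the test loss has gone ``loss_patience``
    epochs without a strict decrease).
    """
    cfg = cfg or TrainConfig()
    if epoch <= cfg.min_epochs_before_stop:
        return False
    if not history.records:
        return False
    bm = history.best_metric_epoch
    bl = history.best_loss_epoch
    metric_stall = bm is not None and (epoch - bm) >= cfg.metric_patience
    loss_stall = bl is not None and (epoch - bl) >= cfg.loss_patience
    return metric_stall or loss_stall


def _stack(dataset: Sequence[SamplePair]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([p.image for p in dataset]).astype(np.float32)
    masks = np.stack([p.mask for p in dataset]).astype(np.int64)
    return images, masks


def _test_pass(model: LiteMRINet, images, masks, batch_size, l2, params):
    """Loss + metrics over a dataset in eval mode, global accumulation."""
    model.eval()
    losses, counts = [], []
    for i in range(0, len(images), batch_size):
        xb, yb = images[i:i + batch_size], masks[i:i + batch_size]
        with nn.autograd.no_grad():
            logits = model(xb)
        losses.append(float(total_loss(logits, yb, params, l2).data) * len(xb))
        pred = np.argmax(logits.data, axis=-1)
        for p, t in zip(pred, yb):
            counts.append(confusion_counts(p.astype(np.uint8), t.astype(np.uint8)))
    return sum(losses) / len(images), compute_metrics(accumulate(counts))


def train_model(config: ModelConfig | LiteMRINet, tcfg: TrainConfig,
                train_set: Sequence[SamplePair], test_set: Sequence[SamplePair],
                run_dir=None, max_steps: int | None = None,
                ) -> tuple[TrainHistory, LiteMRINet]:
    """Run the epoch loop; returns the history and the best-mIoU model.

    ``max_steps`` bounds the total number of gradient steps (for sanity
    runs); ``run_dir`` if given receives a config snapshot, a per-epoch
    metrics CSV, the best checkpoint and a final report.
    """
    if not len(train_set) or not len(test_set):
        raise ValueError("datasets must be non-empty")
    model = config if isinstance(config, LiteMRINet) else LiteMRINet(config, seed=tcfg.seed)
    params = list(model.parameters())
    opt = nn.Adam(params, lr=tcfg.learning_rate, eps=tcfg.adam_eps)
    rng = np.random.default_rng(tcfg.seed)

    run = Path(run_dir) if run_dir is not None else None
    csv_writer = csv_fh = None
    if run is not None:
        run.mkdir(parents=True, exist_ok=True)
        model.config.to_file(run / "model_config.yaml")
        with open(run / "train_config.yaml", "w") as fh:
            import yaml
            yaml.safe_dump(dataclasses.asdict(tcfg), fh, sort_keys=False)
        csv_fh = open(run / "history.csv", "w", newline="")
        csv_writer = csv.writer(csv_fh)
        csv_writer.writerow(["epoch", "train_loss", "test_loss", "test_miou",
                             "test_f1", "test_oa", "steps"])

    xtr, ytr = _stack(train_set)
    xte, yte = _stack(test_set)

    history = TrainHistory()
    best_miou, best_state = -np.inf, None
    steps = 0
    try:
        for epoch in range(1, tcfg.max_epochs + 1):
            model.train()
            order = rng.permutation(len(xtr))
            epoch_losses = []
            for i in range(0, len(order), tcfg.batch_size):
                idx = order[i:i + tcfg.batch_size]
                logits = model(xtr[idx])
                loss = total_loss(logits, ytr[idx], params, tcfg.l2_coefficient)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged: non-finite loss at epoch {epoch}, step {steps}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                steps += 1
                epoch_losses.append(float(loss.data))
                del logits, loss  # free the graph before the next forward
                if max_steps is not None and steps >= max_steps:
                    break

            test_loss, report = _test_pass(model, xte, yte, tcfg.batch_size,
                                           tcfg.l2_coefficient, params)
            rec = EpochRecord(epoch, float(np.mean(epoch_losses)), test_loss,
                              report, steps)
            history.records.append(rec)
            logger.info("epoch %d: train_loss=%.4f test_loss=%.4f test_miou=%.4f",
                        epoch, rec.train_loss, rec.test_loss, report.miou)
            if csv_writer is not None:
                p = report.as_percentages()
                csv_writer.writerow([epoch, f"{rec.train_loss:.6f}",
                                     f"{rec.test_loss:.6f}", f"{p['miou']:.2f}",
                                     f"{p['f1']:.2f}", f"{p['oa']:.2f}", steps])
                csv_fh.flush()

            if report.miou > best_miou:
                best_miou = report.miou
                best_state = copy.deepcopy(model.state_dict())

            if max_steps is not None and steps >= max_steps:
                break
            if should_stop(history, epoch, tcfg):
                logger.info("early stop at epoch %d", epoch)
                break
    finally:
        if csv_fh is not None:
            csv_fh.close()

    if best_state is not None:
        model.load_state_dict(best_state)
    if run is not None:
        save_checkpoint(model, run / "best_checkpoint.npz")
        from .metrics import format_report
        last = history.records[-1].test_metrics
        (run / "report.txt").write_text(format_report({model.config.variant: last}) + "\n")
    return history, model


def evaluate(model, dataset: Sequence[SamplePair], batch_size: int = 4,
             aggregate: str = "global") -> MetricReport:
    """Metrics of a model (or checkpoint path) over image/mask pairs.

    ``aggregate="global"`` pools pixel counts over the whole dataset
    (default); ``"per_image"`` averages the per-image metric values.
    """
    if not isinstance(model, LiteMRINet):
        model = load_checkpoint(model)
    if aggregate not in ("global", "per_image"):
        raise ValueError("aggregate must be 'global' or 'per_image'")
    images, masks = _stack(dataset)
    counts = []
    for i in range(0, len(images), batch_size):
        pred = model.predict(images[i:i + batch_size])
        for p, t in zip(pred, masks[i:i + batch_size]):
            counts.append(confusion_counts(p, t.astype(np.uint8)))
    if aggregate == "global":
        return compute_metrics(accumulate(counts))
    reports = [compute_metrics(c) for c in counts]
    return MetricReport(
        miou=float(np.mean([r.miou for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        oa=float(np.mean([r.oa for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        degenerate=tuple(sorted({d for r in reports for d in r.degenerate})),
    )


def evaluate_paths(model, pairs: Sequence[tuple], target_size: int | None = None,
                   batch_size: int = 4) -> tuple[MetricReport, int]:
    """Evaluate over (image_path, mask_path) pairs loaded from disk.

    Pairs whose mask file is missing are listed in a warning and
    skipped; returns the report and the number skipped.
    """
    if not isinstance(model, LiteMRINet):
        model = load_checkpoint(model)
    size = target_size or model.config.input_size
    dataset, skipped = [], 0
    for image_path, mask_path in pairs:
        if not Path(mask_path).exists():
            logger.warning("missing mask for %s: skipped", image_path)
            skipped += 1
            continue
        dataset.append(load_pair(image_path, mask_path, target_size=size))
    if not dataset:
        raise ValueError("no evaluable pairs (all masks missing?)")
    return evaluate(model, dataset, batch_size=batch_size), skipped
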