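"""Training loop, poly learning-rate schedule, cross-validation splits and
the ablation driver.

Optimization is plain SGD with momentum and decoupled-from-BN weight
decay (decay on convolution weights only by default) on the soft-Dice
loss, with the learning rate following the polynomial rule

    lr(iter) = initial_lr * (1 - iter / max_iter) ** power.

The loop is iteration-based: an infinite sampler reshuffles the training
set each epoch and batches are drawn until ``max_iter`` optimizer steps
have run. Validation mean DSC is evaluated periodically and the best
checkpoint is kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import objectives, preprocess
from .autodiff import Tensor
from .network import DMFFNet, NetworkConfig, build_network, count_parameters
from .preprocess import AugmentParams, downsample2x_area
from .types import BinaryMask, GrayImage

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings; defaults are the reference recipe."""

    optimizer: str = "sgd"
    initial_lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0001
    lr_power: float = 0.9
    batch_size: int = 8
    max_iter: int = 6500
    seed: int = 0
    device: str = "cpu"
    eval_every: int = 50
    decay_bn: bool = False   # apply weight decay to BN affine parameters too

    def __post_init__(self):
        if self.optimizer != "sgd":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        for fld in ("initial_lr", "batch_size"):
            if getattr(self, fld) <= 0:
                raise ValueError(f"{fld} must be positive")
        for fld in ("momentum", "weight_decay", "lr_power", "max_iter",
                    "eval_every"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{fld} must be non-negative")


@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold: disjoint train/val ids plus the shared
    held-out test ids (identical across folds)."""

    train_ids: tuple
    val_ids: tuple
    test_ids: tuple
    fold_index: int

    def __post_init__(self):
        tr, va, te = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if tr & va or tr & te or va & te:
            raise ValueError("fold id lists overlap")
        if not 0 <= self.fold_index <= 4:
            raise ValueError(f"fold_index must be 0-4, got {self.fold_index}")


def poly_lr(iter_num: int, config: TrainConfig) -> float:
    """Polynomial decay: initial_lr * (1 - iter/max_iter) ** power."""
    if iter_num < 0:
        raise ValueError(f"iter_num must be >= 0, got {iter_num}")
    if iter_num > config.max_iter:
        warnings.warn(
            f"iter_num {iter_num} beyond max_iter {config.max_iter}; "
            f"learning rate clamped to 0", stacklevel=2)
        return 0.0
    frac = 1.0 - iter_num / config.max_iter
    return config.initial_lr * frac ** config.lr_power


def make_folds(ids, seed: int) -> list[FoldSplit]:
    """Deterministic 80/20 split, then 5-fold 4:1 cross-validation on the
    80% pool; the five validation sets partition the pool."""
    ids = list(ids)
    if len(ids) < 10:
        raise ValueError(f"need at least 10 ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_test = int(round(len(ids) / 5.0))
    test = tuple(order[:n_test])
    pool = order[n_test:]
    chunks = np.array_split(np.arange(len(pool)), 5)
    folds = []
    for f, chunk in enumerate(chunks):
        val = tuple(pool[i] for i in chunk)
        train = tuple(x for x in pool if x not in set(val))
        folds.append(FoldSplit(train_ids=train, val_ids=val, test_ids=test,
                               fold_index=f))
    return folds


class SGD:
    """SGD with momentum; weight decay only on parameters flagged for it."""

    def __init__(self, params, momentum: float, weight_decay: float,
                 decay_bn: bool = False):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.decay_bn = decay_bn
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and (p.decay or self.decay_bn):
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= lr * v


def _to_batch(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (image, target) pairs into high/low/target batch arrays.

    Targets may be binary masks or mixup's soft masks.
    """
    highs, lows, targets = [], [], []
    for img, target in samples:
        px = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
        t = target.pixels if isinstance(target, BinaryMask) else np.asarray(target)
        highs.append(px[None])
        lows.append(downsample2x_area(px)[None])
        targets.append(t.astype(float)[None])
    return np.stack(highs), np.stack(lows), np.stack(targets)


def evaluate_model(model: DMFFNet, data, threshold: float = 0.5
                   ) -> objectives.MetricReport:
    """Eval-mode metrics of a model over (image, mask) pairs."""
    per = []
    for img, msk in data:
        high, low, _ = _to_batch([(img, msk)])
        _, hard = model.predict(high, low, threshold=threshold)
        m = msk.pixels if isinstance(msk, BinaryMask) else np.asarray(msk)
        per.append(objectives.metrics(objectives.confusion(hard[0, 0], m)))
    return objectives.MetricReport.from_per_image(per)


def _mean_dsc(model: DMFFNet, data) -> float:
    report = evaluate_model(model, data)
    return report.aggregate["DSC"][0] / 100.0 if "DSC" in report.aggregate else 0.0


def train(model: DMFFNet, data, train_config: TrainConfig,
          augment_params: AugmentParams | None = None,
          val_data=None, use_mixup: bool = False
          ) -> tuple[DMFFNet, pd.DataFrame]:
    """Run ``max_iter`` SGD steps on the soft-Dice loss; returns the model
    restored to its best-validation-DSC checkpoint plus the history."""
    if not data:
        raise ValueError("training data is empty")
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), cfg.momentum, cfg.weight_decay,
              decay_bn=cfg.decay_bn)
    history: list[dict] = []
    best = {"dsc": -1.0, "state": model.state_dict(), "iter": 0}

    def batches():
        while True:
            for idx in rng.permutation(len(data)):
                yield data[idx]

    stream = batches()
    model.train()
    for it in range(cfg.max_iter):
        samples = []
        for _ in range(cfg.batch_size):
            img, msk = next(stream)
            if augment_params is not None:
                img, msk = preprocess.augment(img, msk, augment_params, rng)
            samples.append((img, msk))
        if use_mixup and augment_params is not None and len(samples) >= 2:
            mixed = []
            for a, b in zip(samples[0::2], samples[1::2]):
                img, soft = preprocess.mixup(a, b, alpha=augment_params.mixup_alpha,
                                             rng=rng)
                mixed.append((img, soft))
            samples = mixed
        high, low, target = _to_batch(samples)
        lr = poly_lr(it, cfg)
        pred = model.forward(high, low)
        loss = objectives.dice_loss_graph(pred, target)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise FloatingPointError(
                f"non-finite loss {loss_val} at iteration {it}; lr={lr:.3g}"
            )
        model.zero_grad()
        loss.backward()
        opt.step(lr)
        record = {"iter": it, "loss": loss_val, "lr": lr, "val_dsc": np.nan}
        if val_data and cfg.eval_every and (it + 1) % cfg.eval_every == 0:
            dsc = _mean_dsc(model, val_data)
            model.train()
            record["val_dsc"] = dsc
            if dsc > best["dsc"]:
                best = {"dsc": dsc, "state": model.state_dict(), "iter": it}
            log.info("iter %d loss %.4f val DSC %.4f", it, loss_val, dsc)
        history.append(record)
    if val_data and best["dsc"] >= 0.0 and cfg.max_iter > 0:
        model.load_state_dict(best["state"])
    model.eval()
    return model, pd.DataFrame(history, columns=["iter", "loss", "lr", "val_dsc"])


@dataclass
class AblationRow:
    name: str
    params_m: float
    report: objectives.MetricReport | None


def run_ablation(grid: dict[str, NetworkConfig], data, train_config: TrainConfig,
                 val_data=None, test_data=None,
                 augment_params: AugmentParams | None = None) -> pd.DataFrame:
    """Train and evaluate each configuration variant under one shared data
    split and seed; returns a table of metrics plus parameter counts."""
    rows = []
    for name, net_cfg in grid.items():
        model = build_network(net_cfg)
        pc = count_parameters(model)
        model, _ = train(model, data, train_config,
                         augment_params=augment_params, val_data=val_data)
        eval_data = test_data if test_data is not None else data
        report = evaluate_model(model, eval_data)
        row = {"name": name, "params_M": pc.millions}
        for metric in objectives.METRIC_NAMES:
            if metric in report.aggregate:
                mean, std = report.aggregate[metric]
                row[metric] = mean
                row[f"{metric}_std"] = std
        rows.append(row)
    columns = ["name", "params_M"] + [
        c for m in objectives.METRIC_NAMES for c in (m, f"{m}_std")
    ]
    return pd.DataFrame(rows, columns=columns if rows else ["name", "params_M"])
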