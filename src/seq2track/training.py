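"""Training protocol and evaluation metrics.

The objective is the Poisson negative log-likelihood of per-bin counts,
mean over bins and tracks, with the data-only ln(y!) term omitted (it does
not affect optimization, so reported losses are comparable only within
this toolkit). Optimization is AdamW at batch size 1 with a per-iteration
linear warmup from 0 to the peak learning rate over the first epoch and a
linear decay back to 0 over the remaining epochs.

Evaluation pools all bins of all examples into one vector per track and
reports the Pearson correlation coefficient, averaged over tracks;
constant tracks are skipped with a warning.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import TrainingConfig
from .data import TrackDataset
from .errors import (
    ConfigurationError,
    DegenerateMetricError,
    EvaluationError,
    ShapeError,
)
from .model import Model

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-8  # floor inside logarithms; rates are positive by softplus


# ---------------------------------------------------------------------------
# metrics and loss
# ---------------------------------------------------------------------------

def poisson_nll(rates: np.ndarray, targets: np.ndarray) -> float:
    """Mean Poisson negative log-likelihood, up to the y-only constant.

    ``mean(lambda - y * ln(lambda))`` over all elements. ``rates`` must be
    strictly positive, ``targets`` non-negative, shapes equal.
    """
    lam = np.asarray(rates, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if lam.shape != y.shape:
        raise ShapeError(f"shape mismatch: rates {lam.shape} vs targets {y.shape}")
    if lam.size == 0:
        raise ShapeError("empty input")
    if np.any(lam <= 0):
        raise ValueError("rates must be strictly positive")
    if np.any(y < 0):
        raise ValueError("targets must be non-negative")
    return float(np.mean(lam - y * np.log(np.maximum(lam, _LOG_FLOOR))))


def poisson_nll_grad(rates: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """d(mean NLL)/d(rates); same floor as the loss."""
    lam = np.asarray(rates, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    return (1.0 - y / np.maximum(lam, _LOG_FLOOR)) / lam.size


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation, Avg((x-x̄)(y-ȳ)) / sqrt(Var[x]·Var[y]).

    Population moments are used; the normalization cancels, so sample
    versus population moments give the same value.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ShapeError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise DegenerateMetricError("need at least 2 points")
    xm, ym = x - x.mean(), y - y.mean()
    vx, vy = np.mean(xm ** 2), np.mean(ym ** 2)
    if vx == 0.0 or vy == 0.0:
        raise DegenerateMetricError("constant input vector")
    r = float(np.mean(xm * ym) / math.sqrt(vx * vy))
    return max(-1.0, min(1.0, r))


def lr_at(step: int, steps_per_epoch: int, cfg: TrainingConfig) -> float:
    """Learning rate at a global iteration index.

    Piecewise linear: 0 at step 0, ``peak_lr`` at the end of warmup,
    0 at the final step (``epochs * steps_per_epoch``).
    """
    total = cfg.epochs * steps_per_epoch
    warm = cfg.warmup_epochs * steps_per_epoch
    if not 0 <= step <= total:
        raise ValueError(f"step {step} outside [0, {total}]")
    if step <= warm:
        return cfg.peak_lr * (step / warm) if warm > 0 else cfg.peak_lr
    return cfg.peak_lr * (total - step) / (total - warm)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay (applied to all trainable params)."""

    def __init__(self, params, weight_decay: float = 0.0,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= lr * self.wd * p.value
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clip_gradients(params, max_norm: float) -> float:
    total = math.sqrt(sum(float(np.sum(p.grad ** 2)) for p in params if p.trainable))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.trainable:
                p.grad *= scale
    return total


# ---------------------------------------------------------------------------
# history / report containers
# ---------------------------------------------------------------------------

@dataclass
class EpochRecord:
    epoch: int
    mean_loss: float
    eval_avg_pearson: float
    eval_per_track: List[float]
    lr_end: float
    seconds: float


@dataclass
class TrainingHistory:
    records: List[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"epoch": r.epoch, "mean_loss": r.mean_loss,
             "eval_avg_pearson": r.eval_avg_pearson, "lr_end": r.lr_end,
             "seconds": r.seconds}
            for r in self.records
        ])


@dataclass
class EvaluationReport:
    """Per-track pooled Pearson correlations and their mean."""

    per_track: List[float]          # NaN for skipped (constant) tracks
    average: float
    n_bins_pooled: int
    skipped_tracks: List[int]
    track_indices: List[int]

    def value_for(self, track: int) -> float:
        return self.per_track[self.track_indices.index(track)]


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _batch_indices(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train(model: Model, dataset: TrackDataset, cfg: TrainingConfig,
          eval_dataset: Optional[TrackDataset] = None,
          eval_tracks: Optional[Sequence[int]] = None,
          eval_every: int = 1,
          log_every: int = 0) -> Tuple[Model, TrainingHistory]:
    """Train ``model`` on ``dataset`` under the configured protocol.

    One optimizer step per batch (batch size 1 by default), learning rate
    from :func:`lr_at`, per-epoch shuffling seeded from
    ``(shuffle_seed, epoch)``. In ``single_track`` mode the loss uses only
    ``cfg.track_index``. Evaluation runs on ``eval_dataset`` when given,
    otherwise on the training set, every ``eval_every`` epochs and always
    after the final epoch; skipped epochs record NaN.
    """
    if len(dataset) == 0:
        raise ConfigurationError("dataset is empty")
    if dataset.bins != model.config.output_bins:
        raise ShapeError(
            f"dataset bins ({dataset.bins}) != model output_bins "
            f"({model.config.output_bins})")
    if dataset.num_tracks != model.config.num_tracks:
        raise ShapeError(
            f"dataset tracks ({dataset.num_tracks}) != model head tracks "
            f"({model.config.num_tracks})")
    if cfg.mode == "single_track":
        if cfg.track_index is None or not 0 <= cfg.track_index < dataset.num_tracks:
            raise ConfigurationError(
                f"single_track mode needs a valid track_index, got "
                f"{cfg.track_index}")

    history = TrainingHistory()
    if cfg.epochs == 0:
        return model, history

    n = len(dataset)
    steps_per_epoch = math.ceil(n / cfg.batch_size)
    opt = AdamW(model.parameters(), weight_decay=cfg.weight_decay)
    gstep = 0
    eval_on = eval_dataset if eval_dataset is not None else dataset

    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        rng = np.random.default_rng([cfg.shuffle_seed, epoch])
        losses = []
        for batch in _batch_indices(n, cfg.batch_size, rng):
            opt.zero_grad()
            batch_loss = 0.0
            for i in batch:
                x = dataset.one_hot(int(i))
                y = dataset.targets[int(i)]
                rates = model.forward_one(x, train=True, rng=rng)
                if cfg.mode == "single_track":
                    j = cfg.track_index
                    loss = poisson_nll(rates[:, j:j + 1], y[:, j:j + 1])
                    d = np.zeros_like(rates)
                    d[:, j:j + 1] = poisson_nll_grad(rates[:, j:j + 1], y[:, j:j + 1])
                else:
                    loss = poisson_nll(rates, y)
                    d = poisson_nll_grad(rates, y)
                if not math.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, step {gstep}: {loss}")
                model.backward(d / len(batch))
                batch_loss += loss / len(batch)
            losses.append(batch_loss)
            if cfg.grad_clip:
                clip_gradients(opt.params, cfg.grad_clip)
            gstep += 1
            lr = lr_at(gstep, steps_per_epoch, cfg)
            opt.step(lr)
            if log_every and gstep % log_every == 0:
                logger.info("epoch %d step %d loss %.5f lr %.3e",
                            epoch, gstep, batch_loss, lr)
        if (epoch + 1) % eval_every == 0 or epoch == cfg.epochs - 1:
            report = evaluate(model, eval_on, tracks=eval_tracks)
            avg, per_track = report.average, report.per_track
        else:
            avg, per_track = float("nan"), []
        history.records.append(EpochRecord(
            epoch=epoch,
            mean_loss=float(np.mean(losses)),
            eval_avg_pearson=avg,
            eval_per_track=per_track,
            lr_end=lr,
            seconds=time.perf_counter() - t0,
        ))
    return model, history


def evaluate(model: Model, dataset: TrackDataset,
             tracks: Optional[Sequence[int]] = None) -> EvaluationReport:
    """Pooled per-track Pearson correlation between predictions and targets.

    All bins of all examples are concatenated into one prediction vector
    and one target vector per track before the correlation is taken
    (pooled convention). Tracks where either vector is constant are
    skipped with a warning and excluded from the average.
    """
    if len(dataset) == 0:
        raise EvaluationError("dataset is empty")
    track_idx = list(tracks) if tracks is not None else list(range(dataset.num_tracks))
    preds = np.empty((len(dataset), dataset.bins, len(track_idx)))
    targs = dataset.targets[:, :, track_idx]
    for i in range(len(dataset)):
        preds[i] = model.forward_one(dataset.one_hot(i))[:, track_idx]

    per_track: List[float] = []
    skipped: List[int] = []
    for col, j in enumerate(track_idx):
        try:
            per_track.append(pearson(preds[:, :, col].ravel(), targs[:, :, col].ravel()))
        except DegenerateMetricError:
            logger.warning("track %d constant; skipped in evaluation", j)
            per_track.append(float("nan"))
            skipped.append(j)
    valid = [v for v in per_track if not math.isnan(v)]
    if not valid:
        raise EvaluationError("all tracks constant; no correlation defined")
    return EvaluationReport(
        per_track=per_track,
        average=float(np.mean(valid)),
        n_bins_pooled=len(dataset) * dataset.bins,
        skipped_tracks=skipped,
        track_indices=track_idx,
    )
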