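"""End-to-end training with subject-disjoint splits and auROC early stopping.

Per epoch, triplets are resampled under the configured negative-sampling
strategy and optimized with Adam (learning rate 1e-4, batch size 16 by
default).  After every epoch the validation auROC of the inference-realistic
negative types (DSDA and DSSA) is monitored; training stops when none of the
monitored scores has improved for ``patience`` consecutive epochs, and the
weights of the epoch with the best average monitored auROC are returned.

Splits are three-way by subject (train / validation / test) so that early
stopping and final scoring use different unseen subjects; a two-way split
can be expressed by passing an explicit :class:`Split` whose validation and
test partitions coincide.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from autograd import value_and_grad

from .core_io import LabeledClipPair, Manifest
from .encoders import ArchConfig, ThreeStreamNet, build_model
from .evaluation import auroc_by_negative_type, clip_embeddings, scenario_experiment
from .losses import LossConfig, batch_loss
from .preprocess import AugConfig, augment
from .triplets import STRATEGIES, NegativeType, StrategyMixture, build_epoch

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Split:
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                inter = parts[i] & parts[j]
                if inter:
                    raise ValueError(f"subjects appear in two partitions: {sorted(inter)}")
        if not self.train:
            raise ValueError("training partition is empty")


def split_by_subject(
    source: Manifest | Sequence[LabeledClipPair] | Sequence[str],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    explicit: tuple[Sequence[str], Sequence[str], Sequence[str]] | None = None,
    seed: int = 0,
) -> Split:
    """Partition subjects into disjoint train/val/test sets.

    Either by explicit ID lists, or by seeded shuffle and the given ratios
    (each non-zero ratio receives at least one subject).
    """
    if explicit is not None:
        return Split(tuple(explicit[0]), tuple(explicit[1]), tuple(explicit[2]))
    if isinstance(source, Manifest):
        subjects = source.subjects
    elif source and isinstance(source[0], LabeledClipPair):
        subjects = sorted({c.meta.subject_id for c in source})
    else:
        subjects = sorted(source)
    n_parts = sum(r > 0 for r in ratios)
    if len(subjects) < n_parts:
        raise ValueError(f"{len(subjects)} subjects cannot fill {n_parts} partitions")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    n = len(order)
    n_train = max(1, int(round(ratios[0] * n))) if ratios[0] > 0 else 0
    n_val = max(1, int(round(ratios[1] * n))) if ratios[1] > 0 else 0
    n_train = min(n_train, n - (n_parts - 1))
    if ratios[2] > 0:
        n_val = min(n_val, n - n_train - 1)
    return Split(
        tuple(order[:n_train]),
        tuple(order[n_train : n_train + n_val]),
        tuple(order[n_train + n_val :]),
    )


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 16
    patience: int = 50  # epochs without any monitored-auROC improvement
    max_epochs: int = 200
    strategy: str = "easy_hard"
    loss: LossConfig = field(default_factory=LossConfig)
    arch: ArchConfig = field(default_factory=ArchConfig)
    seed: int = 0
    split: Split | None = None  # None: seeded 0.6/0.2/0.2 subject split
    anchors_per_epoch: int | None = None  # subsample anchors (None = all)
    aug: AugConfig | None = None  # silhouette augmentation (None = off)
    monitor: tuple[str, ...] = ("DSDA", "DSSA")
    monitor_assignment: bool = False  # also track val 2-person assignment
    lr_final_frac: float = 1.0  # linear lr decay to lr * frac at max_epochs
    monitor_every: int = 1  # validate every N epochs (always the last epoch)

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 < self.lr_final_frac <= 1:
            raise ValueError("lr_final_frac must be in (0, 1]")
        if self.monitor_every < 1:
            raise ValueError("monitor_every must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def mixture(self) -> StrategyMixture:
        return STRATEGIES[self.strategy]


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)  # per-epoch mean loss
    val_auroc: list[dict[str, float]] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def __post_init__(self) -> None:
        if self.best_epoch > self.stopped_epoch:
            raise ValueError("best_epoch cannot exceed stopped_epoch")


class EarlyStopper:
    """Stop when none of the monitored metrics improves for ``patience``
    consecutive epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best: dict[str, float] = {}
        self.stale = 0

    def update(self, metrics: dict[str, float]) -> bool:
        improved = False
        for k, v in metrics.items():
            if v > self.best.get(k, -np.inf):
                self.best[k] = v
                improved = True
        self.stale = 0 if improved else self.stale + 1
        return self.stale >= self.patience


def _stack_batch(triplets, aug: AugConfig | None, rng: np.random.Generator):
    sils = []
    for t in triplets:
        sil = t.anchor.sil
        if aug is not None:
            sil = augment(sil, rng, aug)
        sils.append(sil)
    sil = np.stack(sils)
    bb = np.stack([t.anchor.bb for t in triplets])
    pos = np.stack([t.positive for t in triplets])
    neg = np.stack([t.negative for t in triplets])
    return sil, bb, pos, neg


def train(
    clips: Sequence[LabeledClipPair], cfg: TrainConfig
) -> tuple[ThreeStreamNet, TrainHistory]:
    """Train the three-stream model; returns the best weights and history."""
    split = cfg.split or split_by_subject(clips, seed=cfg.seed)
    train_clips = [c for c in clips if c.meta.subject_id in split.train]
    val_clips = [c for c in clips if c.meta.subject_id in split.val]
    if not train_clips:
        raise ValueError("training partition has no clips")
    if len({c.meta.subject_id for c in val_clips}) < 2:
        raise ValueError("validation partition needs >= 2 subjects for DS negatives")

    ss = np.random.SeedSequence(cfg.seed)
    init_seed, *epoch_seeds = ss.spawn(1 + 2 * cfg.max_epochs)
    L, H, W = train_clips[0].sil.shape
    net = build_model(cfg.arch, np.random.default_rng(init_seed), input_shape=(L, H, W))
    from .nn import Adam

    opt = Adam(net.params, lr=cfg.lr)
    vag = value_and_grad(batch_loss)
    monitor_types = [NegativeType(m) for m in cfg.monitor]
    stopper = EarlyStopper(cfg.patience)
    history = TrainHistory()
    best_avg = -np.inf
    best_params = copy.deepcopy(net.params)
    best_epoch = 0

    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.lr_final_frac < 1.0 and cfg.max_epochs > 1:
            frac = (epoch - 1) / (cfg.max_epochs - 1)
            opt.lr = cfg.lr * (1.0 - frac * (1.0 - cfg.lr_final_frac))
        rng_e = np.random.default_rng(epoch_seeds[2 * (epoch - 1)])
        rng_v = np.random.default_rng(epoch_seeds[2 * (epoch - 1) + 1])
        anchors = train_clips
        if cfg.anchors_per_epoch and cfg.anchors_per_epoch < len(train_clips):
            pick = rng_e.choice(len(train_clips), size=cfg.anchors_per_epoch, replace=False)
            anchors = [train_clips[i] for i in pick]
        trips = build_epoch(anchors, cfg.mixture, rng_e, pool=train_clips)
        order = rng_e.permutation(len(trips))
        trips = [trips[i] for i in order]
        epoch_losses = []
        for b0 in range(0, len(trips), cfg.batch_size):
            batch = _stack_batch(trips[b0 : b0 + cfg.batch_size], cfg.aug, rng_e)
            masks = net.make_masks(rng_e, batch[0].shape[0])
            loss_val, grads = vag(net.params, net, batch, cfg.loss, masks)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // cfg.batch_size}: "
                    f"{loss_val} (lr={cfg.lr}, loss={cfg.loss.kind})"
                )
            opt.step(net.params, grads)
            epoch_losses.append(float(loss_val))
        history.losses.append(float(np.mean(epoch_losses)))
        history.stopped_epoch = epoch
        if epoch % cfg.monitor_every != 0 and epoch != cfg.max_epochs:
            history.val_auroc.append({})
            continue
        emb = clip_embeddings(net, val_clips)
        metrics = auroc_by_negative_type(
            net, val_clips, rng_v, types=monitor_types, embeddings=emb
        )
        monitored = {k: v for k, v in metrics.items() if k in cfg.monitor}
        if cfg.monitor_assignment:
            sc = scenario_experiment(
                val_clips, "all_sync", rng_v, embeddings=emb, n_values=[2], n_reps=20
            )
            metrics["ASSIGN"] = monitored["ASSIGN"] = float(sc.mean[0])
        avg = float(np.mean(list(monitored.values()))) if monitored else -np.inf
        history.val_auroc.append(metrics)
        if avg > best_avg:
            best_avg = avg
            best_params = copy.deepcopy(net.params)
            best_epoch = epoch
        logger.info("epoch %d: loss %.4f, val %s", epoch, history.losses[-1], monitored)
        if stopper.update(monitored):
            break
    history.best_epoch = best_epoch
    net.params = best_params
    return net, history
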