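"""High-level modelling interface.

:class:`CrossModalMatchingModel` bundles a clip dataset with an
architecture, loss and negative-sampling strategy; ``fit`` trains the
three-stream encoders and returns a :class:`MatchingResults` carrying the
trained network, the training history and evaluation methods (per-type
auROC, assignment accuracy, scenario and observation-time curves) plus a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import LabeledClipPair, Manifest
from .encoders import ArchConfig, ThreeStreamNet
from .evaluation import (
    EvalReport,
    auroc_by_negative_type,
    clip_embeddings,
    evaluate_model,
    observation_time_curve,
    scenario_experiment,
)
from .losses import LossConfig
from .preprocess import PreprocConfig, clips_from_manifest, clips_from_streams
from .synthdata import SynthConfig, gen_streams
from .training import Split, TrainConfig, TrainHistory, split_by_subject, train


class CrossModalMatchingModel:
    """Video-accelerometer matching model over a labelled clip dataset.

    Parameters
    ----------
    clips : the labelled clip pairs (all subjects; the subject split is
        taken from ``config.split`` or drawn by seeded shuffle)
    config : training configuration (architecture, loss, strategy, ...)
    """

    def __init__(self, clips: Sequence[LabeledClipPair], config: TrainConfig | None = None):
        if not clips:
            raise ValueError("empty clip dataset")
        self.clips = list(clips)
        self.config = config or TrainConfig()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_manifest(
        cls,
        path: str | Path | Manifest,
        preproc: PreprocConfig | None = None,
        config: TrainConfig | None = None,
    ) -> "CrossModalMatchingModel":
        from .core_io import read_manifest

        manifest = path if isinstance(path, Manifest) else read_manifest(path)
        clips = clips_from_manifest(manifest, preproc or PreprocConfig())
        return cls(clips, config)

    @classmethod
    def from_synthetic(
        cls,
        synth: SynthConfig | None = None,
        preproc: PreprocConfig | None = None,
        config: TrainConfig | None = None,
    ) -> "CrossModalMatchingModel":
        clips = clips_from_streams(gen_streams(synth or SynthConfig()), preproc or PreprocConfig())
        return cls(clips, config)

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int | None = None) -> "MatchingResults":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        split = cfg.split or split_by_subject(self.clips, seed=cfg.seed)
        cfg = replace(cfg, split=split)
        net, history = train(self.clips, cfg)
        return MatchingResults(self, net, history, cfg)


class MatchingResults:
    """Fitted model: trained encoders, history, and evaluation methods."""

    def __init__(
        self,
        model: CrossModalMatchingModel,
        net: ThreeStreamNet,
        history: TrainHistory,
        config: TrainConfig,
    ):
        self.model = model
        self.net = net
        self.history = history
        self.config = config
        self.split: Split = config.split

    def _clips(self, subset: str) -> list[LabeledClipPair]:
        ids = set(getattr(self.split, subset))
        out = [c for c in self.model.clips if c.meta.subject_id in ids]
        if not out:
            raise ValueError(f"no clips in subset {subset!r}")
        return out

    # -- evaluation -------------------------------------------------------
    def auroc_by_type(self, subset: str = "test", seed: int = 0) -> dict[str, float]:
        clips = self._clips(subset)
        return auroc_by_negative_type(self.net, clips, np.random.default_rng(seed))

    def assignment_accuracy(
        self, n_people: int = 2, subset: str = "test", seed: int = 0, n_reps: int = 50
    ) -> float:
        clips = self._clips(subset)
        sc = scenario_experiment(
            clips, "all_sync", np.random.default_rng(seed), net=self.net,
            n_values=[n_people], n_reps=n_reps,
        )
        return float(sc.mean[0])

    def scenario(self, experiment: str, subset: str = "test", seed: int = 0, **kw):
        return scenario_experiment(
            self._clips(subset), experiment, np.random.default_rng(seed), net=self.net, **kw
        )

    def observation_time(self, subset: str = "test", seed: int = 0, **kw):
        return observation_time_curve(
            self._clips(subset), np.random.default_rng(seed), net=self.net, **kw
        )

    def evaluate(self, subset: str = "test", seed: int = 0) -> EvalReport:
        return evaluate_model(self.net, self._clips(subset), np.random.default_rng(seed))

    def embeddings(self, subset: str = "test"):
        return clip_embeddings(self.net, self._clips(subset))

    # -- reporting --------------------------------------------------------
    def summary(self, subset: str = "test", seed: int = 0) -> str:
        """Plain-text summary: configuration, fit trace, held-out metrics."""
        cfg = self.config
        aurocs = self.auroc_by_type(subset, seed=seed)
        n_test_subj = len(getattr(self.split, subset))
        acc = self.assignment_accuracy(
            n_people=min(2, n_test_subj) if n_test_subj >= 2 else 2,
            subset=subset, seed=seed,
        )
        lines = [
            "Cross-Modal Video-Accelerometer Matching",
            "=" * 56,
            f"architecture:     {cfg.arch.variant} (channels {cfg.arch.channels}, D={cfg.arch.embed_dim})",
            f"loss:             {cfg.loss.kind}"
            + (f" (margin alpha={cfg.loss.alpha})" if cfg.loss.kind == "stl" else ""),
            f"strategy:         {cfg.strategy}",
            f"optimizer:        Adam, lr={cfg.lr:g}, batch={cfg.batch_size}",
            f"subjects:         train={len(self.split.train)} val={len(self.split.val)} test={len(self.split.test)}",
            f"epochs:           {self.history.stopped_epoch} (best {self.history.best_epoch})",
            f"final train loss: {self.history.losses[-1]:.4f}",
            "-" * 56,
            f"held-out ({subset}) verification auROC by negative type:",
        ]
        for k in ("DSDA", "DSSA", "SSSA", "OVLP", "AVG"):
            if k in aurocs:
                lines.append(f"  {k:<6} {100 * aurocs[k]:5.1f}%")
        lines.append(f"2-person assignment accuracy: {100 * acc:5.1f}%")
        lines.append("=" * 56)
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.net.save(path)
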