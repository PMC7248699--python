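"""Centroid-acceleration baseline.

A classical, training-free comparison method: the visible person's
acceleration is estimated from the second finite difference of their
bounding-box centroid, and compared by Euclidean distance against the
wearable's acceleration after high-pass filtering (which removes gravity and
posture DC).  Both signals are reduced to magnitudes — the camera plane and
the IMU axes are not registered, and the magnitude sidesteps the unknown
rotation — and z-scored before the distance, since pixels and g-units are
incommensurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .core_io import BoundingBox, LabeledClipPair
from .evaluation import roc
from .triplets import eval_negatives

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineConfig:
    highpass_cutoff_hz: float = 0.5
    use_magnitude: bool = True
    smooth_window: int = 3  # frames, moving average on the centroid signal

    def validate(self, fps: float) -> None:
        if not 0 < self.highpass_cutoff_hz < fps / 2:
            raise ValueError(
                f"cutoff must be in (0, fps/2) = (0, {fps / 2}), got {self.highpass_cutoff_hz}"
            )


def _centroids(bb: Sequence[BoundingBox] | np.ndarray) -> np.ndarray:
    if isinstance(bb, np.ndarray):
        arr = np.asarray(bb, dtype=float)  # L x 4 (x, y, w, h), any consistent units
        return np.column_stack([arr[:, 0] + arr[:, 2] / 2, arr[:, 1] + arr[:, 3] / 2])
    return np.array([(b.x + b.w / 2, b.y + b.h / 2) for b in bb], dtype=float)


def centroid_accel(
    bb: Sequence[BoundingBox] | np.ndarray,
    fps: float,
    use_magnitude: bool = True,
    smooth_window: int = 1,
) -> np.ndarray:
    """Acceleration estimated from bounding-box centroids.

    Second central finite difference of the centroid times fps^2 (per-frame
    units -> units/s^2), edges replicated; optionally reduced to the
    magnitude over the two image axes.
    """
    c = _centroids(bb)
    if c.shape[0] < 3:
        raise ValueError(f"need at least 3 frames, got {c.shape[0]}")
    if smooth_window > 1:
        # edge-replicated moving average: zero-padding would inject edge
        # steps that the second difference amplifies by fps^2
        c = ndimage.uniform_filter1d(c, smooth_window, axis=0, mode="nearest")
    acc = np.empty_like(c)
    acc[1:-1] = (c[2:] - 2 * c[1:-1] + c[:-2]) * fps**2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    if use_magnitude:
        return np.linalg.norm(acc, axis=1)
    return acc


def highpass(acc: np.ndarray, cutoff_hz: float, fps: float) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth high-pass; removes DC."""
    acc = np.atleast_2d(np.asarray(acc, dtype=float).T).T  # ensure L x C
    sos = signal.butter(4, cutoff_hz / (fps / 2), btype="highpass", output="sos")
    out = signal.sosfiltfilt(sos, acc, axis=0)
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean()
    sd = x.std()
    if sd < 1e-12:
        logger.warning("zero-variance signal; comparing centred (unscaled) signals")
        return x - mu
    return (x - mu) / sd


def baseline_distance(
    bb: Sequence[BoundingBox] | np.ndarray,
    acc: np.ndarray,
    fps: float,
    cfg: BaselineConfig | None = None,
) -> float:
    """Euclidean distance between the z-scored centroid-acceleration
    magnitude and the z-scored high-pass-filtered wearable magnitude."""
    cfg = cfg or BaselineConfig()
    cfg.validate(fps)
    v = centroid_accel(bb, fps, use_magnitude=cfg.use_magnitude, smooth_window=cfg.smooth_window)
    w = highpass(np.asarray(acc, dtype=float), cfg.highpass_cutoff_hz, fps)
    w = np.linalg.norm(w, axis=1) if cfg.use_magnitude else w
    n = min(len(v), len(w))
    dv = _zscore(np.asarray(v[:n], dtype=float).ravel())
    dw = _zscore(np.asarray(w[:n], dtype=float).ravel())
    return float(np.linalg.norm(dv - dw))


def baseline_auroc(
    clips: Sequence[LabeledClipPair],
    rng: np.random.Generator,
    cfg: BaselineConfig | None = None,
) -> dict[str, float]:
    """Verification auROC of the baseline on inference-realistic negatives.

    Positives: each clip's own (bounding boxes, acceleration) pair;
    negatives: a 50/50 DSDA/DSSA draw, scored per type and jointly.
    """
    cfg = cfg or BaselineConfig()
    fps = clips[0].meta.fps
    pos = [baseline_distance(c.bb, c.acc, fps, cfg) for c in clips]
    neg_by_type: dict[str, list[float]] = {}
    for anchor, neg_acc, neg_type in eval_negatives(clips, rng):
        d = baseline_distance(anchor.bb, neg_acc, fps, cfg)
        neg_by_type.setdefault(neg_type.value, []).append(d)
    out = {}
    all_neg = []
    for t, dists in neg_by_type.items():
        out[t] = roc(pos, dists).auroc
        all_neg.extend(dists)
    out["combined"] = roc(pos, all_neg).auroc
    out["AVG"] = float(np.mean([v for k, v in out.items() if k not in ("combined",)]))
    return out
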