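"""Triplet losses over squared embedding distances.

Standard triplet loss (STL) with margin alpha:

    L = max(d_pos^2 - d_neg^2 + alpha, 0)

and the margin-free reciprocal triplet loss (RTL):

    L = d_pos^2 + 1 / d_neg^2

STL saturates to zero (and stops producing gradient) once the margin is
met, and only constrains distance differences within each triplet, so
distances from different triplets need not share a scale.  RTL keeps a
nonzero gradient everywhere — it continuously pulls every positive distance
toward 0 and pushes every negative distance up — which induces a common
scale across triplets and lets a single universal threshold separate
matching from non-matching pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .nn import DTYPE

DEFAULT_ALPHA = 0.2  # margin of the standard triplet loss
DEFAULT_EPS = 1e-8  # stabilizer for the RTL denominator


@dataclass(frozen=True)
class LossConfig:
    kind: str = "rtl"  # "stl" | "rtl"
    alpha: float = DEFAULT_ALPHA
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if self.kind not in ("stl", "rtl"):
            raise ValueError(f"loss kind must be 'stl' or 'rtl', got {self.kind!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


def _check_nonneg(*vals) -> None:
    for v in vals:
        if isinstance(v, (int, float, np.ndarray)) and np.any(np.asarray(v) < 0):
            raise ValueError("squared distances must be nonnegative")


def stl(d_pos_sq, d_neg_sq, alpha: float = DEFAULT_ALPHA):
    """Standard triplet loss on squared distances (scalar or elementwise)."""
    _check_nonneg(d_pos_sq, d_neg_sq)
    return anp.maximum(d_pos_sq - d_neg_sq + alpha, 0.0)


def rtl(d_pos_sq, d_neg_sq, eps: float = DEFAULT_EPS):
    """Reciprocal triplet loss on squared distances (scalar or elementwise)."""
    _check_nonneg(d_pos_sq, d_neg_sq)
    return d_pos_sq + 1.0 / (d_neg_sq + eps)


def triplet_distances(net, params, batch_sil, batch_bb, batch_pos, batch_neg, masks=None):
    """Squared anchor-positive and anchor-negative distances for a batch."""
    e_v = net.video_forward(params, batch_sil, batch_bb, masks)
    e_p = net.accel_forward(params, batch_pos, masks)
    e_n = net.accel_forward(params, batch_neg, masks)
    d_pos = anp.sum((e_v - e_p) ** 2, axis=1)
    d_neg = anp.sum((e_v - e_n) ** 2, axis=1)
    return d_pos, d_neg


def batch_loss(params, net, batch, cfg: LossConfig, masks=None):
    """Mean per-triplet loss over a batch.

    ``batch`` is a tuple (sil, bb, pos, neg) of stacked numpy arrays:
    (B, L, H, W), (B, L, 4), (B, L, 3), (B, L, 3).
    """
    sil, bb, pos, neg = batch
    d_pos, d_neg = triplet_distances(net, params, sil, bb, pos, neg, masks)
    if cfg.kind == "stl":
        per = anp.maximum(d_pos - d_neg + DTYPE(cfg.alpha), 0.0)
    else:
        per = d_pos + 1.0 / (d_neg + DTYPE(cfg.eps))
    return anp.mean(per)
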