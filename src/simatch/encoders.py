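"""Three-stream embedding networks and the embedding-space distance.

The video encoder f(.) is the elementwise sum of a silhouette encoder
f_sil(.) (3-D convolutions over time x height x width) and a bounding-box
encoder f_bb(.) (1-D convolutions over time); the acceleration encoder g(.)
mirrors f_bb with 3 input channels.  All convolutions use kernel size 3,
ReLU activations and spatial (whole-channel) dropout.  Three variants:

fully_conv
    alternating max-pool / convolution stages that shrink every axis while
    the channel count grows, a final convolution to the embedding width with
    tanh activation, then a global max-pool — embeddings lie in [-1, 1]^D.
lstm_tp
    the same stack but temporal pooling stops after the first ``tp_stages``
    stages; the remaining per-timestep features feed an LSTM whose final
    hidden state is the embedding.
lstm
    no temporal pooling at all; the full-length temporal feature sequence
    feeds the LSTM.

Matching is scored with the squared Euclidean distance between f and g
embeddings, which share one dimension D.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import autograd.numpy as anp
import numpy as np

from . import nn

VARIANTS = ("fully_conv", "lstm_tp", "lstm")
_BRANCH_CHANNELS = {"sil": 1, "bb": 4, "acc": 3}


@dataclass(frozen=True)
class ArchConfig:
    variant: str = "fully_conv"
    kernel_size: int = 3
    channels: tuple[int, ...] = (8, 16, 32, 64)
    dropout_rate: float = 0.2
    embed_dim: int = 64
    lstm_hidden: int = 64
    tp_stages: int = 2  # temporal-pooling stages for the lstm_tp variant
    emb_init_gain: float = 0.3  # scale on the final (pre-tanh) conv init

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.kernel_size != 3:
            raise ValueError("kernel_size is fixed at 3")
        if not self.channels:
            raise ValueError("channels must be non-empty")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.emb_init_gain <= 0:
            raise ValueError("emb_init_gain must be > 0")


def _pool_axes(cfg: ArchConfig, stage: int, nd: int) -> tuple[int, ...]:
    """Axes pooled before the conv of a given stage (batch=0, channel=1)."""
    spatial = tuple(range(3, 2 + nd))  # H, W for the 3-D branch; empty for 1-D
    time_ax = (2,)
    if cfg.variant == "fully_conv":
        return time_ax + spatial
    if cfg.variant == "lstm_tp":
        return (time_ax + spatial) if stage < cfg.tp_stages else spatial
    return spatial  # lstm: never pool time


def _branch_forward(params, prefix: str, x, cfg: ArchConfig, masks=None):
    """Shared conv-stack forward for one branch.  x: (B, C, T[, H, W])."""
    nd = x.ndim - 2
    for i in range(len(cfg.channels)):
        x = nn.maxpool(x, _pool_axes(cfg, i, nd))
        x = nn.conv_nd(x, params[f"{prefix}/stage{i}/w"], params[f"{prefix}/stage{i}/b"])
        x = nn.relu(x)
        if masks is not None:
            x = nn.spatial_dropout(x, masks[(prefix, i)])
    if cfg.variant == "fully_conv":
        x = nn.conv_nd(x, params[f"{prefix}/emb/w"], params[f"{prefix}/emb/b"])
        x = anp.tanh(x)
        return nn.global_maxpool(x, tuple(range(2, 2 + nd)))
    # LSTM variants: collapse spatial axes, keep time
    if nd > 1:
        x = nn.global_maxpool(x, tuple(range(3, 2 + nd)))
    x = anp.transpose(x, (0, 2, 1))  # (B, T', C)
    h = nn.lstm(x, params[f"{prefix}/lstm/wx"], params[f"{prefix}/lstm/wh"],
                params[f"{prefix}/lstm/b"])
    if cfg.lstm_hidden != cfg.embed_dim:
        h = nn.dense(h, params[f"{prefix}/proj/w"], params[f"{prefix}/proj/b"])
    return h


def simulate_shapes(cfg: ArchConfig, input_shape: tuple[int, ...], nd: int) -> list[tuple[int, ...]]:
    """Trace the spatial shape through the stack; raises if an axis collapses."""
    axes_names = ("time", "height", "width")[:nd]
    shape = list(input_shape)
    trace = [tuple(shape)]
    for i in range(len(cfg.channels)):
        pool_axes = [a - 2 for a in _pool_axes(cfg, i, nd)]
        for a in pool_axes:
            if shape[a] >= 2:
                shape[a] //= 2
        for a, s in enumerate(shape):
            if s < 1:
                raise ValueError(f"stage {i}: {axes_names[a]} axis reduced below 1")
        trace.append(tuple(shape))
    return trace


def build_model(
    cfg: ArchConfig,
    seed: int | np.random.Generator = 0,
    input_shape: tuple[int, int, int] | None = None,
) -> "ThreeStreamNet":
    """Initialize a three-stream network with seeded weights.

    ``input_shape`` (clip_len, H, W), if given, is validated against the
    stack (an axis that would collapse raises with the offending axis).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if input_shape is not None:
        simulate_shapes(cfg, input_shape, 3)
        simulate_shapes(cfg, input_shape[:1], 1)
    params: dict[str, np.ndarray] = {}
    for prefix, c_in0 in _BRANCH_CHANNELS.items():
        nd = 3 if prefix == "sil" else 1
        c_in = c_in0
        for i, c_out in enumerate(cfg.channels):
            params[f"{prefix}/stage{i}/w"] = nn.init_conv(rng, c_out, c_in, cfg.kernel_size, nd)
            params[f"{prefix}/stage{i}/b"] = np.zeros(c_out, dtype=nn.DTYPE)
            c_in = c_out
        if cfg.variant == "fully_conv":
            # Damped init keeps the pre-tanh field near its linear range, so
            # the global max of tanh stays input-sensitive early in training
            # instead of saturating all channels at +1.
            params[f"{prefix}/emb/w"] = nn.DTYPE(cfg.emb_init_gain) * nn.init_conv(
                rng, cfg.embed_dim, c_in, cfg.kernel_size, nd
            )
            params[f"{prefix}/emb/b"] = np.zeros(cfg.embed_dim, dtype=nn.DTYPE)
        else:
            lstm_p = nn.init_lstm(rng, c_in, cfg.lstm_hidden)
            for k, v in lstm_p.items():
                params[f"{prefix}/lstm/{k}"] = v
            if cfg.lstm_hidden != cfg.embed_dim:
                params[f"{prefix}/proj/w"] = nn.init_dense(rng, cfg.lstm_hidden, cfg.embed_dim)
                params[f"{prefix}/proj/b"] = np.zeros(cfg.embed_dim, dtype=nn.DTYPE)
    return ThreeStreamNet(cfg, params)


class ThreeStreamNet:
    """Parameter container plus pure forward functions.

    The ``*_forward`` methods are autograd-differentiable functions of the
    parameter dict; ``encode_video`` / ``encode_accel`` are inference-mode
    conveniences (dropout off, numpy in / numpy out, deterministic).
    """

    def __init__(self, cfg: ArchConfig, params: dict[str, np.ndarray]):
        self.cfg = cfg
        self.params = params

    # -- differentiable forwards ------------------------------------------
    def video_forward(self, params, sil, bb, masks=None):
        """sil: (B, L, H, W) binary; bb: (B, L, 4) in [0, 1] -> (B, D)."""
        if sil.ndim != 4:
            raise ValueError(f"sil must be (B, L, H, W), got shape {sil.shape}")
        if bb.ndim != 3 or bb.shape[2] != 4:
            raise ValueError(f"bb must be (B, L, 4), got shape {bb.shape}")
        x_sil = sil[:, None].astype(nn.DTYPE) if isinstance(sil, np.ndarray) else sil[:, None]
        x_bb = anp.transpose(bb, (0, 2, 1)).astype(nn.DTYPE)
        e_sil = _branch_forward(params, "sil", x_sil, self.cfg, masks)
        e_bb = _branch_forward(params, "bb", x_bb, self.cfg, masks)
        return e_sil + e_bb

    def accel_forward(self, params, acc, masks=None):
        """acc: (B, L, 3) -> (B, D)."""
        if acc.ndim != 3 or acc.shape[2] != 3:
            raise ValueError(f"acc must be (B, L, 3), got shape {acc.shape}")
        x = anp.transpose(acc, (0, 2, 1)).astype(nn.DTYPE)
        return _branch_forward(params, "acc", x, self.cfg, masks)

    # -- dropout masks ----------------------------------------------------
    def make_masks(self, rng: np.random.Generator, batch: int):
        if self.cfg.dropout_rate == 0:
            return None
        masks = {}
        for prefix in _BRANCH_CHANNELS:
            nd = 3 if prefix == "sil" else 1
            for i, c in enumerate(self.cfg.channels):
                masks[(prefix, i)] = nn.make_channel_mask(
                    rng, batch, c, self.cfg.dropout_rate, nd
                )
        return masks

    # -- inference --------------------------------------------------------
    def encode_video(self, sil: np.ndarray, bb: np.ndarray, chunk: int = 32) -> np.ndarray:
        sil = np.asarray(sil)
        bb = np.asarray(bb)
        single = sil.ndim == 3
        if single:
            sil, bb = sil[None], bb[None]
        out = [
            np.asarray(self.video_forward(self.params, sil[i : i + chunk], bb[i : i + chunk]))
            for i in range(0, len(sil), chunk)
        ]
        res = np.concatenate(out)
        return res[0] if single else res

    def encode_accel(self, acc: np.ndarray, chunk: int = 256) -> np.ndarray:
        acc = np.asarray(acc)
        single = acc.ndim == 2
        if single:
            acc = acc[None]
        out = [
            np.asarray(self.accel_forward(self.params, acc[i : i + chunk]))
            for i in range(0, len(acc), chunk)
        ]
        res = np.concatenate(out)
        return res[0] if single else res

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **{k.replace("/", "__"): v for k, v in self.params.items()})
        path.with_suffix(".json").write_text(json.dumps(asdict(self.cfg)))

    @classmethod
    def load(cls, path: str | Path) -> "ThreeStreamNet":
        path = Path(path)
        doc = json.loads(path.with_suffix(".json").read_text())
        doc["channels"] = tuple(doc["channels"])
        cfg = ArchConfig(**doc)
        with np.load(path.with_suffix(".npz")) as z:
            params = {k.replace("__", "/"): z[k] for k in z.files}
        return cls(cfg, params)


def pair_distance(e1: np.ndarray, e2: np.ndarray) -> float:
    """Squared Euclidean distance between two embeddings."""
    d = np.asarray(e1, dtype=float) - np.asarray(e2, dtype=float)
    return float(np.dot(d.ravel(), d.ravel()))


def pairwise_sq_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All squared distances between rows of ``a`` (N x D) and ``b`` (M x D)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d2 = (a * a).sum(1)[:, None] + (b * b).sum(1)[None, :] - 2.0 * (a @ b.T)
    return np.maximum(d2, 0.0)
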