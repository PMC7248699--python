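"""Raw streams -> fixed-size labelled clip pairs.

Each silhouette frame is cropped to its bounding box and rescaled so the
longer side equals ``target_size`` (nearest-neighbour, aspect preserved),
then centred on a square zero canvas; streams are truncated into
fixed-length overlapping clips; the accelerometer stream is subsampled to
the video frame rate by nearest-timestamp selection; bounding boxes are
normalized by the frame extents and fed to the model as a side channel.
Training-time augmentation operates on whole silhouette clips: joint
horizontal flip, dilation/erosion with a radius drawn once per clip, and
independent per-pixel salt-and-pepper corruption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .core_io import (
    AccelSample,
    BoundingBox,
    LabeledClipPair,
    Manifest,
    MaskFrame,
    StreamMeta,
    accel_to_arrays,
    read_accel_csv,
    read_bbox_csv,
    read_mask_stream,
)
from .synthdata import StreamBundle

logger = logging.getLogger(__name__)


@dataclass
class AugConfig:
    p_flip: float = 0.5
    max_dilate: int = 5  # pixels
    max_erode: int = 5  # pixels
    sp_fraction: float = 0.03  # salt-and-pepper pixel-flip probability

    def __post_init__(self) -> None:
        if not 0 <= self.p_flip <= 1:
            raise ValueError("p_flip must be in [0, 1]")
        if not 0 <= self.sp_fraction <= 1:
            raise ValueError("sp_fraction must be in [0, 1]")


@dataclass
class PreprocConfig:
    clip_len: int = 100  # frames (~3 s at 30 fps)
    overlap: float = 0.95  # fraction of consecutive clips shared
    target_size: int = 100  # pixels, longer side of the resized crop
    aug: AugConfig = field(default_factory=AugConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.clip_len < 2:
            raise ValueError("clip_len must be >= 2")

    @property
    def canvas(self) -> tuple[int, int]:
        return (self.target_size, self.target_size)


def crop_and_resize(frame: MaskFrame | np.ndarray, box: BoundingBox, target_size: int) -> np.ndarray:
    """Crop a mask to its box and rescale the longer side to ``target_size``.

    The aspect ratio is preserved (nearest-neighbour sampling) and the
    content is centred on a ``target_size x target_size`` zero canvas.
    """
    grid = frame.grid if isinstance(frame, MaskFrame) else np.asarray(frame)
    Hf, Wf = grid.shape
    if box.x + box.w > Wf or box.y + box.h > Hf:
        raise ValueError(f"box {box} exceeds frame bounds {grid.shape}")
    crop = grid[box.y : box.y + box.h, box.x : box.x + box.w]
    if crop.size == 0:
        raise ValueError("empty crop")
    scale = target_size / max(box.h, box.w)
    nh = max(1, int(round(box.h * scale)))
    nw = max(1, int(round(box.w * scale)))
    content = resize(
        crop.astype(float), (nh, nw), order=0, anti_aliasing=False, preserve_range=True
    )
    content = (content > 0.5).astype(np.uint8)
    out = np.zeros((target_size, target_size), dtype=np.uint8)
    oy = (target_size - nh) // 2
    ox = (target_size - nw) // 2
    out[oy : oy + nh, ox : ox + nw] = content
    return out


def truncate_stream(n_frames: int, clip_len: int, overlap: float) -> list[int]:
    """Start indices of fixed-length clips with the given overlap fraction.

    stride = round(clip_len * (1 - overlap)), at least 1; every clip is
    exactly ``clip_len`` frames and lies fully inside the stream.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    stride = max(1, int(round(clip_len * (1.0 - overlap))))
    return list(range(0, max(n_frames - clip_len, -1) + 1, stride))


def subsample_accel(
    samples: Sequence[AccelSample] | tuple[np.ndarray, np.ndarray],
    frame_times: np.ndarray,
) -> np.ndarray:
    """Select, for every frame time, the accel sample of nearest timestamp.

    Returns an ``len(frame_times) x 3`` matrix.  The accel stream must cover
    the requested span to within half a sample period.
    """
    if isinstance(samples, tuple):
        t, a = samples
    else:
        t, a = accel_to_arrays(samples)
    frame_times = np.asarray(frame_times, dtype=float)
    if len(t) == 0:
        raise ValueError("empty accel stream")
    slack = 0.5 * (np.median(np.diff(t)) if len(t) > 1 else 0.0)
    lo, hi = frame_times.min(), frame_times.max()
    if lo < t[0] - slack or hi > t[-1] + slack:
        raise ValueError(
            f"clip span [{lo:.3f}, {hi:.3f}] s outside accel coverage [{t[0]:.3f}, {t[-1]:.3f}] s"
        )
    idx = np.searchsorted(t, frame_times)
    idx = np.clip(idx, 1, len(t) - 1)
    left, right = t[idx - 1], t[idx]
    choose_left = (frame_times - left) < (right - frame_times)
    idx = idx - choose_left.astype(int)
    return a[idx]


def normalize_bboxes(boxes: Sequence[BoundingBox], frame_w: int, frame_h: int) -> np.ndarray:
    """(x/W, y/H, w/W, h/H) per frame, as an L x 4 matrix in [0, 1]."""
    out = np.array(
        [
            (b.x / frame_w, b.y / frame_h, b.w / frame_w, b.h / frame_h)
            for b in boxes
        ],
        dtype=float,
    )
    return out


def augment(clip: np.ndarray, rng: np.random.Generator, cfg: AugConfig) -> np.ndarray:
    """Augment one silhouette clip (L x H x W, binary), returning a new clip.

    The horizontal flip applies to all frames jointly; dilation and erosion
    radii are each drawn once per clip, uniformly in {0, ..., max}, with a
    square structuring element; salt-and-pepper flips each pixel
    independently with probability ``sp_fraction``.
    """
    out = np.asarray(clip, dtype=np.uint8)
    if cfg.p_flip > 0 and rng.random() < cfg.p_flip:
        out = out[:, :, ::-1]
    r_dil = int(rng.integers(0, cfg.max_dilate + 1)) if cfg.max_dilate > 0 else 0
    if r_dil > 0:
        se = np.ones((1, 2 * r_dil + 1, 2 * r_dil + 1), dtype=bool)
        out = ndimage.binary_dilation(out, structure=se).astype(np.uint8)
    r_ero = int(rng.integers(0, cfg.max_erode + 1)) if cfg.max_erode > 0 else 0
    if r_ero > 0:
        se = np.ones((1, 2 * r_ero + 1, 2 * r_ero + 1), dtype=bool)
        out = ndimage.binary_erosion(out, structure=se).astype(np.uint8)
    if cfg.sp_fraction > 0:
        flips = rng.random(out.shape) < cfg.sp_fraction
        out = (out ^ flips).astype(np.uint8)
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# stream -> clip pairs


def _stream_to_clips(
    masks: Sequence[MaskFrame],
    boxes: Sequence[BoundingBox],
    accel: Sequence[AccelSample] | tuple[np.ndarray, np.ndarray],
    meta: StreamMeta,
    cfg: PreprocConfig,
) -> list[LabeledClipPair]:
    n = len(masks)
    if len(boxes) != n:
        raise ValueError(f"{n} mask frames but {len(boxes)} bounding boxes")
    frame_h, frame_w = masks[0].grid.shape
    frame_times = meta.t0 + np.arange(n) / meta.fps
    # per-frame accel for the whole stream: computed once, shared by clips
    source_accel = subsample_accel(accel, frame_times)
    sil_all = np.stack(
        [crop_and_resize(m, b, cfg.target_size) for m, b in zip(masks, boxes)]
    )
    bb_all = normalize_bboxes(boxes, frame_w, frame_h)
    clips = []
    for start in truncate_stream(n, cfg.clip_len, cfg.overlap):
        sl = slice(start, start + cfg.clip_len)
        clips.append(
            LabeledClipPair(
                sil=sil_all[sl],
                bb=bb_all[sl],
                acc=source_accel[sl],
                meta=meta,
                start_frame=start,
                source_accel=source_accel,
            )
        )
    return clips


def clips_from_streams(streams: Sequence[StreamBundle], cfg: PreprocConfig) -> list[LabeledClipPair]:
    """Build clip pairs from in-memory generated streams."""
    out: list[LabeledClipPair] = []
    for s in streams:
        out.extend(_stream_to_clips(s.masks, s.boxes, s.accel, s.meta, cfg))
    return out


def clips_from_manifest(manifest: Manifest, cfg: PreprocConfig) -> list[LabeledClipPair]:
    """Build clip pairs from an on-disk dataset."""
    out: list[LabeledClipPair] = []
    for e in manifest:
        masks = read_mask_stream(e.mask_dir)
        boxes = read_bbox_csv(e.bbox_csv)
        accel = read_accel_csv(e.accel_csv)
        out.extend(_stream_to_clips(masks, boxes, accel, e.meta, cfg))
    return out


# ---------------------------------------------------------------------------
# HDF5 clip store (CLI artifact)


def write_clip_store(path: str | Path, clips: Sequence[LabeledClipPair]) -> None:
    with h5py.File(path, "w") as f:
        str_dt = h5py.string_dtype()
        f.create_dataset("sil", data=np.stack([c.sil for c in clips]).astype(np.uint8))
        f.create_dataset("bb", data=np.stack([c.bb for c in clips]))
        f.create_dataset("acc", data=np.stack([c.acc for c in clips]))
        f.create_dataset("start_frame", data=np.array([c.start_frame for c in clips]))
        for name in ("subject_id", "activity", "session"):
            f.create_dataset(
                name, data=np.array([getattr(c.meta, name) for c in clips], dtype=str_dt)
            )
        f.create_dataset("fps", data=np.array([c.meta.fps for c in clips]))
        f.create_dataset("t0", data=np.array([c.meta.t0 for c in clips]))
        # full-stream accel, one per unique stream, for overlap negatives
        streams = {}
        for c in clips:
            streams.setdefault(c.meta.stream_key, c.source_accel)
        g = f.create_group("stream_accel")
        for i, (key, arr) in enumerate(sorted(streams.items())):
            if arr is None:
                continue
            d = g.create_dataset(str(i), data=arr)
            d.attrs["key"] = "|".join(key)


def read_clip_store(path: str | Path) -> list[LabeledClipPair]:
    with h5py.File(path, "r") as f:
        stream_accel = {}
        for name, d in f["stream_accel"].items():
            key = tuple(d.attrs["key"].split("|"))
            stream_accel[key] = np.asarray(d)
        n = f["sil"].shape[0]
        clips = []
        for i in range(n):
            meta = StreamMeta(
                subject_id=f["subject_id"][i].decode(),
                activity=f["activity"][i].decode(),
                session=f["session"][i].decode(),
                fps=float(f["fps"][i]),
                t0=float(f["t0"][i]),
            )
            clips.append(
                LabeledClipPair(
                    sil=np.asarray(f["sil"][i]),
                    bb=np.asarray(f["bb"][i]),
                    acc=np.asarray(f["acc"][i]),
                    meta=meta,
                    start_frame=int(f["start_frame"][i]),
                    source_accel=stream_accel.get(meta.stream_key),
                )
            )
    return clips
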