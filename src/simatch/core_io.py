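"""Domain types and on-disk formats.

Streams live on disk as plain, inspectable files: silhouette masks as
single-channel PNG-per-frame directories (an HDF5 stack is also accepted for
large sets), accelerometer data as ``t,ax,ay,az`` CSV, bounding boxes as
``frame,x,y,w,h,track_id`` CSV, and a YAML manifest tying streams to subject,
activity and session.  Embeddings round-trip through HDF5.

Conventions: frame indexing is 0-based and clip windows are half-open
``[start, start + L)``; bounding boxes are top-left-origin ``(x, y, w, h)`` in
integer pixels; timestamps are seconds, with frame ``k`` occurring at
``t0 + k / fps``.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StreamMeta",
    "MaskFrame",
    "BoundingBox",
    "AccelSample",
    "LabeledClipPair",
    "ManifestEntry",
    "Manifest",
    "read_mask_stream",
    "write_mask_stream",
    "read_bbox_csv",
    "write_bbox_csv",
    "read_accel_csv",
    "write_accel_csv",
    "read_manifest",
    "write_manifest",
    "write_embeddings",
    "read_embeddings",
]


@dataclass(frozen=True)
class StreamMeta:
    """Identity of one recorded stream: who, doing what, in which session."""

    subject_id: str
    activity: str
    session: str = "s0"
    fps: float = 30.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if not self.activity:
            raise ValueError("activity must be non-empty")
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")

    @property
    def stream_key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.activity, self.session)


@dataclass(frozen=True)
class MaskFrame:
    """One binary silhouette frame."""

    grid: np.ndarray  # H x W, values in {0, 1}
    frame_index: int

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.shape[0] < 1 or g.shape[1] < 1:
            raise ValueError(f"mask grid must be 2-D and non-empty, got shape {g.shape}")
        vals = np.unique(g)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")


@dataclass(frozen=True)
class BoundingBox:
    frame_index: int
    x: int
    y: int
    w: int
    h: int
    track_id: int = 0

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"bounding box extents must be >= 1, got w={self.w}, h={self.h}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"bounding box origin must be >= 0, got x={self.x}, y={self.y}")


@dataclass(frozen=True)
class AccelSample:
    t: float
    a: np.ndarray  # (ax, ay, az) in g-units


@dataclass
class LabeledClipPair:
    """One fixed-length window with its silhouette clip, bounding boxes and
    time-aligned acceleration — the (V, A) pair of the matching problem.

    ``source_accel`` optionally keeps the full per-frame acceleration of the
    parent stream so that overlapping, out-of-sync negatives can be cut from
    the same stream later.
    """

    sil: np.ndarray  # L x Hc x Wc, {0, 1}
    bb: np.ndarray  # L x 4, in [0, 1]
    acc: np.ndarray  # L x 3
    meta: StreamMeta
    start_frame: int
    source_accel: np.ndarray | None = None  # full-stream per-frame accel (optional)

    def __post_init__(self) -> None:
        L = self.sil.shape[0]
        if not (self.bb.shape == (L, 4) and self.acc.shape == (L, 3)):
            raise ValueError(
                f"temporal axes disagree: sil {self.sil.shape}, bb {self.bb.shape}, acc {self.acc.shape}"
            )
        if self.bb.size and (self.bb.min() < 0 or self.bb.max() > 1):
            raise ValueError("normalized bounding boxes must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.sil.shape[0]

    @property
    def window(self) -> tuple[int, int]:
        return (self.start_frame, self.start_frame + self.length)


@dataclass(frozen=True)
class ManifestEntry:
    mask_dir: Path
    bbox_csv: Path
    accel_csv: Path
    meta: StreamMeta


@dataclass
class Manifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def subjects(self) -> list[str]:
        return sorted({e.meta.subject_id for e in self.entries})


# ---------------------------------------------------------------------------
# mask streams

_FRAME_RE = re.compile(r"^(\d+)\.(png|pgm|bmp|tif|tiff)$", re.IGNORECASE)


def read_mask_stream(path: str | Path) -> list[MaskFrame]:
    """Read a silhouette stream from a directory of numbered single-channel
    images or from an HDF5 stack (dataset ``masks``, shape T x H x W).

    Any pixel > 0 maps to 1.  Frame indices must form a contiguous 0-based
    range.
    """
    path = Path(path)
    if path.is_file() and path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            stack = np.asarray(f["masks"])
        return [MaskFrame((fr > 0).astype(np.uint8), i) for i, fr in enumerate(stack)]
    if not path.is_dir():
        raise FileNotFoundError(f"mask stream not found: {path}")
    indexed: dict[int, Path] = {}
    for p in sorted(path.iterdir()):
        m = _FRAME_RE.match(p.name)
        if m:
            indexed[int(m.group(1))] = p
    if not indexed:
        raise ValueError(f"no frames found in {path}")
    n = max(indexed) + 1
    frames = []
    for i in range(n):
        if i not in indexed:
            raise ValueError(f"missing frame index {i} in {path}")
        try:
            img = iio.imread(indexed[i])
        except Exception as exc:  # noqa: BLE001 - wrap decoder errors uniformly
            raise ValueError(f"cannot decode image {indexed[i]}: {exc}") from exc
        if img.ndim == 3:
            img = img[..., 0]
        frames.append(MaskFrame((img > 0).astype(np.uint8), i))
    return frames


def write_mask_stream(path: str | Path, frames: Sequence[MaskFrame | np.ndarray]) -> None:
    """Write frames as zero-padded PNGs (``000000.png``, ...) into ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, fr in enumerate(frames):
        grid = fr.grid if isinstance(fr, MaskFrame) else np.asarray(fr)
        iio.imwrite(path / f"{i:06d}.png", (grid.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# CSV streams

_BBOX_COLS = ["frame", "x", "y", "w", "h", "track_id"]
_ACCEL_COLS = ["t", "ax", "ay", "az"]


def read_bbox_csv(path: str | Path) -> list[BoundingBox]:
    df = pd.read_csv(path)
    missing = [c for c in _BBOX_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"bbox CSV {path} missing columns {missing}")
    return [
        BoundingBox(int(r.frame), int(r.x), int(r.y), int(r.w), int(r.h), int(r.track_id))
        for r in df.itertuples()
    ]


def write_bbox_csv(path: str | Path, boxes: Sequence[BoundingBox]) -> None:
    df = pd.DataFrame(
        [(b.frame_index, b.x, b.y, b.w, b.h, b.track_id) for b in boxes], columns=_BBOX_COLS
    )
    df.to_csv(path, index=False)


def read_accel_csv(path: str | Path) -> list[AccelSample]:
    """Read a ``t,ax,ay,az`` CSV; timestamps must be strictly increasing."""
    df = pd.read_csv(path)
    missing = [c for c in _ACCEL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"accel CSV {path} missing columns {missing}")
    t = df["t"].to_numpy(float)
    dt = np.diff(t)
    if (dt <= 0).any():
        k = int(np.argmax(dt <= 0))
        raise ValueError(
            f"accel CSV {path}: timestamps not strictly increasing at row {k + 1} "
            f"(t={t[k]} followed by t={t[k + 1]})"
        )
    a = df[["ax", "ay", "az"]].to_numpy(float)
    return [AccelSample(float(ti), ai) for ti, ai in zip(t, a)]


def write_accel_csv(path: str | Path, samples: Sequence[AccelSample]) -> None:
    df = pd.DataFrame(
        [(s.t, *np.asarray(s.a, dtype=float)) for s in samples], columns=_ACCEL_COLS
    )
    df.to_csv(path, index=False, float_format="%.6f")


def accel_to_arrays(samples: Sequence[AccelSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a sample sequence into (t, a) arrays of shapes (N,), (N, 3)."""
    t = np.array([s.t for s in samples], dtype=float)
    a = np.stack([np.asarray(s.a, dtype=float) for s in samples]) if samples else np.zeros((0, 3))
    return t, a


# ---------------------------------------------------------------------------
# manifest

def write_manifest(path: str | Path, manifest: Manifest) -> None:
    doc = [
        {
            "mask_dir": str(e.mask_dir),
            "bbox_csv": str(e.bbox_csv),
            "accel_csv": str(e.accel_csv),
            "meta": dataclasses.asdict(e.meta),
        }
        for e in manifest.entries
    ]
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def read_manifest(path: str | Path) -> Manifest:
    """Load a manifest; every referenced path must resolve.

    Relative paths are taken relative to the manifest's directory.  Entry
    order is preserved exactly as written.
    """
    path = Path(path)
    with open(path) as f:
        doc = yaml.safe_load(f)
    root = path.parent
    entries = []
    for item in doc:
        e = ManifestEntry(
            mask_dir=_resolve(root, item["mask_dir"]),
            bbox_csv=_resolve(root, item["bbox_csv"]),
            accel_csv=_resolve(root, item["accel_csv"]),
            meta=StreamMeta(**item["meta"]),
        )
        for p in (e.mask_dir, e.bbox_csv, e.accel_csv):
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest {path}: referenced path does not exist: {p}")
        entries.append(e)
    return Manifest(entries)


def _resolve(root: Path, p: str) -> Path:
    q = Path(p)
    return q if q.is_absolute() else root / q


# ---------------------------------------------------------------------------
# embedding stores

def write_embeddings(store_path: str | Path, ids: Sequence[str], vectors: Sequence[np.ndarray]) -> None:
    """Write embeddings to HDF5.  All vectors must share one dimension."""
    vecs = [np.asarray(v) for v in vectors]
    if len(vecs) != len(ids):
        raise ValueError(f"{len(ids)} ids but {len(vecs)} vectors")
    dims = {v.shape for v in vecs}
    if len(dims) > 1:
        raise ValueError(f"embedding dimension mismatch: {sorted(dims)}")
    arr = np.stack(vecs) if vecs else np.zeros((0, 0))
    with h5py.File(store_path, "w") as f:
        f.create_dataset("ids", data=np.array(list(ids), dtype=h5py.string_dtype()))
        f.create_dataset("vectors", data=arr)


def read_embeddings(store_path: str | Path) -> tuple[list[str], np.ndarray]:
    with h5py.File(store_path, "r") as f:
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][()]]
        vectors = np.asarray(f["vectors"])
    return ids, vectors
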