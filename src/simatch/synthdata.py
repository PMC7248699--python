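"""Paired silhouette-video / accelerometer stream generator.

The generator emulates the data regime of a single-occupancy home-monitoring
recording: one tracked person per camera view, a wrist-worn tri-axial
accelerometer, and both streams time-stamped on a shared clock.  Each
(subject, activity) segment is driven by one latent wrist trajectory: the
camera sees a 2-D projection of it (an arm attached to a body ellipse,
rendered as a binary silhouette), while the wearable reports its second time
derivative in 3-D plus gravity and sensor noise.  This makes the true
cross-modal coupling explicit — matching is possible exactly because both
modalities observe the same motion.

Subjects differ by deterministic per-subject traits (amplitude multiplier,
frequency within the activity band, phases, body size, arm length), so two
subjects doing the same activity produce distinct but same-band signals:
identity information exists in both modalities, which is what makes
same-activity and same-subject negatives meaningful rather than degenerate.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk, ellipse, line

from .core_io import (
    AccelSample,
    BoundingBox,
    Manifest,
    ManifestEntry,
    MaskFrame,
    StreamMeta,
    write_accel_csv,
    write_bbox_csv,
    write_manifest,
    write_mask_stream,
)

logger = logging.getLogger(__name__)

GRAVITY_MS2 = 9.81  # 1 g, placed on the z channel of every wearable sample


@dataclass(frozen=True)
class ActivitySpec:
    """Parameters of one activity's wrist-motion regime.

    freq_band : (lo, hi) Hz of the dominant gesture frequency
    amp_range : (lo, hi) metres of the dominant gesture amplitude
    rest_fraction : fraction of the segment during which the wrist is static
    axis_ratios : relative amplitude of the (x, y, z) wrist components
    drift_sigma : std (m) of the smooth positional drift added to the gesture
    amp_jitter : half-width of the per-subject amplitude multiplier
                 (multiplier drawn in [1 - amp_jitter, 1 + amp_jitter])
    """

    name: str
    freq_band: tuple[float, float]
    amp_range: tuple[float, float]
    rest_fraction: float = 0.0
    axis_ratios: tuple[float, float, float] = (1.0, 0.5, 0.3)
    drift_sigma: float = 0.02
    amp_jitter: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.rest_fraction <= 1:
            raise ValueError("rest_fraction must be in [0, 1]")
        if self.freq_band[0] > self.freq_band[1] or self.freq_band[0] <= 0:
            raise ValueError(f"invalid freq_band {self.freq_band}")
        if self.amp_range[0] > self.amp_range[1] or self.amp_range[0] < 0:
            raise ValueError(f"invalid amp_range {self.amp_range}")


#: Default activity set: distinct frequency bands and amplitudes, mimicking
#: a slow large-sweep chore, a mid-band wave and a fast small-amplitude
#: exercise — the kinds of movement-rich actions kept in the study data.
DEFAULT_ACTIVITIES: tuple[ActivitySpec, ...] = (
    ActivitySpec("sweeping", freq_band=(0.7, 1.1), amp_range=(0.22, 0.34)),
    ActivitySpec("waving", freq_band=(1.6, 2.2), amp_range=(0.10, 0.16)),
    ActivitySpec("exercising", freq_band=(2.6, 3.2), amp_range=(0.05, 0.09)),
)


@dataclass
class SynthConfig:
    n_subjects: int = 10
    activities: tuple[ActivitySpec, ...] = DEFAULT_ACTIVITIES
    duration_s: float = 10.0
    fps: float = 30.0
    accel_hz: float = 50.0
    canvas: tuple[int, int] = (64, 64)
    noise_sigma: float = 0.05  # accel noise std, g
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.accel_hz < self.fps:
            raise ValueError("accel_hz must be >= fps")

    @property
    def subject_ids(self) -> list[str]:
        return [f"Sub{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class MotionTrace:
    """Latent motion of one (subject, activity) segment.

    body_xy : T x 2 body-centre trajectory in pixels (canvas coordinates)
    wrist_xyz : T x 3 wrist position in metres, shoulder-relative
    rest_mask : T booleans, True while the wrist is held static
    """

    body_xy: np.ndarray
    wrist_xyz: np.ndarray
    rest_mask: np.ndarray
    fps: float
    # rendering traits (per subject)
    body_axes: tuple[float, float] = (7.0, 14.0)  # ellipse semi-axes, px
    arm_scale: float = 50.0  # pixels per metre for the projected arm
    shoulder_offset: tuple[float, float] = (4.0, -8.0)  # (dx, dy) px from body centre

    def __post_init__(self) -> None:
        if not (np.isfinite(self.body_xy).all() and np.isfinite(self.wrist_xyz).all()):
            raise ValueError("trajectories must be finite")


def _trait_rng(subject_id: str, activity: str) -> np.random.Generator:
    """Deterministic per-(subject, activity) generator for identity traits."""
    return np.random.default_rng(
        [zlib.crc32(subject_id.encode()), zlib.crc32(activity.encode()), 0x51A7C4]
    )


def gen_motion(
    subject_id: str,
    spec: ActivitySpec,
    duration_s: float,
    fps: float,
    rng: np.random.Generator,
    canvas: tuple[int, int] = (64, 64),
) -> MotionTrace:
    """Generate the latent wrist + body motion of one segment.

    The wrist follows a subject-specific sum of sinusoids inside the
    activity's frequency band (dominant component plus a weak second
    harmonic) with smooth low-frequency drift; the per-subject amplitude
    multiplier, base frequency and phases come from a generator seeded by
    the subject identity, so identity is encoded in the motion itself.
    During the rest segment (if any) the wrist is held fixed.
    """
    T = int(round(duration_s * fps))
    t = np.arange(T) / fps
    traits = _trait_rng(subject_id, spec.name)

    f0 = traits.uniform(*spec.freq_band)
    base_amp = traits.uniform(*spec.amp_range)
    amp_mult = 1.0 + spec.amp_jitter * traits.uniform(-1.0, 1.0)
    amp = base_amp * amp_mult
    phases = traits.uniform(0, 2 * np.pi, size=3)
    harm_w = traits.uniform(0.1, 0.25)

    rx, ry, rz = spec.axis_ratios
    wrist = np.empty((T, 3))
    for k, (ratio, ph) in enumerate(zip((rx, ry, rz), phases)):
        main = np.sin(2 * np.pi * f0 * t + ph)
        harm = harm_w * np.sin(2 * np.pi * 2 * f0 * t + 2.1 * ph)
        wrist[:, k] = amp * ratio * (main + harm) / (1 + harm_w)

    if spec.drift_sigma > 0:
        drift = rng.standard_normal((T, 3))
        drift = gaussian_filter1d(drift, sigma=max(fps, 1.0), axis=0, mode="nearest")
        sd = drift.std(axis=0)
        sd[sd == 0] = 1.0
        wrist += spec.drift_sigma * drift / sd

    rest_mask = np.zeros(T, dtype=bool)
    n_rest = int(round(spec.rest_fraction * T))
    if n_rest > 0:
        rest_start = T - n_rest  # rest placed at the end of the segment
        rest_mask[rest_start:] = True
        hold = wrist[max(rest_start - 1, 0)].copy()
        wrist[rest_start:] = hold

    H, W = canvas
    traits2 = _trait_rng(subject_id, "body")
    body_b = traits2.uniform(0.18, 0.24) * H  # vertical semi-axis
    body_a = body_b * traits2.uniform(0.45, 0.6)
    # largest default gesture (~0.34 m) projects to ~25% of the canvas width
    arm_scale = (0.25 * W / 0.34) * traits2.uniform(0.9, 1.1)
    shoulder = (0.6 * body_a, -0.5 * body_b)

    centre = np.array([W / 2.0, H / 2.0])
    wander = rng.standard_normal((T, 2))
    wander = gaussian_filter1d(wander, sigma=2 * max(fps, 1.0), axis=0, mode="nearest")
    sd = wander.std(axis=0)
    sd[sd == 0] = 1.0
    body_xy = centre + 0.05 * min(H, W) * wander / sd
    margin_x = body_a + 2
    margin_y = body_b + 2
    body_xy[:, 0] = np.clip(body_xy[:, 0], margin_x, W - 1 - margin_x)
    body_xy[:, 1] = np.clip(body_xy[:, 1], margin_y, H - 1 - margin_y)
    if n_rest > 0:
        body_xy[rest_mask] = body_xy[max(T - n_rest - 1, 0)]

    return MotionTrace(
        body_xy=body_xy,
        wrist_xyz=wrist,
        rest_mask=rest_mask,
        fps=fps,
        body_axes=(body_a, body_b),
        arm_scale=arm_scale,
        shoulder_offset=shoulder,
    )


def derive_accel(
    trace: MotionTrace,
    accel_hz: float,
    noise_sigma: float,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> list[AccelSample]:
    """Derive the wearable's samples from the latent wrist trajectory.

    Acceleration is the second central difference of ``wrist_xyz`` on the
    video-frame grid (in m/s^2), linearly resampled at ``accel_hz``,
    converted to g-units, with constant 1 g gravity on z and i.i.d. Gaussian
    noise of std ``noise_sigma`` (g) on every channel.
    """
    w = np.asarray(trace.wrist_xyz, dtype=float)
    T = w.shape[0]
    if T < 3:
        raise ValueError(f"trace must have at least 3 samples, got {T}")
    fps = trace.fps
    # second central difference on the frame grid; endpoints replicated
    acc_frames = np.empty_like(w)
    acc_frames[1:-1] = (w[2:] - 2 * w[1:-1] + w[:-2]) * fps**2
    acc_frames[0] = acc_frames[1]
    acc_frames[-1] = acc_frames[-2]

    t_frames = np.arange(T) / fps
    n = int(np.floor(t_frames[-1] * accel_hz)) + 1
    t_acc = np.arange(n) / accel_hz
    acc = np.column_stack([np.interp(t_acc, t_frames, acc_frames[:, k]) for k in range(3)])
    acc /= GRAVITY_MS2
    acc[:, 2] += 1.0  # gravity
    if noise_sigma > 0:
        acc = acc + rng.normal(0.0, noise_sigma, size=acc.shape)
    return [AccelSample(t0 + float(ti), ai) for ti, ai in zip(t_acc, acc)]


def render_silhouette(
    trace: MotionTrace,
    canvas: tuple[int, int],
    fps: float,
    rng: np.random.Generator | None = None,
) -> tuple[list[MaskFrame], list[BoundingBox]]:
    """Render the binary silhouette stream and its tight bounding boxes.

    Each frame is one connected blob: a body ellipse at the body centre plus
    a 2-pixel-wide arm from the shoulder to the projected wrist, ending in a
    small hand disk.  The camera projection keeps wrist (x, y) and discards
    z, reproducing the 2-D-video / 3-D-IMU modality asymmetry.  Blobs that
    would leave the canvas are clipped at its edge (logged once).
    """
    H, W = canvas
    T = trace.body_xy.shape[0]
    a, b = trace.body_axes
    sdx, sdy = trace.shoulder_offset
    frames: list[MaskFrame] = []
    boxes: list[BoundingBox] = []
    clipped = False
    for i in range(T):
        grid = np.zeros((H, W), dtype=np.uint8)
        cx, cy = trace.body_xy[i]
        rr, cc = ellipse(cy, cx, b, a, shape=(H, W))
        grid[rr, cc] = 1
        sx, sy = cx + sdx, cy + sdy
        wx = sx + trace.arm_scale * trace.wrist_xyz[i, 0]
        wy = sy - trace.arm_scale * trace.wrist_xyz[i, 1]  # image rows grow downwards
        if not (0 <= wx < W and 0 <= wy < H):
            clipped = True
        wxc = int(np.clip(round(wx), 0, W - 1))
        wyc = int(np.clip(round(wy), 0, H - 1))
        syc = int(np.clip(round(sy), 0, H - 1))
        sxc = int(np.clip(round(sx), 0, W - 1))
        rr, cc = line(syc, sxc, wyc, wxc)
        grid[rr, cc] = 1
        grid[np.clip(rr + 1, 0, H - 1), cc] = 1  # 2-px-wide arm
        rr, cc = disk((wyc, wxc), 2.0, shape=(H, W))
        grid[rr, cc] = 1
        rows = np.flatnonzero(grid.any(axis=1))
        cols = np.flatnonzero(grid.any(axis=0))
        boxes.append(
            BoundingBox(
                frame_index=i,
                x=int(cols[0]),
                y=int(rows[0]),
                w=int(cols[-1] - cols[0] + 1),
                h=int(rows[-1] - rows[0] + 1),
                track_id=0,
            )
        )
        frames.append(MaskFrame(grid, i))
    if clipped:
        logger.warning("silhouette blob clipped at canvas edge for at least one frame")
    return frames, boxes


@dataclass
class StreamBundle:
    """One generated (subject, activity) stream, in memory."""

    meta: StreamMeta
    masks: list[MaskFrame]
    boxes: list[BoundingBox]
    accel: list[AccelSample]
    trace: MotionTrace = field(repr=False, default=None)


def gen_streams(config: SynthConfig) -> list[StreamBundle]:
    """Generate all (subject, activity) streams of a dataset in memory.

    Deterministic under ``config.seed``: stream order and the per-stream
    random state are fixed by the (subject, activity) enumeration order.
    """
    ss = np.random.SeedSequence(config.seed)
    n_streams = config.n_subjects * len(config.activities)
    children = ss.spawn(n_streams)
    bundles = []
    k = 0
    for subject_id in config.subject_ids:
        for spec in config.activities:
            rng = np.random.default_rng(children[k])
            k += 1
            trace = gen_motion(
                subject_id, spec, config.duration_s, config.fps, rng, canvas=config.canvas
            )
            accel = derive_accel(trace, config.accel_hz, config.noise_sigma, rng)
            masks, boxes = render_silhouette(trace, config.canvas, config.fps, rng)
            meta = StreamMeta(
                subject_id=subject_id, activity=spec.name, session="s0", fps=config.fps, t0=0.0
            )
            bundles.append(StreamBundle(meta, masks, boxes, accel, trace))
    return bundles


def gen_dataset(config: SynthConfig, out_dir: str | Path) -> Manifest:
    """Generate and write a dataset in the on-disk formats; returns the
    manifest (also written to ``out_dir / manifest.yaml``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for bundle in gen_streams(config):
        stem = f"{bundle.meta.subject_id}_{bundle.meta.activity}_{bundle.meta.session}"
        mask_dir = out_dir / f"{stem}_masks"
        bbox_csv = out_dir / f"{stem}_bboxes.csv"
        accel_csv = out_dir / f"{stem}_accel.csv"
        write_mask_stream(mask_dir, bundle.masks)
        write_bbox_csv(bbox_csv, bundle.boxes)
        write_accel_csv(accel_csv, bundle.accel)
        entries.append(ManifestEntry(mask_dir, bbox_csv, accel_csv, bundle.meta))
    manifest = Manifest(entries)
    write_manifest(out_dir / "manifest.yaml", manifest)
    return manifest
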