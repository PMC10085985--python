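"""Synthetic fluorescein blue-light video generator with full ground truth.

Emulates the structure a TFBUT pipeline assumes in a slit-lamp recording:
a bright green corneal disc under cobalt-blue illumination, periodic blinks
(full eyelid closure), dark breakup spots that appear a configurable time
after each eye opening and grow, plus the unusable-frame artifacts that a
quality filter must remove (defocus blur, eyelash occluders). Every frame is
rendered from a per-frame seeded RNG, so a video is bit-identical whether
frames are materialized in full, sparsely, or twice.

Times are in seconds; frame ``i`` of an ``fps`` recording sits at t = i/fps
and t = 0 is the first frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import FrameSequence

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "FrameState",
    "schedule_blinks",
    "ground_truth",
    "scene_state",
    "render_frame",
    "generate_video",
    "generate_sliced",
    "oracle_frame_table",
    "write_video_dir",
    "load_ground_truth",
]

# Scene palette (RGB, [0, 1]): dark periocular background, fluorescein-green
# corneal disc, skin-toned eyelid during blink, near-black eyelash stroke.
BACKGROUND_RGB = (0.08, 0.10, 0.12)
DISC_RGB = (0.20, 0.85, 0.55)
EYELID_RGB = (0.30, 0.22, 0.20)
LASH_LEVEL = 0.05
EDGE_SOFT_PX = 1.5

# Minimum rendered spot radius at which a spot counts as visible (sets the
# per-frame positive label); the default initial spot radius exceeds it, so
# labels turn positive exactly at the configured breakup time.
VISIBILITY_RADIUS_PX = 3.0

_MIN_SEGMENT_S = 0.5  # a segment shorter than this cannot carry a measurement


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.

    Defaults describe the recording conditions of a hand-held smartphone
    slit-lamp exam: ~56 s videos at 30 fps, at least three blinks, and about
    a quarter of frames spoiled by blur or eyelashes.
    """

    duration_s: float = 56.1
    fps: int = 30
    resolution: tuple[int, int] = (720, 1280)  # (height, width)
    n_blinks: int = 3
    blink_duration_s: float = 0.3
    #: Per post-opening segment: seconds after eye opening at which breakup
    #: starts, or None for a segment with no breakup (censored). When the
    #: whole field is None, times are drawn per segment from the seed.
    true_breakup_times_s: tuple[float | None, ...] | None = None
    corneal_radius_frac: float = 0.35
    spot_growth_rate: float = 8.0  # px/s
    spot_initial_radius_px: float = 6.0
    spot_depth: float = 0.6  # fraction of disc intensity removed inside a spot
    noise_sd: float = 0.02
    artifact_rate: float = 0.2  # per open-eye frame; ~ the clinical exclusion rate
    blink_jitter_frac: float = 0.1  # jitter of blink times, fraction of spacing
    seed: int = 0
    enforce_device_profile: bool = False

    def __post_init__(self) -> None:
        if self.fps not in (30, 60):
            raise ValueError(f"fps must be 30 or 60, got {self.fps}")
        if self.n_blinks < 3:
            raise ValueError("a valid recording requires at least three blinks")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not (0.0 < self.spot_depth <= 1.0):
            raise ValueError("spot_depth must be in (0, 1]")
        h, w = self.resolution
        if h < 64 or w < 64:
            raise ValueError("resolution too small to render a corneal scene")
        if self.enforce_device_profile and not (720 <= h <= 1080 and 1280 <= w <= 1920):
            raise ValueError(
                f"resolution {self.resolution} outside the device range 720x1280..1080x1920"
            )
        if self.true_breakup_times_s is not None:
            if len(self.true_breakup_times_s) != self.n_blinks:
                raise ValueError(
                    "true_breakup_times_s must have one entry per post-opening segment "
                    f"({self.n_blinks}), got {len(self.true_breakup_times_s)}"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruth:
    """Everything the pipeline is later asked to recover."""

    timestamps_s: np.ndarray
    per_frame_labels: list[str]  # positive | negative | blink | artifact
    blink_schedule: list[tuple[float, float]]  # (close_time_s, open_time_s)
    segments: list[tuple[float, float]]  # (opening_time_s, end_time_s), post-opening
    segment_breakup_times_s: list[float | None]  # None = censored (no breakup)
    true_tfbut_s: float | None
    disc_center_xy: tuple[float, float]
    disc_radius_px: float
    spot_centers_xy: list[tuple[float, float] | None]

    @property
    def segment_lengths_s(self) -> list[float]:
        return [end - start for start, end in self.segments]


@dataclass
class FrameState:
    """Scene description of one frame, sufficient to render it."""

    frame_index: int
    timestamp_s: float
    eye_open: bool
    spots: list[tuple[float, float, float]]  # (cx, cy, radius_px), visible only
    artifact: str | None  # None | "blur" | "lash"
    label: str


def _rng(config: SimulationConfig, *stream) -> np.random.Generator:
    return np.random.default_rng((int(config.seed), *stream))


def schedule_blinks(config: SimulationConfig) -> list[tuple[float, float]]:
    """Blink closures, evenly spaced over the recording with seeded jitter.

    Returns (close_time_s, open_time_s) per blink. The open intervals between
    consecutive blinks (plus the leading and trailing ones) tile the rest of
    the recording.
    """
    n = config.n_blinks
    spacing = config.duration_s / (n + 1)
    if spacing - config.blink_duration_s < _MIN_SEGMENT_S:
        raise ValueError(
            f"duration {config.duration_s} s cannot fit {n} blinks of "
            f"{config.blink_duration_s} s with usable segments in between"
        )
    rng = _rng(config, 1)
    jitter_scale = config.blink_jitter_frac * spacing
    max_jitter = max(0.0, (spacing - config.blink_duration_s - _MIN_SEGMENT_S) / 2.0)
    jitter_scale = min(jitter_scale, max_jitter)
    closes = spacing * np.arange(1, n + 1)
    closes = closes + rng.uniform(-jitter_scale, jitter_scale, size=n)
    schedule = [(float(c), float(c + config.blink_duration_s)) for c in closes]
    for (c0, o0), (c1, _) in zip(schedule, schedule[1:]):
        if c1 - o0 < _MIN_SEGMENT_S:
            raise ValueError("blink schedule leaves a segment shorter than the minimum")
    if config.duration_s - schedule[-1][1] < 0:
        raise ValueError("last blink extends past the end of the recording")
    return schedule


def _segments(config: SimulationConfig, schedule) -> list[tuple[float, float]]:
    """Post-opening segments: eye opening -> next blink closure (or video end)."""
    segs = []
    for k, (_, open_t) in enumerate(schedule):
        end = schedule[k + 1][0] if k + 1 < len(schedule) else config.duration_s
        segs.append((open_t, end))
    return segs


def _breakup_times(config: SimulationConfig, segs) -> list[float | None]:
    if config.true_breakup_times_s is not None:
        times = list(config.true_breakup_times_s)
        for bt, (start, end) in zip(times, segs):
            if bt is not None and not (0.0 < bt < end - start):
                raise ValueError(
                    f"breakup time {bt} s does not fall strictly inside its "
                    f"segment of length {end - start:.2f} s"
                )
        return times
    rng = _rng(config, 2)
    times = []
    for start, end in segs:
        length = end - start
        hi = min(10.0, 0.8 * length)
        times.append(float(rng.uniform(1.0, hi)) if hi > 1.0 else None)
    return times


def _disc_geometry(config: SimulationConfig) -> tuple[float, float, float]:
    h, w = config.resolution
    radius = config.corneal_radius_frac * min(h, w)
    rng = _rng(config, 3)
    cx = w / 2.0 + rng.uniform(-0.02, 0.02) * min(h, w)
    cy = h / 2.0 + rng.uniform(-0.02, 0.02) * min(h, w)
    return cx, cy, radius


def _spot_centers(config: SimulationConfig, segs) -> list[tuple[float, float] | None]:
    cx, cy, radius = _disc_geometry(config)
    rng = _rng(config, 4)
    centers: list[tuple[float, float] | None] = []
    for _ in segs:
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.1, 0.55) * radius
        centers.append((cx + rad * np.cos(ang), cy + rad * np.sin(ang)))
    return centers


def _eye_open_at(t: float, schedule) -> bool:
    for close_t, open_t in schedule:
        if close_t <= t < open_t:
            return False
    return True


def _artifact_at(config: SimulationConfig, frame_index: int) -> str | None:
    rng = _rng(config, 5, frame_index)
    if rng.random() >= config.artifact_rate:
        return None
    return "blur" if rng.random() < 0.5 else "lash"


def _spot_radius(config: SimulationConfig, dt: float) -> float:
    if dt < 0:
        return 0.0
    return config.spot_initial_radius_px + config.spot_growth_rate * dt


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """Analytic ground truth for a configuration; no rendering involved."""
    schedule = schedule_blinks(config)
    segs = _segments(config, schedule)
    breakups = _breakup_times(config, segs)
    disc_cx, disc_cy, disc_r = _disc_geometry(config)
    centers = _spot_centers(config, segs)
    n = config.n_frames
    ts = np.arange(n) / config.fps
    labels: list[str] = []
    for i, t in enumerate(ts):
        if not _eye_open_at(t, schedule):
            labels.append("blink")
            continue
        if _artifact_at(config, i) is not None:
            labels.append("artifact")
            continue
        positive = False
        for (start, end), bt in zip(segs, breakups):
            if bt is None or not (start <= t < end):
                continue
            if _spot_radius(config, t - (start + bt)) >= VISIBILITY_RADIUS_PX:
                positive = True
        labels.append("positive" if positive else "negative")
    uncensored = [bt for bt in breakups if bt is not None]
    true_tfbut = float(np.mean(uncensored[:3])) if uncensored else None
    return GroundTruth(
        timestamps_s=ts,
        per_frame_labels=labels,
        blink_schedule=schedule,
        segments=segs,
        segment_breakup_times_s=breakups,
        true_tfbut_s=true_tfbut,
        disc_center_xy=(disc_cx, disc_cy),
        disc_radius_px=disc_r,
        spot_centers_xy=centers,
    )


def scene_state(config: SimulationConfig, frame_index: int, gt: GroundTruth | None = None) -> FrameState:
    """Scene description of frame ``frame_index`` (what :func:`render_frame` draws)."""
    if gt is None:
        gt = ground_truth(config)
    t = frame_index / config.fps
    open_ = _eye_open_at(t, gt.blink_schedule)
    spots: list[tuple[float, float, float]] = []
    if open_:
        for (start, end), bt, center in zip(
            gt.segments, gt.segment_breakup_times_s, gt.spot_centers_xy
        ):
            if bt is None or center is None or not (start <= t < end):
                continue
            r = _spot_radius(config, t - (start + bt))
            if r > 0:
                spots.append((center[0], center[1], r))
    artifact = _artifact_at(config, frame_index) if open_ else None
    if not open_:
        label = "blink"
    elif artifact is not None:
        label = "artifact"
    elif any(r >= VISIBILITY_RADIUS_PX for *_, r in spots):
        label = "positive"
    else:
        label = "negative"
    return FrameState(
        frame_index=frame_index,
        timestamp_s=t,
        eye_open=open_,
        spots=spots,
        artifact=artifact,
        label=label,
    )


def _soft_disc(dist: np.ndarray, radius: float) -> np.ndarray:
    return np.clip((radius - dist) / EDGE_SOFT_PX, 0.0, 1.0)


def _draw_lash(img: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> None:
    """Dark curved stroke (eyelash) across the corneal region, in place."""
    h, w = config.resolution
    cx, cy, radius = _disc_geometry(config)
    x = np.linspace(cx - 1.2 * radius, cx + 1.2 * radius, 160)
    y0 = cy + rng.uniform(-0.5, 0.5) * radius
    curv = rng.uniform(0.2, 0.6) / radius
    tilt = rng.uniform(-0.3, 0.3)
    y = y0 + tilt * (x - cx) + curv * (x - cx) ** 2
    mask = np.zeros((h, w), dtype=bool)
    xi = np.round(x).astype(int)
    yi = np.round(y).astype(int)
    ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    mask[yi[ok], xi[ok]] = True
    mask = ndimage.binary_dilation(mask, iterations=2)
    img[mask] = LASH_LEVEL


@lru_cache(maxsize=8)
def _disc_weight_cached(h: int, w: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy = (np.arange(h, dtype=np.float32)[:, None] - np.float32(cy)) ** 2
    xx = (np.arange(w, dtype=np.float32)[None, :] - np.float32(cx)) ** 2
    dist = np.sqrt(yy + xx)
    out = _soft_disc(dist, radius).astype(np.float32)
    out.setflags(write=False)
    return out


def render_frame(config: SimulationConfig, state: FrameState) -> np.ndarray:
    """Render one frame as an HxWx3 float32 image in [0, 1]."""
    h, w = config.resolution
    img = np.empty((h, w, 3), dtype=np.float32)
    rng = _rng(config, 6, state.frame_index)
    if not state.eye_open:
        # eyelid fills the field: skin tone with a faint vertical shading
        shade = (1.0 - 0.15 * (np.arange(h) / max(h - 1, 1))).astype(np.float32)
        img[:] = np.asarray(EYELID_RGB, dtype=np.float32)
        img *= shade[:, None, None]
    else:
        cx, cy, radius = _disc_geometry(config)
        disc_w = _disc_weight_cached(h, w, cx, cy, radius)
        bg = np.asarray(BACKGROUND_RGB, dtype=np.float32)
        img[:] = bg
        img += disc_w[..., None] * (np.asarray(DISC_RGB, dtype=np.float32) - bg)
        for sx, sy, sr in state.spots:
            sdist = np.sqrt(
                (np.arange(h, dtype=np.float32)[:, None] - np.float32(sy)) ** 2
                + (np.arange(w, dtype=np.float32)[None, :] - np.float32(sx)) ** 2
            )
            spot_w = _soft_disc(sdist, sr) * disc_w
            img *= (1.0 - np.float32(config.spot_depth) * spot_w)[..., None]
        if state.artifact == "lash":
            _draw_lash(img, config, rng)
    if config.noise_sd > 0:
        img += np.float32(config.noise_sd) * rng.standard_normal(img.shape, dtype=np.float32)
    if state.artifact == "blur":
        sigma = max(4.0, 0.025 * min(h, w))
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    return np.clip(img, 0.0, 1.0, out=img)


def _materialize(config: SimulationConfig, indices: np.ndarray, gt: GroundTruth) -> list[np.ndarray]:
    return [render_frame(config, scene_state(config, int(i), gt)) for i in indices]


def _slice_grid(config: SimulationConfig, interval_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Tick times and nearest source frame indices, matching ``slice_video``."""
    n_ticks = int(np.floor(config.duration_s / interval_s + 1e-9)) + 1
    ticks = np.arange(n_ticks) * interval_s
    # nearest frame, ties to the earlier frame (same rule as slice_video)
    idx = np.ceil(ticks * config.fps - 0.5).astype(int)
    idx = np.clip(idx, 0, config.n_frames - 1)
    keep = np.ones(len(idx), dtype=bool)
    keep[1:] = np.diff(idx) > 0
    return ticks[keep], idx[keep]


def generate_video(config: SimulationConfig) -> tuple[FrameSequence, GroundTruth]:
    """Render the full recording at ``config.fps``."""
    gt = ground_truth(config)
    indices = np.arange(config.n_frames)
    frames = _materialize(config, indices, gt)
    seq = FrameSequence(
        frames=frames,
        timestamps_s=gt.timestamps_s,
        fps=config.fps,
        source_id=f"sim-{config.seed}",
    )
    return seq, gt


def generate_sliced(
    config: SimulationConfig, interval_s: float = 0.2
) -> tuple[FrameSequence, GroundTruth]:
    """Render only the frames the 200-ms slicing grid would retain.

    Equivalent to ``slice_video(generate_video(config)[0])`` frame for frame
    (per-frame seeding makes sparse and full materialization identical), at a
    fraction of the rendering cost.
    """
    gt = ground_truth(config)
    ticks, indices = _slice_grid(config, interval_s)
    frames = _materialize(config, indices, gt)
    seq = FrameSequence(
        frames=frames,
        timestamps_s=ticks,
        fps=1.0 / interval_s,
        source_id=f"sim-{config.seed}",
        source_indices=indices,
    )
    return seq, gt


def oracle_frame_table(gt: GroundTruth, config: SimulationConfig, interval_s: float = 0.2):
    """Frame table on the slicing grid filled from ground truth.

    Labels and quality statuses come straight from the simulator (an oracle
    classifier and an oracle quality filter), which isolates the timing logic
    downstream from the imaging components.
    """
    import pandas as pd

    ticks, indices = _slice_grid(config, interval_s)
    rows = []
    for t, i in zip(ticks, indices):
        lab = gt.per_frame_labels[i]
        if lab == "blink":
            quality, reason, label, conf = "fail", "no_cornea", "unknown", np.nan
        elif lab == "artifact":
            quality, reason, label, conf = "fail", "noise", "unknown", np.nan
        else:
            quality, reason, label = "pass", "", lab
            conf = 1.0 if lab == "positive" else 0.0
        rows.append(
            {
                "timestamp_s": float(t),
                "source_index": int(i),
                "quality": quality,
                "reason": reason,
                "label": label,
                "confidence": conf,
            }
        )
    return pd.DataFrame(rows)


def write_video_dir(path: str | Path, seq: FrameSequence, gt: GroundTruth | None = None) -> Path:
    """Write a recording as numbered PNG frames + manifest (+ ground-truth JSON)."""
    import imageio.v3 as iio
    import pandas as pd

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(seq.frames):
        name = f"frame_{i:05d}.png"
        iio.imwrite(path / name, (np.asarray(frame) * 255).astype(np.uint8))
        names.append(name)
    pd.DataFrame({"filename": names, "timestamp_s": seq.timestamps_s}).to_csv(
        path / "manifest.csv", index=False
    )
    if gt is not None:
        payload = {
            "blink_schedule": gt.blink_schedule,
            "segments": gt.segments,
            "segment_breakup_times_s": gt.segment_breakup_times_s,
            "true_tfbut_s": gt.true_tfbut_s,
            "per_frame_labels": [
                {"timestamp_s": float(t), "label": lab}
                for t, lab in zip(gt.timestamps_s, gt.per_frame_labels)
            ],
            "disc_center_xy": gt.disc_center_xy,
            "disc_radius_px": gt.disc_radius_px,
        }
        (path / "ground_truth.json").write_text(json.dumps(payload))
    return path


def load_ground_truth(path: str | Path) -> dict:
    """Ground-truth sidecar as written by :func:`write_video_dir`."""
    return json.loads(Path(path).read_text())
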