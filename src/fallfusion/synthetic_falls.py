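"""Synthetic fall-phase video generator.

Renders a single actor as a bright ellipse silhouette on a dark background,
one phase per clip, mirroring how real fall footage is manually cut into
phase sub-clips before windowing:

* ``standing`` — upright ellipse with a small lateral walking sway (a slow
  sinusoid plus a deterministic 1-pixel alternation, so adjacent frames
  always differ slightly, as a real standing person's silhouette does);
* ``falling`` — ellipse orientation rotating from 90 deg (vertical) to
  0 deg (horizontal) over ``fall_duration`` frames while the center drops
  toward the floor;
* ``fallen`` — horizontal ellipse lying at the floor, geometrically static
  (only pixel noise varies between frames);
* ``other`` — a sitting motion: the vertical half-axis shrinks to ~60% over
  ``sit_duration`` frames with the silhouette's base fixed, then holds.

Gaussian pixel noise of standard deviation ``noise_sigma`` is added to every
frame. With ``noise_sigma=0`` a fallen clip is bit-static, so its fused
images are exactly achromatic. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as _ellipse

from .fusion import FusedStack
from .video_io import PHASES, RawClip, write_clip


@dataclass(frozen=True)
class SceneConfig:
    """Rendering parameters of the simulator.

    ``image_size`` is the native (pre-resize) frame size; ``actor_half_axes``
    is the (major, minor) half-axis pair of the ellipse silhouette in pixels;
    intensities are in [0, 1].
    """

    image_size: tuple[int, int] = (240, 320)
    fps: float = 30.0
    n_clips_per_class: int = 10
    frame_count_range: tuple[int, int] = (63, 144)
    actor_half_axes: tuple[float, float] = (55.0, 16.0)
    fall_duration: int = 24
    sit_duration: int = 20
    noise_sigma: float = 0.02
    background: float = 0.15
    actor_intensity: float = 0.9
    floor_margin: int = 12
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.frame_count_range
        if not (0 < lo <= hi):
            raise ValueError("frame_count_range must satisfy 0 < lo <= hi")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def falling_orientation(t: int, fall_duration: int) -> float:
    """Major-axis angle (degrees from horizontal) at frame index ``t``.

    Linear from 90 deg at t=0 to 0 deg at t = fall_duration - 1, then 0.
    """
    if fall_duration <= 1:
        return 0.0 if t > 0 else 90.0
    frac = min(t / (fall_duration - 1), 1.0)
    return 90.0 * (1.0 - frac)


def _render_frame(cfg: SceneConfig, center, half_axes, theta_deg: float) -> np.ndarray:
    h, w = cfg.image_size
    frame = np.full((h, w), cfg.background, dtype=np.float64)
    a, b = half_axes
    rr, cc = _ellipse(
        center[0],
        center[1],
        a,
        b,
        shape=(h, w),
        rotation=math.radians(90.0 - theta_deg),
    )
    frame[rr, cc] = cfg.actor_intensity
    return frame


def render_clip(phase: str, cfg: SceneConfig = SceneConfig(), seed: int = 0) -> RawClip:
    """Render one single-phase clip; frame count is drawn uniformly from
    ``cfg.frame_count_range``. Same seed, same clip, bit for bit."""
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    rng = np.random.default_rng(seed)
    h, w = cfg.image_size
    lo, hi = cfg.frame_count_range
    n_frames = int(rng.integers(lo, hi + 1))
    a, b = cfg.actor_half_axes
    floor_r = h - cfg.floor_margin
    mid_c = w / 2.0
    stand_r = floor_r - a  # upright center row
    lie_r = floor_r - b  # lying center row

    frames = np.empty((n_frames, h, w), dtype=np.float64)
    for t in range(n_frames):
        if phase == "standing":
            sway = 6.0 * math.sin(2.0 * math.pi * t / 20.0) + (t % 2)
            frames[t] = _render_frame(cfg, (stand_r, mid_c + sway), (a, b), 90.0)
        elif phase == "falling":
            theta = falling_orientation(t, cfg.fall_duration)
            frac = 1.0 - theta / 90.0
            center_r = stand_r + frac * (lie_r - stand_r)
            center_c = mid_c + frac * 0.8 * a  # body pivots sideways as it falls
            frames[t] = _render_frame(cfg, (center_r, center_c), (a, b), theta)
        elif phase == "fallen":
            frames[t] = _render_frame(cfg, (lie_r, mid_c), (a, b), 0.0)
        else:  # other: sitting down
            frac = min(t / max(cfg.sit_duration - 1, 1), 1.0)
            a_t = a * (1.0 - 0.4 * frac)
            frames[t] = _render_frame(cfg, (floor_r - a_t, mid_c), (a_t, b), 90.0)
        if cfg.noise_sigma > 0:
            frames[t] += rng.normal(0.0, cfg.noise_sigma, size=(h, w))
    np.clip(frames, 0.0, 1.0, out=frames)
    return RawClip(frames=frames, fps=cfg.fps, label=phase, source_id=f"{phase}_{seed}")


def make_dataset(cfg: SceneConfig = SceneConfig()) -> tuple[list[RawClip], list[dict]]:
    """Render ``n_clips_per_class`` clips for each of the four phases.

    Returns the clips plus a manifest (one dict per clip: source id, label,
    frame count, fps).
    """
    if cfg.n_clips_per_class < 1:
        raise ValueError("n_clips_per_class must be >= 1")
    master = np.random.default_rng(cfg.seed)
    clips, manifest = [], []
    for phase in PHASES:
        for i in range(cfg.n_clips_per_class):
            clip_seed = int(master.integers(2**31))
            clip = render_clip(phase, cfg, seed=clip_seed)
            clip.source_id = f"{phase}_{i:03d}"
            clips.append(clip)
            manifest.append(
                {
                    "source_id": clip.source_id,
                    "label": phase,
                    "n_frames": clip.n_frames,
                    "fps": cfg.fps,
                }
            )
    return clips, manifest


def write_dataset(clips: list[RawClip], manifest: list[dict], directory) -> Path:
    """Write clips as frame directories plus a top-level ``manifest.json``,
    in the layout :func:`fallfusion.video_io.load_clip` reads back."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for clip in clips:
        write_clip(clip, directory / clip.source_id)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_dataset(directory) -> list[RawClip]:
    """Read back a dataset written by :func:`write_dataset`."""
    from .video_io import load_clip

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return [load_clip(directory / m["source_id"]) for m in manifest]


def standing_fallen_heuristic(stack: FusedStack) -> str:
    """Classify standing vs fallen from the chroma of the last fused image.

    A fallen actor is motionless, so B4 carries (near-)zero chroma; a
    standing actor's sway puts chroma mass at the silhouette, well above the
    floor. Used as a separability guarantee for the simulator, not as a
    detector.
    """
    ch = stack.images[3].chroma()
    mass = ch.sum()
    if mass < 1e-9:
        return "fallen"
    rows = np.arange(ch.shape[0], dtype=np.float64)
    centroid = (ch.sum(axis=1) @ rows) / mass
    return "standing" if centroid < 0.75 * ch.shape[0] else "fallen"
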