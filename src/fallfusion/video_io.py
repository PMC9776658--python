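"""Frame and clip I/O: loading videos/frame directories, grayscale conversion,
resizing to the canonical 128x128 frame, and writing fused stacks to disk.

All pixel data is float in [0, 1] internally; 8-bit quantization happens only
at file boundaries, so the two fusion levels never accumulate rounding error.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

#: Side length of the canonical preprocessed frame.
FRAME_SIZE = 128

#: The four fall phases used as class labels, in canonical index order.
PHASES = ("standing", "falling", "fallen", "other")

#: ITU-R BT.601 luminance weights for RGB -> gray reduction.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
_CLIP_META = "clip.json"


@dataclass
class RawClip:
    """A labeled video clip held in memory.

    Attributes
    ----------
    frames : ndarray
        Shape ``(T, H, W)`` or ``(T, H, W, 3)``, float in [0, 1]. All frames
        share one native size.
    fps : float
        Nominal frame rate (defaults to 30).
    label : str or None
        One of :data:`PHASES`, or ``None`` for unlabeled footage.
    source_id : str
        Opaque identifier of the clip's origin.
    """

    frames: np.ndarray
    fps: float = 30.0
    label: Optional[str] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4) or len(self.frames) < 1:
            raise ValueError(
                "clip frames must be a (T,H,W) or (T,H,W,3) array with T >= 1"
            )
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise ValueError("color clips must have exactly 3 channels")
        if self.label is not None and self.label not in PHASES:
            raise ValueError(f"label must be one of {PHASES} or None, got {self.label!r}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _as_float(image: np.ndarray) -> np.ndarray:
    """Map integer images to [0,1]; pass floats through unchanged."""
    if np.issubdtype(image.dtype, np.integer):
        scale = float(np.iinfo(image.dtype).max)
        return image.astype(np.float64) / scale
    return image.astype(np.float64)


def to_gray_frame(image: np.ndarray) -> np.ndarray:
    """Convert an image to the canonical 128x128 single-channel frame.

    3-channel inputs are reduced with BT.601 luminance weights
    (0.299 R + 0.587 G + 0.114 B) before resizing. Integer-multiple
    downscales use exact block (area) averaging; other size changes use
    anti-aliased bilinear interpolation. Output values are clamped to [0, 1].

    Parameters
    ----------
    image : ndarray
        2-D grayscale or 3-D RGB image of arbitrary size. Integer dtypes are
        interpreted on their full range (e.g. uint8 / 255).

    Returns
    -------
    ndarray
        ``(128, 128)`` float64 array in [0, 1].
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3 and image.shape[-1] == 1:
        image = image[..., 0]
    if image.ndim not in (2, 3) or (image.ndim == 3 and image.shape[-1] != 3):
        raise ValueError(f"expected 2-D or (H,W,3) image, got shape {image.shape}")
    image = _as_float(image)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    if image.ndim == 3:
        image = image @ LUMA_WEIGHTS
    h, w = image.shape
    if (h, w) != (FRAME_SIZE, FRAME_SIZE):
        if h % FRAME_SIZE == 0 and w % FRAME_SIZE == 0:
            # exact area average for integer downscale factors
            fh, fw = h // FRAME_SIZE, w // FRAME_SIZE
            image = image.reshape(FRAME_SIZE, fh, FRAME_SIZE, fw).mean(axis=(1, 3))
        else:
            image = _sk_resize(
                image,
                (FRAME_SIZE, FRAME_SIZE),
                order=1,
                anti_aliasing=(h > FRAME_SIZE or w > FRAME_SIZE),
                preserve_range=True,
            )
    return np.clip(image, 0.0, 1.0)


def clip_to_gray_frames(clip: RawClip) -> np.ndarray:
    """Preprocess every frame of a clip; returns ``(T, 128, 128)``."""
    return np.stack([to_gray_frame(f) for f in clip.frames])


def _frame_files(directory: Path) -> list[Path]:
    files = [
        p
        for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in _IMAGE_EXTS
    ]
    # strict lexicographic order on names: deterministic across filesystems
    return sorted(files, key=lambda p: p.name)


def load_clip(path, label: Optional[str] = None) -> RawClip:
    """Load a clip from a frame directory or a video file.

    A directory is read as lexicographically ordered frame images; a sidecar
    ``clip.json`` (written by :func:`write_clip`) supplies fps / label /
    source id when present. An explicit ``label`` argument overrides the
    sidecar. Video containers are attempted through imageio and raise
    ``OSError`` when no decoder is available.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file or directory: {path}")
    fps, source_id, meta_label = 30.0, path.name, None
    if path.is_dir():
        meta_path = path / _CLIP_META
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            fps = float(meta.get("fps", fps))
            source_id = meta.get("source_id", source_id)
            meta_label = meta.get("label")
        files = _frame_files(path)
        if not files:
            raise ValueError(f"no decodable frames in {path}")
        frames = [_as_float(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame sizes in {path}: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        try:
            frames = [_as_float(f) for f in iio.imiter(path)]
            meta = iio.immeta(path)
            fps = float(meta.get("fps", fps))
        except Exception as exc:  # no decoder / corrupt container
            raise OSError(f"cannot decode video {path}: {exc}") from exc
        if not frames:
            raise ValueError(f"zero decodable frames in {path}")
        stack = np.stack(frames)
        if stack.ndim == 4 and stack.shape[-1] == 4:
            stack = stack[..., :3]
    return RawClip(frames=stack, fps=fps, label=label or meta_label, source_id=source_id)


def write_clip(clip: RawClip, directory) -> Path:
    """Write a clip as zero-padded 8-bit PNG frames plus a ``clip.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(clip.frames):
        data = np.clip(np.asarray(frame, dtype=np.float64), 0.0, 1.0)
        iio.imwrite(directory / f"frame_{i:05d}.png", (data * 255).round().astype(np.uint8))
    meta = {
        "fps": clip.fps,
        "label": clip.label,
        "source_id": clip.source_id or directory.name,
        "n_frames": clip.n_frames,
    }
    (directory / _CLIP_META).write_text(json.dumps(meta, indent=1))
    return directory


def write_fused_stack(
    stack_pixels: np.ndarray,
    directory,
    clip_id: str,
    window_index: int,
    frame_range: tuple[int, int],
    label: Optional[str] = None,
) -> list[Path]:
    """Write one fused stack as four PNGs plus a JSON sidecar manifest.

    Files are named ``<clip_id>_w<window_idx>_b<1..4>.png``; the sidecar
    records clip id, label, window index and frame range.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack_pixels = np.asarray(stack_pixels)
    if stack_pixels.shape != (4, FRAME_SIZE, FRAME_SIZE, 3):
        raise ValueError(f"expected (4,128,128,3) stack, got {stack_pixels.shape}")
    paths = []
    for b in range(4):
        p = directory / f"{clip_id}_w{window_index}_b{b + 1}.png"
        iio.imwrite(p, (np.clip(stack_pixels[b], 0, 1) * 255).round().astype(np.uint8))
        paths.append(p)
    sidecar = directory / f"{clip_id}_w{window_index}.json"
    sidecar.write_text(
        json.dumps(
            {
                "clip_id": clip_id,
                "label": label,
                "window_index": window_index,
                "frame_range": list(frame_range),
            },
            indent=1,
        )
    )
    return paths


def read_fused_stack(directory, clip_id: str, window_index: int) -> np.ndarray:
    """Read back a fused stack written by :func:`write_fused_stack`."""
    directory = Path(directory)
    imgs = []
    for b in range(4):
        p = directory / f"{clip_id}_w{window_index}_b{b + 1}.png"
        imgs.append(_as_float(iio.imread(p)))
    return np.stack(imgs)
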