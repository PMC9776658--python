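"""Two-level temporal false-color fusion.

A 16-frame grayscale window is reduced to four RGB images in two rounds of
pairwise fusion. The pairwise operator is a green-magenta composite: the
earlier frame drives the green channel, the later frame drives red and blue.
Pixels where the two frames agree stay gray (achromatic); pixels that changed
between the frames become colored, so inter-frame motion shows up as chroma.
Each final image summarizes four consecutive frames: 16 frames -> 8 level-1
images -> 4 level-2 images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video_io import FRAME_SIZE, LUMA_WEIGHTS

WINDOW_LEN = 16  #: frames consumed by one two-level fusion


@dataclass(frozen=True)
class FusedImage:
    """A 128x128x3 false-color composite of two grayscale inputs."""

    pixels: np.ndarray  # (128, 128, 3) in [0, 1]
    level: int  # 1 or 2

    def chroma(self) -> np.ndarray:
        """Per-pixel chroma: max channel minus min channel. Zero wherever the
        two fused inputs were equal."""
        return self.pixels.max(axis=-1) - self.pixels.min(axis=-1)


@dataclass(frozen=True)
class FusedStack:
    """The model's input sample: the four level-2 images B1..B4, in order."""

    images: tuple[FusedImage, FusedImage, FusedImage, FusedImage]

    def __post_init__(self):
        if len(self.images) != 4:
            raise ValueError("a fused stack holds exactly 4 images")

    def as_array(self) -> np.ndarray:
        """Stack pixels into a ``(4, 128, 128, 3)`` array."""
        return np.stack([im.pixels for im in self.images])


def _check_gray(frame: np.ndarray, name: str) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != (FRAME_SIZE, FRAME_SIZE):
        raise ValueError(
            f"{name} must be a ({FRAME_SIZE},{FRAME_SIZE}) gray frame, got {frame.shape}"
        )
    return frame


def fuse_pair(a: np.ndarray, b: np.ndarray, level: int = 1) -> FusedImage:
    """Fuse two grayscale frames into a green-magenta false-color composite.

    Channel assignment: G = ``a`` (earlier frame), R = B = ``b`` (later
    frame). Where a == b the result is achromatic; where they differ the
    pixel leans green (brighter in ``a``) or magenta (brighter in ``b``).
    Purely a channel reassignment, so values never leave [0, 1].
    """
    a = _check_gray(a, "a")
    b = _check_gray(b, "b")
    return FusedImage(pixels=np.stack([b, a, b], axis=-1), level=level)


def luminance(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luminance of an RGB image (same weights as frame preprocessing)."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected (H,W,3), got {rgb.shape}")
    return rgb @ LUMA_WEIGHTS


def two_level_fuse(window) -> FusedStack:
    """Reduce a 16-frame window to the four level-2 fused images B1..B4.

    Level 1 fuses every odd frame with the one following it
    (A_k = fuse(F_{2k-1}, F_{2k}), k = 1..8). Each A_k is reduced to
    luminance, and level 2 fuses consecutive pairs again
    (B_k = fuse(lum A_{2k-1}, lum A_{2k}), k = 1..4). B_k therefore depends
    only on frames 4k-3 .. 4k.
    """
    frames = [_check_gray(f, f"frame {i}") for i, f in enumerate(window)]
    if len(frames) != WINDOW_LEN:
        raise ValueError(f"a fusion window holds exactly {WINDOW_LEN} frames, got {len(frames)}")
    level1 = [fuse_pair(frames[2 * k], frames[2 * k + 1], level=1) for k in range(8)]
    lum1 = [luminance(im.pixels) for im in level1]
    level2 = tuple(
        fuse_pair(lum1[2 * k], lum1[2 * k + 1], level=2) for k in range(4)
    )
    return FusedStack(images=level2)
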