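"""Sliding-window sampling of clips into 16-frame training sequences.

Consecutive windows start ``overlap_factor`` frames apart (the "overlapping
factor"), so an N-frame clip yields floor((N - 16) / overlap_factor + 1)
windows; a trailing remainder shorter than one window is discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .fusion import WINDOW_LEN, two_level_fuse
from .video_io import PHASES, RawClip, clip_to_gray_frames


@dataclass(frozen=True)
class WindowSpec:
    """Window length and start-index stride used to cut clips into samples."""

    window_len: int = WINDOW_LEN
    overlap_factor: int = 5

    def __post_init__(self):
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.overlap_factor < 1:
            raise ValueError("overlap_factor must be >= 1")


@dataclass(frozen=True)
class SampleRecord:
    """One labeled 16-frame window cut from a clip.

    ``frame_range`` is half-open and 0-based: the k-th window of a clip
    covers frames [k*overlap_factor, k*overlap_factor + window_len).
    """

    clip_id: str
    window_index: int
    frame_range: tuple[int, int]
    label: str


def count_windows(n_frames: int, spec: WindowSpec = WindowSpec()) -> int:
    """Number of windows an ``n_frames``-long clip yields under ``spec``.

    floor((n_frames - window_len) / overlap_factor + 1), or 0 when the clip
    is shorter than one window (short remainders are discarded).
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    if n_frames < spec.window_len:
        return 0
    return (n_frames - spec.window_len) // spec.overlap_factor + 1


def enumerate_windows(clip: RawClip, spec: WindowSpec = WindowSpec()) -> list[SampleRecord]:
    """List the windows of a labeled clip as :class:`SampleRecord` entries."""
    if clip.label is None:
        raise ValueError("cannot enumerate windows of an unlabeled clip")
    n = count_windows(clip.n_frames, spec)
    return [
        SampleRecord(
            clip_id=clip.source_id,
            window_index=k,
            frame_range=(k * spec.overlap_factor, k * spec.overlap_factor + spec.window_len),
            label=clip.label,
        )
        for k in range(n)
    ]


def build_sample_set(
    clips: Iterable[RawClip], spec: WindowSpec = WindowSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[SampleRecord]]:
    """Window, preprocess and fuse a collection of labeled clips.

    Returns
    -------
    X : ndarray, float32, shape (n_samples, 4, 128, 128, 3)
        Fused stacks, one per window.
    y : ndarray, int64
        Phase labels encoded by their index in :data:`~fallfusion.video_io.PHASES`.
    clip_ids : ndarray of str
        Source clip of each sample (used for grouped cross-validation splits).
    records : list of SampleRecord
    """
    X, y, ids, records = [], [], [], []
    for clip in clips:
        recs = enumerate_windows(clip, spec)
        if not recs:
            continue
        gray = clip_to_gray_frames(clip)
        for rec in recs:
            s, e = rec.frame_range
            stack = two_level_fuse(gray[s:e])
            X.append(stack.as_array().astype(np.float32))
            y.append(PHASES.index(rec.label))
            ids.append(rec.clip_id)
            records.append(rec)
    if not X:
        raise ValueError("no clip yielded any window")
    return np.stack(X), np.asarray(y, dtype=np.int64), np.asarray(ids), records


# ---------------------------------------------------------------------------
# manifest I/O and dataset bookkeeping


def save_manifest(records: list[SampleRecord], path) -> None:
    """Write a list of sample records as a JSON array."""
    Path(path).write_text(json.dumps([asdict(r) for r in records], indent=1))


def load_manifest(path) -> list[SampleRecord]:
    raw = json.loads(Path(path).read_text())
    return [
        SampleRecord(
            clip_id=r["clip_id"],
            window_index=r["window_index"],
            frame_range=tuple(r["frame_range"]),
            label=r["label"],
        )
        for r in raw
    ]


@dataclass(frozen=True)
class DatasetSummary:
    """Per-class clip/sequence bookkeeping for a prepared dataset."""

    videos_per_class: dict[str, int]
    sequences_per_class: dict[str, int]

    @property
    def total_videos(self) -> int:
        return sum(self.videos_per_class.values())

    @property
    def total_sequences(self) -> int:
        return sum(self.sequences_per_class.values())


def summarize_records(records: Iterable[SampleRecord]) -> DatasetSummary:
    """Tally videos and sequences per class from a sample manifest."""
    vids: dict[str, set] = {p: set() for p in PHASES}
    seqs: dict[str, int] = {p: 0 for p in PHASES}
    for r in records:
        vids[r.label].add(r.clip_id)
        seqs[r.label] += 1
    return DatasetSummary(
        videos_per_class={p: len(v) for p, v in vids.items()},
        sequences_per_class=seqs,
    )
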