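"""Core domain containers: trajectories, segments and segmentations.

Conventions used throughout the package:

* frame indices are 0-based and segments are half-open ``[start, end)``;
* the within-segment Gaussian-process time index runs 1..k (k = segment
  length) and is derived from frame indices at exactly one place, segment
  extraction, so the two coordinate systems never mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["Trajectory", "Segment", "Segmentation"]


@dataclass(frozen=True)
class Trajectory:
    """A multivariate time series: ``frames`` is a T x D float matrix.

    Parameters
    ----------
    frames:
        Observed values, one row per frame, one column per dimension.
    id:
        Identifier used to tie segmentations back to their sequence.
    frame_rate:
        Optional sampling rate in frames per second.
    dim_names:
        Optional column names (kept from CSV headers).
    """

    frames: np.ndarray
    id: str = "seq"
    frame_rate: float | None = None
    dim_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(
                f"trajectory {self.id!r}: frames must be a T x D matrix "
                f"with T >= 1 and D >= 1, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"trajectory {self.id!r}: non-finite entries in frames")
        object.__setattr__(self, "frames", arr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_dims(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True, order=True)
class Segment:
    """A contiguous span ``[start, end)`` of one sequence with a class label."""

    sequence_id: str
    start: int
    end: int
    class_id: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"segment of {self.sequence_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.class_id < 0:
            raise ValueError(f"segment of {self.sequence_id!r}: negative class id")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Segmentation:
    """An ordered, contiguous, exhaustive partition of one sequence.

    Invariants enforced on construction: the first segment starts at 0,
    consecutive segments abut exactly, and all segments carry the same
    sequence id.
    """

    segments: tuple[Segment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("a segmentation must contain at least one segment")
        if segs[0].start != 0:
            raise ValueError(f"first segment must start at 0, got {segs[0].start}")
        sid = segs[0].sequence_id
        for prev, cur in zip(segs, segs[1:]):
            if cur.sequence_id != sid:
                raise ValueError("all segments must share one sequence id")
            if cur.start != prev.end:
                raise ValueError(
                    f"segments must be contiguous: [{prev.start},{prev.end}) "
                    f"followed by [{cur.start},{cur.end})"
                )
        object.__setattr__(self, "segments", segs)

    @classmethod
    def from_lengths(
        cls, sequence_id: str, lengths: Sequence[int], classes: Sequence[int]
    ) -> "Segmentation":
        if len(lengths) != len(classes):
            raise ValueError("lengths and classes must have equal length")
        segs = []
        t = 0
        for k, c in zip(lengths, classes):
            segs.append(Segment(sequence_id, t, t + int(k), int(c)))
            t += int(k)
        return cls(tuple(segs))

    @property
    def sequence_id(self) -> str:
        return self.segments[0].sequence_id

    @property
    def total_frames(self) -> int:
        return self.segments[-1].end

    def labels(self) -> np.ndarray:
        """Expand to a per-frame class vector of length ``total_frames``."""
        out = np.empty(self.total_frames, dtype=int)
        for seg in self.segments:
            out[seg.start : seg.end] = seg.class_id
        return out

    def boundaries(self) -> list[int]:
        """Interior boundaries (segment ends, excluding the final frame)."""
        return [seg.end for seg in self.segments[:-1]]

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)
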