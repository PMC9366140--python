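"""Protocol-aware 3-fold partition of latency points for cross-validation.

Latency series are autocorrelated time series with protocol-dependent
drifts, so random K-fold splitting is inappropriate.  Instead, within every
background-protocol segment the time-ordered latency points are cut into
three contiguous pieces of (near-)equal *point count* — not equal duration,
since point density follows the stimulation frequency — and piece k of every
segment joins fold k.  Each protocol is thereby represented in all folds,
and the assignment is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError
from .records import FiberRecord, ProtocolSegment

__all__ = [
    "FoldAssignment",
    "segment_points",
    "three_fold_split",
    "fold_rotations",
    "infer_segments",
]

N_FOLDS = 3


@dataclass
class FoldAssignment:
    """Per-latency-point fold labels (1..3) and protocol-segment indices (0-based)."""

    fold_labels: np.ndarray
    segment_ids: np.ndarray

    def __post_init__(self) -> None:
        self.fold_labels = np.asarray(self.fold_labels, dtype=np.int64)
        self.segment_ids = np.asarray(self.segment_ids, dtype=np.int64)
        if self.fold_labels.shape != self.segment_ids.shape:
            raise ValidationError("fold_labels and segment_ids must be equal-length")
        if self.fold_labels.size and not np.isin(
            self.fold_labels, np.arange(1, N_FOLDS + 1)
        ).all():
            raise ValidationError("fold labels must be in {1, 2, 3}")

    def __len__(self) -> int:
        return self.fold_labels.size

    def fold_sizes(self) -> tuple[int, ...]:
        return tuple(int((self.fold_labels == k).sum()) for k in range(1, N_FOLDS + 1))

    def to_frame(self, stimulus_times: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stim_time_s": stimulus_times,
                "segment_id": self.segment_ids,
                "fold": self.fold_labels,
            }
        )


def segment_points(record: FiberRecord) -> np.ndarray:
    """Map each latency point to the protocol segment containing it.

    Segments are half-open ``[start, end)``, so a point exactly at a shared
    boundary belongs to the later segment.  A point covered by no segment
    raises :class:`CoverageError` naming the offending time.
    """
    if not record.segments:
        raise CoverageError(f"record {record.fiber_id!r} has no protocol segments")
    t = record.latencies.stimulus_times
    starts = np.array([s.start for s in record.segments])
    ends = np.array([s.end for s in record.segments])
    idx = np.searchsorted(starts, t, side="right") - 1
    bad = (idx < 0) | (t >= ends[np.clip(idx, 0, None)])
    if bad.any():
        raise CoverageError(
            f"latency point at t={t[bad][0]:g} s falls outside every protocol segment"
        )
    return idx.astype(np.int64)


def three_fold_split(record: FiberRecord) -> FoldAssignment:
    """Deterministic protocol-aware 3-fold assignment of latency points.

    Within each segment the time-ordered points are cut into three
    contiguous pieces whose sizes differ by at most one (remainders go to
    the earlier pieces); piece k is labeled fold k.  A segment with fewer
    than three points cannot populate all folds: its points are assigned
    round-robin (1, 2, 3, ...) with a warning.
    """
    seg_ids = segment_points(record)
    labels = np.empty(seg_ids.shape, dtype=np.int64)
    for seg in np.unique(seg_ids):
        pos = np.flatnonzero(seg_ids == seg)  # already time-ordered
        m = pos.size
        if m < N_FOLDS:
            warnings.warn(
                f"protocol segment {seg} has only {m} latency point(s); "
                "assigning round-robin — it cannot populate all three folds",
                stacklevel=2,
            )
            labels[pos] = (np.arange(m) % N_FOLDS) + 1
            continue
        base, rem = divmod(m, N_FOLDS)
        sizes = [base + (1 if k < rem else 0) for k in range(N_FOLDS)]
        bounds = np.cumsum([0] + sizes)
        for k in range(N_FOLDS):
            labels[pos[bounds[k] : bounds[k + 1]]] = k + 1
    return FoldAssignment(labels, seg_ids)


def fold_rotations(assignment: FoldAssignment) -> list[tuple[np.ndarray, np.ndarray]]:
    """The three (train_index, test_index) rotations of the 3-fold assignment.

    Rotation r tests on fold r and trains on the other two; across the three
    rotations every point is tested exactly once.
    """
    rotations = []
    for k in range(1, N_FOLDS + 1):
        test = np.flatnonzero(assignment.fold_labels == k)
        train = np.flatnonzero(assignment.fold_labels != k)
        rotations.append((train, test))
    return rotations


def infer_segments(
    background_times: np.ndarray,
    *,
    rel_change: float = 0.25,
    min_pulses: int = 3,
) -> list[ProtocolSegment]:
    """Infer protocol segments from background pulse times (change-point helper).

    For records shipped without a protocol table, consecutive inter-pulse
    intervals are scanned for relative changes exceeding ``rel_change``;
    each constant-interval run becomes a segment whose frequency is the
    reciprocal median interval.  Explicit protocol tables always take
    precedence over this helper.
    """
    t = np.asarray(background_times, dtype=float)
    if t.size < min_pulses:
        raise ValidationError(
            f"need at least {min_pulses} background pulses to infer segments"
        )
    ipi = np.diff(t)
    change = np.abs(np.diff(ipi)) > rel_change * ipi[:-1]
    # change[i] flags a new regime starting at pulse i+1 (interval i+1 differs)
    boundaries = [0] + [i + 1 for i in np.flatnonzero(change)] + [ipi.size]
    segments: list[ProtocolSegment] = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if hi <= lo:
            continue
        freq = 1.0 / float(np.median(ipi[lo:hi]))
        start = t[lo] if not segments else segments[-1].end
        end = t[hi] + float(np.median(ipi[lo:hi]))
        if end <= start:
            continue
        segments.append(ProtocolSegment(start, end, freq))
    return segments
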