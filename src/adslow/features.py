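"""Spike-count history features over geometrically growing time windows.

For each background-locked response latency at time ``t`` the predictor
vector is the spike count of the fiber in a ladder of look-back windows
ending at ``t``: the shortest window has length ``T_min`` and each
subsequent window is 4x longer, up to ``T_max = T_min * 4**(N-1)``.

Windows are *inclusive* by default: the k-th count contains every spike of
the shorter windows, so ``s_1 <= s_2 <= ... <= s_N``.  The *exclusive*
variant (first differences, i.e. counts in the annuli between consecutive
windows) is provided for comparison but performs poorly in practice because
it produces very sparse vectors.

Window boundary convention: half-open ``[t - w, t)`` — a spike exactly at
``t - w`` counts, the response at ``t`` itself never counts, and exclusive
counts are an exact partition of the largest window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParameterError, ValidationError
from .records import FiberRecord, SpikeTrain

__all__ = [
    "WindowScheme",
    "FeatureRow",
    "FeatureMatrix",
    "window_lengths",
    "count_history",
    "featurize",
]

GROWTH_FACTOR = 4


def window_lengths(t_min: float, n: int, growth_factor: int = GROWTH_FACTOR) -> np.ndarray:
    """Window lengths ``[T_min * g**0, ..., T_min * g**(N-1)]`` in seconds.

    >>> window_lengths(0.25, 7)
    array([2.50e-01, 1.00e+00, 4.00e+00, 1.60e+01, 6.40e+01, 2.56e+02,
           1.02e+03])
    """
    if t_min <= 0:
        raise ParameterError(f"T_min must be > 0 s, got {t_min}")
    if n < 1:
        raise ParameterError(f"N must be >= 1, got {n}")
    if growth_factor <= 1:
        raise ParameterError(f"growth factor must be > 1, got {growth_factor}")
    return t_min * np.power(float(growth_factor), np.arange(n))


@dataclass(frozen=True)
class WindowScheme:
    """The ``(T_min, N, x growth_factor)`` spike-count window ladder."""

    t_min: float
    n: int
    growth_factor: int = GROWTH_FACTOR
    mode: str = "inclusive"

    def __post_init__(self) -> None:
        window_lengths(self.t_min, self.n, self.growth_factor)  # validates
        if self.mode not in ("inclusive", "exclusive"):
            raise ParameterError(f"mode must be inclusive or exclusive, got {self.mode!r}")

    @property
    def t_max(self) -> float:
        """Largest window length, ``T_min * growth_factor**(N-1)`` seconds."""
        return float(self.t_min * self.growth_factor ** (self.n - 1))

    @property
    def lengths(self) -> np.ndarray:
        return window_lengths(self.t_min, self.n, self.growth_factor)


@dataclass(frozen=True)
class FeatureRow:
    """One latency point's history-count vector and normalized-latency target."""

    stimulus_time: float
    counts: tuple[int, ...]
    target: float
    truncated: bool = False


@dataclass
class FeatureMatrix:
    """All feature rows of one fiber under one window scheme.

    ``counts`` has shape ``(n_rows, scheme.n)``; rows are ordered by
    ``stimulus_times``.  ``truncated`` flags rows whose largest window
    extends before the recording start (their counts cover only the
    available portion of history).
    """

    scheme: WindowScheme
    fiber_id: str
    stimulus_times: np.ndarray
    counts: np.ndarray
    targets: np.ndarray
    truncated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.truncated is None:
            self.truncated = np.zeros(len(self.targets), dtype=bool)
        if not (
            len(self.stimulus_times) == len(self.counts) == len(self.targets)
            == len(self.truncated)
        ):
            raise ValidationError("feature matrix arrays must share their length")
        if self.counts.ndim != 2 or self.counts.shape[1] != self.scheme.n:
            raise ValidationError(
                f"counts must be (n_rows, {self.scheme.n}), got {self.counts.shape}"
            )

    def __len__(self) -> int:
        return len(self.targets)

    def row(self, i: int) -> FeatureRow:
        return FeatureRow(
            float(self.stimulus_times[i]),
            tuple(int(c) for c in self.counts[i]),
            float(self.targets[i]),
            bool(self.truncated[i]),
        )

    def subset(self, index: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.scheme,
            self.fiber_id,
            self.stimulus_times[index],
            self.counts[index],
            self.targets[index],
            self.truncated[index],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, columns=[f"s_{k + 1}" for k in range(self.scheme.n)]
        )
        df.insert(0, "stim_time_s", self.stimulus_times)
        df["latency_norm"] = self.targets
        df["truncated_history"] = self.truncated.astype(int)
        return df


def count_history(spikes: SpikeTrain | np.ndarray, t: float, w: float) -> int:
    """Number of spikes in the half-open window ``[t - w, t)``.

    A spike exactly at ``t - w`` counts; a spike exactly at ``t`` (the
    response being predicted) does not.  An empty train yields 0.
    """
    if w <= 0:
        raise ParameterError(f"window length must be > 0 s, got {w}")
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    lo = np.searchsorted(times, t - w, side="left")
    hi = np.searchsorted(times, t, side="left")
    return int(hi - lo)


def _count_matrix(
    spike_times: np.ndarray, query_times: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """Inclusive counts for all (query, window) pairs; shape (n_queries, n_windows)."""
    hi = np.searchsorted(spike_times, query_times, side="left")
    lo = np.searchsorted(
        spike_times, query_times[:, None] - lengths[None, :], side="left"
    )
    return (hi[:, None] - lo).astype(np.int64)


def featurize(
    record: FiberRecord,
    scheme: WindowScheme,
    *,
    drop_truncated: bool = False,
) -> FeatureMatrix:
    """Build the feature matrix of ``record`` under ``scheme``.

    One row per latency point; the target is the normalized latency, so the
    record must have been normalized first.  Rows whose largest window
    reaches before the recording start are flagged ``truncated`` (their
    counts cover the available history) and optionally dropped.
    """
    if len(record.latencies) == 0:
        raise EmptyInputError(f"record {record.fiber_id!r} has no latency points")
    if record.latencies.norm is None:
        raise ValidationError(
            f"record {record.fiber_id!r} is not normalized; run normalize_latencies first"
        )
    t = record.latencies.stimulus_times
    lengths = scheme.lengths
    counts = _count_matrix(record.spikes.times, t, lengths)
    if scheme.mode == "exclusive":
        counts = np.diff(counts, axis=1, prepend=0)
    truncated = (t - scheme.t_max) < record.start_time
    fm = FeatureMatrix(
        scheme, record.fiber_id, t, counts, record.latencies.norm.copy(), truncated
    )
    if drop_truncated:
        fm = fm.subset(~fm.truncated)
    return fm
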