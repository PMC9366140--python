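"""Single-fiber recording bundles: domain types, I/O and preprocessing.

A *fiber record* holds everything the latency-prediction pipeline needs about
one C-fiber: the background-stimulation protocol segments, the stimulus
events (regular background pulses, extra electrical trains, mechanical
bursts), the fiber's full spike train, and the series of response latencies
locked to the background stimuli.

Latencies are measured in milliseconds from the background stimulus to the
onset of the evoked action potential.  Because absolute latency is dominated
by the electrode-to-ending conduction distance (millimetres in vitro, tens
of centimetres in human microneurography), the modeling pipeline works on
*normalized* latency: raw latency divided by a per-fiber baseline, so a
value of 1.05 means "5 % slower than baseline".

The on-disk representation is a directory bundle of plain CSV files
(``spikes.csv``, ``stimuli.csv``, ``protocol.csv``, ``latencies.csv``) with a
``fiber.json`` sidecar for identity and baseline metadata.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    FormatError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "StimulusEvent",
    "ProtocolSegment",
    "SpikeTrain",
    "LatencyPoint",
    "LatencySeries",
    "FiberRecord",
    "read_fiber_record",
    "write_fiber_record",
    "normalize_latencies",
    "remove_latency_outliers",
    "highpass_detrend",
]

#: Spike times closer than this (seconds) are treated as digitization duplicates.
SPIKE_TIME_RESOLUTION = 1e-6

STIMULUS_KINDS = ("background", "extra_electrical", "mechanical")


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus event.

    Parameters
    ----------
    time
        Onset in seconds from recording start.  For an extra electrical
        train this is the time of the train's first pulse.
    kind
        ``"background"``, ``"extra_electrical"`` or ``"mechanical"``.
    n_pulses
        Number of pulses in an electrical train, or the evoked spike count
        of a mechanical burst.
    pulse_frequency
        Within-train pulse frequency in Hz; 0 denotes a single pulse.
    distance_to_next_background
        Gap in milliseconds between the train's last pulse and the next
        background pulse (electrical trains only).
    amplitude
        Peak force in mN (mechanical bursts only).
    """

    time: float
    kind: str
    n_pulses: int = 1
    pulse_frequency: float = 0.0
    distance_to_next_background: float | None = None
    amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValidationError(f"unknown stimulus kind {self.kind!r}")
        if self.time < 0:
            raise ValidationError(f"stimulus time must be >= 0, got {self.time}")
        if self.n_pulses < 1:
            raise ValidationError(f"n_pulses must be >= 1, got {self.n_pulses}")
        if self.pulse_frequency < 0:
            raise ValidationError(
                f"pulse_frequency must be >= 0, got {self.pulse_frequency}"
            )
        if (
            self.distance_to_next_background is not None
            and self.distance_to_next_background <= 0
        ):
            raise ValidationError(
                "distance_to_next_background must be > 0 ms, got "
                f"{self.distance_to_next_background}"
            )


@dataclass(frozen=True)
class ProtocolSegment:
    """A stretch of recording with a constant background stimulation frequency.

    Segments are half-open intervals ``[start, end)`` in seconds.
    """

    start: float
    end: float
    background_frequency: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"segment start must precede end, got [{self.start}, {self.end})"
            )
        if self.background_frequency <= 0:
            raise ValidationError(
                f"background_frequency must be > 0 Hz, got {self.background_frequency}"
            )

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


class SpikeTrain:
    """A strictly increasing sequence of spike times (seconds).

    Duplicate times within :data:`SPIKE_TIME_RESOLUTION` are collapsed with
    a warning — they are digitization artifacts, not physiology.
    """

    __slots__ = ("times",)

    def __init__(self, times: Sequence[float] | np.ndarray):
        arr = np.asarray(times, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("spike times must be one-dimensional")
        if arr.size and np.any(np.diff(arr) < 0):
            bad = int(np.argmax(np.diff(arr) < 0)) + 1
            raise ValidationError(
                f"spike times must be sorted ascending; row {bad} "
                f"({arr[bad]:g}) precedes its predecessor"
            )
        if arr.size:
            keep = np.concatenate(([True], np.diff(arr) >= SPIKE_TIME_RESOLUTION))
            if not keep.all():
                warnings.warn(
                    f"collapsed {int((~keep).sum())} duplicate spike time(s) "
                    f"within {SPIKE_TIME_RESOLUTION:g} s",
                    stacklevel=2,
                )
                arr = arr[keep]
        self.times = arr

    def __len__(self) -> int:
        return self.times.size

    def __iter__(self) -> Iterator[float]:
        return iter(self.times)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return np.array_equal(self.times, other.times)

    def __repr__(self) -> str:
        return f"SpikeTrain(n={len(self)})"

    def shifted(self, dt: float) -> "SpikeTrain":
        return SpikeTrain(self.times + dt)


@dataclass(frozen=True)
class LatencyPoint:
    """One background-locked response latency."""

    stimulus_time: float  # s
    latency_raw: float  # ms
    latency_norm: float | None = None  # dimensionless (raw / baseline)


class LatencySeries:
    """Time-ordered latency series, array-backed but indexable as points.

    ``raw`` is in milliseconds; ``norm`` is ``raw / baseline`` and is ``None``
    until :func:`normalize_latencies` has run.
    """

    __slots__ = ("stimulus_times", "raw", "norm")

    def __init__(
        self,
        stimulus_times: Sequence[float] | np.ndarray,
        raw: Sequence[float] | np.ndarray,
        norm: Sequence[float] | np.ndarray | None = None,
    ):
        t = np.asarray(stimulus_times, dtype=float)
        r = np.asarray(raw, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValidationError("stimulus_times and raw latencies must be equal-length 1-D")
        if t.size and np.any(np.diff(t) < 0):
            bad = int(np.argmax(np.diff(t) < 0)) + 1
            raise ValidationError(
                f"latencies must be sorted by stimulus_time; row {bad} out of order"
            )
        if np.any(r <= 0):
            bad = int(np.argmax(r <= 0))
            raise ValidationError(
                f"latency_raw must be > 0 ms; row {bad} has {r[bad]:g}"
            )
        self.stimulus_times = t
        self.raw = r
        self.norm = None if norm is None else np.asarray(norm, dtype=float)
        if self.norm is not None and self.norm.shape != t.shape:
            raise ValidationError("norm must match stimulus_times in length")

    def __len__(self) -> int:
        return self.stimulus_times.size

    def __getitem__(self, i: int) -> LatencyPoint:
        return LatencyPoint(
            float(self.stimulus_times[i]),
            float(self.raw[i]),
            None if self.norm is None else float(self.norm[i]),
        )

    def __iter__(self) -> Iterator[LatencyPoint]:
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LatencySeries):
            return NotImplemented
        if not np.array_equal(self.stimulus_times, other.stimulus_times):
            return False
        if not np.array_equal(self.raw, other.raw):
            return False
        if (self.norm is None) != (other.norm is None):
            return False
        return self.norm is None or np.array_equal(self.norm, other.norm)

    def __repr__(self) -> str:
        state = "normalized" if self.norm is not None else "raw"
        return f"LatencySeries(n={len(self)}, {state})"


@dataclass
class FiberRecord:
    """One fiber's protocol, stimuli, spike train and latency series."""

    fiber_id: str
    segments: list[ProtocolSegment]
    stimuli: list[StimulusEvent]
    spikes: SpikeTrain
    latencies: LatencySeries
    baseline_latency: float | None = None  # ms
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_latency is not None and self.baseline_latency <= 0:
            raise ValidationError(
                f"baseline_latency must be > 0 ms, got {self.baseline_latency}"
            )
        starts = [s.start for s in self.segments]
        if sorted(starts) != starts:
            raise ValidationError("protocol segments must be time-ordered")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end > b.start:
                raise ValidationError(
                    f"protocol segments overlap: [{a.start}, {a.end}) and "
                    f"[{b.start}, {b.end})"
                )
        if self.segments and len(self.latencies):
            t = self.latencies.stimulus_times
            covered = np.zeros(t.shape, dtype=bool)
            for seg in self.segments:
                covered |= (t >= seg.start) & (t < seg.end)
            if not covered.all():
                bad = float(t[~covered][0])
                raise ValidationError(
                    f"latency point at t={bad:g} s lies outside every protocol segment"
                )

    @property
    def start_time(self) -> float:
        """Recording start (seconds): first protocol segment's onset."""
        return self.segments[0].start if self.segments else 0.0

    def replace(self, **changes) -> "FiberRecord":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_BUNDLE_SCHEMAS = {
    "spikes.csv": ["time_s"],
    "stimuli.csv": [
        "time_s",
        "kind",
        "n_pulses",
        "pulse_freq_hz",
        "distance_ms",
        "amplitude_mn",
    ],
    "protocol.csv": ["start_s", "end_s", "background_hz"],
    "latencies.csv": ["stim_time_s", "latency_ms"],
}
# optional extra columns tolerated per file
_BUNDLE_OPTIONAL = {"latencies.csv": ["latency_norm"]}


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"missing bundle file {path}")
    df = pd.read_csv(path)
    required = _BUNDLE_SCHEMAS[name]
    optional = _BUNDLE_OPTIONAL.get(name, [])
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in required + optional]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")
    return df


def read_fiber_record(bundle_dir: str | Path, metadata: dict | None = None) -> FiberRecord:
    """Read a fiber bundle directory into a validated :class:`FiberRecord`.

    Parameters
    ----------
    bundle_dir
        Directory containing ``spikes.csv``, ``stimuli.csv``, ``protocol.csv``,
        ``latencies.csv`` and ``fiber.json``.
    metadata
        Extra key–value pairs merged over the sidecar's metadata.
    """
    bundle = Path(bundle_dir)
    spikes_df = _read_csv(bundle / "spikes.csv", "spikes.csv")
    stim_df = _read_csv(bundle / "stimuli.csv", "stimuli.csv")
    proto_df = _read_csv(bundle / "protocol.csv", "protocol.csv")
    lat_df = _read_csv(bundle / "latencies.csv", "latencies.csv")

    sidecar_path = bundle / "fiber.json"
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}

    segments = [
        ProtocolSegment(float(r.start_s), float(r.end_s), float(r.background_hz))
        for r in proto_df.itertuples()
    ]
    stimuli = []
    for r in stim_df.itertuples():
        stimuli.append(
            StimulusEvent(
                time=float(r.time_s),
                kind=str(r.kind),
                n_pulses=int(r.n_pulses),
                pulse_frequency=float(r.pulse_freq_hz),
                distance_to_next_background=(
                    None if pd.isna(r.distance_ms) else float(r.distance_ms)
                ),
                amplitude=None if pd.isna(r.amplitude_mn) else float(r.amplitude_mn),
            )
        )
    spikes = SpikeTrain(spikes_df["time_s"].to_numpy())
    norm = (
        lat_df["latency_norm"].to_numpy()
        if "latency_norm" in lat_df.columns
        else None
    )
    latencies = LatencySeries(
        lat_df["stim_time_s"].to_numpy(), lat_df["latency_ms"].to_numpy(), norm
    )
    meta = dict(sidecar.get("metadata", {}))
    if metadata:
        meta.update(metadata)
    return FiberRecord(
        fiber_id=str(sidecar.get("fiber_id", bundle.name)),
        segments=segments,
        stimuli=stimuli,
        spikes=spikes,
        latencies=latencies,
        baseline_latency=sidecar.get("baseline_latency"),
        metadata=meta,
    )


def write_fiber_record(record: FiberRecord, bundle_dir: str | Path) -> Path:
    """Write ``record`` as a CSV bundle directory (inverse of :func:`read_fiber_record`)."""
    bundle = Path(bundle_dir)
    bundle.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": record.spikes.times}).to_csv(
        bundle / "spikes.csv", index=False
    )
    pd.DataFrame(
        {
            "time_s": [s.time for s in record.stimuli],
            "kind": [s.kind for s in record.stimuli],
            "n_pulses": [s.n_pulses for s in record.stimuli],
            "pulse_freq_hz": [s.pulse_frequency for s in record.stimuli],
            "distance_ms": [s.distance_to_next_background for s in record.stimuli],
            "amplitude_mn": [s.amplitude for s in record.stimuli],
        }
    ).to_csv(bundle / "stimuli.csv", index=False)
    pd.DataFrame(
        {
            "start_s": [s.start for s in record.segments],
            "end_s": [s.end for s in record.segments],
            "background_hz": [s.background_frequency for s in record.segments],
        }
    ).to_csv(bundle / "protocol.csv", index=False)
    lat = {
        "stim_time_s": record.latencies.stimulus_times,
        "latency_ms": record.latencies.raw,
    }
    if record.latencies.norm is not None:
        lat["latency_norm"] = record.latencies.norm
    pd.DataFrame(lat).to_csv(bundle / "latencies.csv", index=False)
    (bundle / "fiber.json").write_text(
        json.dumps(
            {
                "fiber_id": record.fiber_id,
                "metadata": record.metadata,
                "baseline_latency": record.baseline_latency,
            },
            indent=2,
        )
    )
    return bundle


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def normalize_latencies(
    record: FiberRecord,
    baseline: float | None = None,
    *,
    eps: float = 0.05,
    outlier_k: float = 5.0,
) -> FiberRecord:
    """Divide raw latencies by a per-fiber baseline latency.

    The microneurography standard baseline — the unconditioned latency after
    a two-minute stimulation pause — is rarely available post hoc, so the
    default baseline is the minimum raw latency after an automatic outlier
    screen (``outlier_k``), which stands in for the visual outlier check an
    experimenter would perform.

    Parameters
    ----------
    record
        Record with at least one latency point.
    baseline
        Explicit baseline in ms; default is the screened minimum.
    eps
        Tolerated dip of normalized latency below 1 (supernormal conduction
        and observation noise).  Values below ``1 - eps`` raise.
    outlier_k
        Range multiplier for the default-baseline outlier screen.
    """
    if len(record.latencies) == 0:
        raise EmptyInputError("cannot normalize an empty latency series")
    if baseline is None:
        if len(record.latencies) >= 3:
            screened, _ = remove_latency_outliers(record, k=outlier_k)
            baseline = float(np.min(screened.latencies.raw))
        else:
            baseline = float(np.min(record.latencies.raw))
    if baseline <= 0:
        raise ParameterError(f"baseline latency must be > 0 ms, got {baseline}")
    norm = record.latencies.raw / baseline
    if np.any(norm < 1.0 - eps):
        bad = int(np.argmax(norm < 1.0 - eps))
        raise ValidationError(
            f"normalized latency {norm[bad]:.4f} at row {bad} is below 1 - eps "
            f"(eps={eps}); baseline {baseline:g} ms looks too large"
        )
    latencies = LatencySeries(record.latencies.stimulus_times, record.latencies.raw, norm)
    return record.replace(latencies=latencies, baseline_latency=baseline)


def remove_latency_outliers(
    record: FiberRecord, k: float = 5.0
) -> tuple[FiberRecord, list[LatencyPoint]]:
    """Screen latency points whose raw latency is far outside the bulk range.

    A point is an outlier when its raw latency lies outside
    ``median ± k · IQR`` of the retained points; the screen is iterated to a
    fixpoint so that a second application never removes anything.

    Returns the screened record and the list of removed points.
    """
    if len(record.latencies) < 3:
        raise EmptyInputError("outlier screening needs at least 3 latency points")
    if not np.isfinite(k) and k > 0:
        return record, []
    raw = record.latencies.raw
    keep = np.ones(raw.shape, dtype=bool)
    while True:
        vals = raw[keep]
        if vals.size == 0:
            raise DegenerateInputError("outlier screen removed every latency point")
        med = np.median(vals)
        q25, q75 = np.percentile(vals, [25, 75])
        half = k * (q75 - q25)
        new_keep = keep & (np.abs(raw - med) <= half)
        if new_keep.sum() == keep.sum():
            break
        keep = new_keep
    if keep.sum() == 0:
        raise DegenerateInputError("outlier screen removed every latency point")
    removed = [record.latencies[i] for i in np.flatnonzero(~keep)]
    latencies = LatencySeries(
        record.latencies.stimulus_times[keep],
        record.latencies.raw[keep],
        None if record.latencies.norm is None else record.latencies.norm[keep],
    )
    return record.replace(latencies=latencies), removed


def highpass_detrend(
    record: FiberRecord,
    cutoff: float = 0.005,
    *,
    grid_dt: float = 1.0,
    zero_phase: bool = True,
    order: int = 2,
) -> FiberRecord:
    """Remove sub-``cutoff`` drift from the latency series, preserving its mean.

    Latency samples arrive at the (uneven) background stimulation times, so
    the series is linearly resampled onto a uniform ``grid_dt`` grid, a
    Butterworth low-pass trend (< ``cutoff`` Hz) is estimated — zero-phase by
    default to avoid latency-shift artifacts, causal optionally — subtracted,
    and the residual is sampled back at the original stimulus times with the
    original global mean re-added.

    The default 0.005 Hz cutoff removes slow drifts (e.g. skin-temperature
    related) with periods longer than ~200 s while leaving activity-evoked
    latency jumps intact.
    """
    if len(record.latencies) < 8:
        raise EmptyInputError("high-pass detrending needs at least 8 latency points")
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be > 0 Hz, got {cutoff}")
    nyquist = 0.5 / grid_dt
    if cutoff >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff} Hz is at or above the Nyquist frequency "
            f"{nyquist} Hz of the {grid_dt} s resampling grid"
        )
    t = record.latencies.stimulus_times
    y = record.latencies.raw
    grid = np.arange(t[0], t[-1] + grid_dt, grid_dt)
    b, a = signal.butter(order, cutoff, btype="low", fs=1.0 / grid_dt)
    padlen = 3 * max(len(a), len(b))
    if grid.size <= padlen:
        raise ParameterError(
            f"latency series spans only {grid.size} grid samples; "
            f"need more than {padlen} for the {order}-order filter"
        )
    yg = np.interp(grid, t, y)
    trend = signal.filtfilt(b, a, yg) if zero_phase else signal.lfilter(b, a, yg)
    resid = yg - trend
    y_new = np.interp(t, grid, resid)
    y_new += y.mean() - y_new.mean()
    if np.any(y_new <= 0):
        raise DegenerateInputError(
            "detrended latencies are non-positive; cutoff removes the signal itself"
        )
    norm = None
    baseline = record.baseline_latency
    if record.latencies.norm is not None and baseline:
        norm = y_new / baseline
    latencies = LatencySeries(t, y_new, norm)
    return record.replace(latencies=latencies)
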