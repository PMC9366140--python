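"""Mechanistic synthetic C-fiber generator.

Real microneurography and in-vitro fiber recordings are access-restricted,
so every pipeline stage is exercised against simulated fibers that carry
the statistical structure the analysis assumes:

* stimulation protocols — low-frequency background pulses (0.1–5 Hz),
  extra electrical trains (1–32 pulses, 2–100 Hz, placed 10–4,000 ms before
  the next background pulse) and mechanical bursts (10–30 spikes in 250 ms);
* activity-dependent slowing — every preceding spike adds to the
  normalized latency through two decaying exponential kernels: a fast,
  sub-second component (passive membrane recovery) and a slow component
  with a time constant of tens to hundreds of seconds (axonal ion
  accumulation), optionally with a brief supernormal (latency-*reducing*)
  window after each spike;
* slow drift, observation noise, and optional saturation of total slowing.

The normalized latency observed at a background pulse at time ``t`` is

    l(t) = 1 + min(cap, sum_{u<t} [a_s e^{-(t-u)/tau_s} + a_f e^{-(t-u)/tau_f}])
             - a_sup * #{u : t-u in supernormal window}
             + drift * t + eps,   eps ~ N(0, sigma^2)

and the raw latency is ``L0 * l(t)`` milliseconds.  Spike times themselves
are fed back through the current latency (a response to a pulse at ``p``
occurs at ``p + L0*l(p)/1000``), which is a small second-order effect and
can be switched off.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, PlacementError, ValidationError
from .features import WindowScheme, _count_matrix
from .records import (
    FiberRecord,
    LatencySeries,
    ProtocolSegment,
    SpikeTrain,
    StimulusEvent,
)

__all__ = [
    "GroundTruthDynamics",
    "ExtraTrain",
    "MechanicalBurstTrain",
    "ProtocolSpec",
    "SimulationConfig",
    "build_protocol",
    "simulate_spikes",
    "simulate_latencies",
    "simulate_fiber",
    "make_linear_feature_fiber",
    "mes_like_config",
    "rms_like_config",
    "hes_like_config",
    "preset_config",
]

#: Fixed duration of a mechanical half-sine burst (seconds).
MECH_BURST_DURATION = 0.25


@dataclass(frozen=True)
class GroundTruthDynamics:
    """Ground-truth latency dynamics of a simulated fiber.

    Parameters
    ----------
    baseline_latency
        Unconditioned response latency ``L0`` in ms.
    fast_amplitude, fast_tau
        Per-spike slowing increment (dimensionless, on normalized latency)
        and decay constant (s) of the fast, sub-second process.
    slow_amplitude, slow_tau
        Same for the slow accumulation process (tens to hundreds of s).
    supernormal_amplitude, supernormal_window
        Optional per-spike latency *decrease* applied when the elapsed time
        since the spike falls inside the window (s).
    noise_sd
        Observation noise SD on normalized latency.
    drift
        Linear drift of normalized latency per second (e.g. thermal).
    saturation_cap
        Optional upper bound on the summed (positive) slowing.
    """

    baseline_latency: float = 250.0
    fast_amplitude: float = 0.01
    fast_tau: float = 0.5
    slow_amplitude: float = 0.001
    slow_tau: float = 100.0
    supernormal_amplitude: float = 0.0
    supernormal_window: tuple[float, float] = (0.2, 1.0)
    noise_sd: float = 0.005
    drift: float = 0.0
    saturation_cap: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_latency <= 0:
            raise ParameterError("baseline_latency must be > 0 ms")
        if not self.fast_tau < self.slow_tau:
            raise ParameterError(
                f"fast_tau ({self.fast_tau}) must be smaller than slow_tau ({self.slow_tau})"
            )
        if min(self.fast_amplitude, self.slow_amplitude, self.supernormal_amplitude) < 0:
            raise ParameterError("kernel amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        w0, w1 = self.supernormal_window
        if not 0 <= w0 < w1:
            raise ParameterError(f"invalid supernormal window ({w0}, {w1})")


@dataclass(frozen=True)
class ExtraTrain:
    """An extra electrical pulse train anchored before one background pulse.

    The train's last pulse precedes background pulse ``background_index`` by
    exactly ``distance_to_next_background`` milliseconds; earlier pulses are
    spaced at ``pulse_frequency`` Hz (0 denotes a single pulse).
    """

    background_index: int
    n_pulses: int
    pulse_frequency: float
    distance_to_next_background: float  # ms

    def __post_init__(self) -> None:
        if self.background_index < 1:
            raise ParameterError("extra trains must follow at least one background pulse")
        if not 1 <= self.n_pulses <= 32:
            raise ParameterError(f"n_pulses must be in 1..32, got {self.n_pulses}")
        if self.pulse_frequency != 0 and not 2 <= self.pulse_frequency <= 100:
            raise ParameterError(
                f"pulse_frequency must be 0 (single pulse) or 2–100 Hz, "
                f"got {self.pulse_frequency}"
            )
        if self.pulse_frequency == 0 and self.n_pulses != 1:
            raise ParameterError("pulse_frequency 0 denotes a single pulse")
        if not 10 <= self.distance_to_next_background <= 4000:
            raise ParameterError(
                f"distance_to_next_background must be in 10–4,000 ms, "
                f"got {self.distance_to_next_background}"
            )

    @property
    def duration(self) -> float:
        """Span from first to last pulse, seconds."""
        if self.pulse_frequency == 0:
            return 0.0
        return (self.n_pulses - 1) / self.pulse_frequency


@dataclass(frozen=True)
class MechanicalBurstTrain:
    """Periodic mechanical bursts, each evoking a fixed spike count in 250 ms."""

    period: float  # s between bursts
    spike_count: int
    burst_duration: float = MECH_BURST_DURATION
    amplitude: float = 10.0  # mN

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ParameterError("burst period must be > 0 s")
        if not 10 <= self.spike_count <= 30:
            raise ParameterError(f"spike_count must be in 10..30, got {self.spike_count}")
        if self.burst_duration <= 0:
            raise ParameterError("burst_duration must be > 0 s")


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative stimulation protocol: segments + extra trains + bursts."""

    segments: tuple[tuple[float, float], ...]  # (duration s, background Hz)
    extra_trains: tuple[ExtraTrain, ...] = ()
    mechanical_bursts: tuple[MechanicalBurstTrain, ...] = ()

    def __post_init__(self) -> None:
        if not self.segments:
            raise ParameterError("protocol needs at least one segment")
        for dur, freq in self.segments:
            if dur <= 0 or freq <= 0:
                raise ParameterError(
                    f"segment duration and frequency must be > 0, got ({dur}, {freq})"
                )

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.segments))


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one synthetic fiber byte-for-byte."""

    protocol: ProtocolSpec
    dynamics: GroundTruthDynamics = field(default_factory=GroundTruthDynamics)
    seed: int = 0
    fiber_id: str = "synthetic"
    spontaneous_rate: float = 0.0  # Hz, Poisson
    latency_feedback: bool = True


# ---------------------------------------------------------------------------
# Protocol construction
# ---------------------------------------------------------------------------


def build_protocol(
    spec: ProtocolSpec,
) -> tuple[list[ProtocolSegment], list[StimulusEvent]]:
    """Materialize a protocol spec into segments and time-ordered stimuli.

    Background pulses fire at each segment's frequency starting at the
    segment onset; extra trains end exactly ``distance_to_next_background``
    ms before their anchor pulse.  A train whose first pulse would not fall
    strictly after the preceding background pulse raises
    :class:`PlacementError`.
    """
    segments: list[ProtocolSegment] = []
    bg_times: list[float] = []
    t0 = 0.0
    for dur, freq in spec.segments:
        seg = ProtocolSegment(t0, t0 + dur, freq)
        segments.append(seg)
        n = int(math.floor(dur * freq - 1e-9)) + 1
        bg_times.extend(t0 + k / freq for k in range(n))
        t0 += dur
    events = [StimulusEvent(t, "background") for t in bg_times]

    for train in spec.extra_trains:
        if train.background_index >= len(bg_times):
            raise PlacementError(
                f"extra train anchored to background pulse {train.background_index}, "
                f"but only {len(bg_times)} background pulses exist"
            )
        anchor = bg_times[train.background_index]
        prev_bg = bg_times[train.background_index - 1]
        last = anchor - train.distance_to_next_background / 1000.0
        first = last - train.duration
        if first <= prev_bg:
            raise PlacementError(
                f"extra train ({train.n_pulses} pulses @ {train.pulse_frequency} Hz, "
                f"distance {train.distance_to_next_background} ms) starting at "
                f"{first:g} s overlaps the background pulse at {prev_bg:g} s"
            )
        events.append(
            StimulusEvent(
                time=first,
                kind="extra_electrical",
                n_pulses=train.n_pulses,
                pulse_frequency=train.pulse_frequency,
                distance_to_next_background=train.distance_to_next_background,
            )
        )

    total = spec.total_duration
    for burst in spec.mechanical_bursts:
        t = burst.period
        while t + burst.burst_duration < total:
            events.append(
                StimulusEvent(
                    time=t,
                    kind="mechanical",
                    n_pulses=burst.spike_count,
                    pulse_frequency=0.0,
                    amplitude=burst.amplitude,
                )
            )
            t += burst.period

    events.sort(key=lambda e: e.time)
    return segments, events


def _electrical_pulse_times(event: StimulusEvent) -> np.ndarray:
    if event.kind == "background" or event.pulse_frequency == 0:
        return np.array([event.time])
    return event.time + np.arange(event.n_pulses) / event.pulse_frequency


# ---------------------------------------------------------------------------
# Latency-state engine
# ---------------------------------------------------------------------------


class _AdsState:
    """Running fast/slow slowing accumulators with O(1) per-event updates."""

    def __init__(self, dyn: GroundTruthDynamics):
        self.dyn = dyn
        self.t: float | None = None
        self.slow = 0.0
        self.fast = 0.0
        self.recent: deque[float] = deque()  # for the supernormal window

    def _advance(self, t: float) -> None:
        if self.t is not None:
            dt = t - self.t
            if dt < 0:
                raise ValidationError("latency-state events must be time-ordered")
            self.slow *= math.exp(-dt / self.dyn.slow_tau)
            self.fast *= math.exp(-dt / self.dyn.fast_tau)
        self.t = t

    def add_spike(self, u: float) -> None:
        self._advance(u)
        self.slow += self.dyn.slow_amplitude
        self.fast += self.dyn.fast_amplitude
        if self.dyn.supernormal_amplitude > 0:
            self.recent.append(u)

    def slowing_at(self, t: float) -> float:
        """Deterministic slowing term of l(t) (everything except drift and noise)."""
        self._advance(t)
        s = self.slow + self.fast
        if self.dyn.saturation_cap is not None:
            s = min(s, self.dyn.saturation_cap)
        if self.dyn.supernormal_amplitude > 0:
            w0, w1 = self.dyn.supernormal_window
            while self.recent and t - self.recent[0] > w1:
                self.recent.popleft()
            n_sup = sum(1 for u in self.recent if w0 <= t - u <= w1)
            s -= self.dyn.supernormal_amplitude * n_sup
        return s


def simulate_spikes(
    segments: list[ProtocolSegment],
    stimuli: list[StimulusEvent],
    dynamics: GroundTruthDynamics,
    seed: int | np.random.Generator = 0,
    *,
    spontaneous_rate: float = 0.0,
    latency_feedback: bool = True,
) -> SpikeTrain:
    """Generate the fiber's spike train for a materialized protocol.

    Every electrical pulse (background or extra) evokes exactly one spike,
    offset by the fiber's current latency when ``latency_feedback`` is on
    (else by the baseline latency).  A mechanical burst emits its
    ``n_pulses`` spikes spread uniformly at random over the 250 ms burst.
    Optional spontaneous firing is homogeneous Poisson at
    ``spontaneous_rate`` Hz.
    """
    rng = np.random.default_rng(seed)
    dyn = dynamics
    drivers: list[tuple[float, str]] = []
    for e in stimuli:
        if e.kind == "mechanical":
            times = e.time + np.sort(
                rng.uniform(0.0, MECH_BURST_DURATION, size=e.n_pulses)
            )
            drivers.extend((float(t), "spike") for t in times)
        else:
            drivers.extend((float(t), "pulse") for t in _electrical_pulse_times(e))
    if spontaneous_rate > 0:
        total = segments[-1].end if segments else max(t for t, _ in drivers)
        t = float(rng.exponential(1.0 / spontaneous_rate))
        while t < total:
            drivers.append((t, "spike"))
            t += float(rng.exponential(1.0 / spontaneous_rate))
    drivers.sort()

    state = _AdsState(dyn)
    pending: list[float] = []
    spikes: list[float] = []

    def drain(up_to: float) -> None:
        while pending and pending[0] < up_to:
            u = heapq.heappop(pending)
            state.add_spike(u)
            spikes.append(u)

    for t, kind in drivers:
        drain(t)
        if kind == "pulse":
            l_norm = 1.0 + state.slowing_at(t) + dyn.drift * t
            offset_ms = dyn.baseline_latency * (l_norm if latency_feedback else 1.0)
            heapq.heappush(pending, t + offset_ms / 1000.0)
        else:
            heapq.heappush(pending, t)
    drain(math.inf)
    return SpikeTrain(np.asarray(spikes))


def simulate_latencies(
    spikes: SpikeTrain,
    stimuli: list[StimulusEvent],
    dynamics: GroundTruthDynamics,
    seed: int | np.random.Generator = 0,
) -> LatencySeries:
    """Evaluate the observed latency series at every background pulse.

    The deterministic slowing state is driven by *all* spikes in the train
    (background responses, extra-train responses, mechanical and
    spontaneous spikes alike); observation noise is added per background
    pulse and does not feed back into the dynamics.
    """
    rng = np.random.default_rng(seed)
    dyn = dynamics
    bg_times = np.array([e.time for e in stimuli if e.kind == "background"])
    state = _AdsState(dyn)
    spike_times = spikes.times
    j = 0
    norm = np.empty(bg_times.shape)
    for i, t in enumerate(bg_times):
        while j < spike_times.size and spike_times[j] < t:
            state.add_spike(float(spike_times[j]))
            j += 1
        norm[i] = 1.0 + state.slowing_at(float(t)) + dyn.drift * t
    if dyn.noise_sd > 0:
        norm = norm + rng.normal(0.0, dyn.noise_sd, size=norm.shape)
    raw = dyn.baseline_latency * norm
    return LatencySeries(bg_times, raw, norm)


def simulate_fiber(config: SimulationConfig) -> FiberRecord:
    """End-to-end synthetic fiber: protocol -> spikes -> latency series.

    Fully reproducible: the same :class:`SimulationConfig` (including seed)
    yields byte-identical bundles.  The returned record is already
    normalized by the ground-truth baseline ``L0``.
    """
    segments, stimuli = build_protocol(config.protocol)
    ss = np.random.SeedSequence(config.seed)
    rng_spikes, rng_lat = (np.random.default_rng(s) for s in ss.spawn(2))
    spikes = simulate_spikes(
        segments,
        stimuli,
        config.dynamics,
        rng_spikes,
        spontaneous_rate=config.spontaneous_rate,
        latency_feedback=config.latency_feedback,
    )
    latencies = simulate_latencies(spikes, stimuli, config.dynamics, rng_lat)
    return FiberRecord(
        fiber_id=config.fiber_id,
        segments=segments,
        stimuli=stimuli,
        spikes=spikes,
        latencies=latencies,
        baseline_latency=config.dynamics.baseline_latency,
        metadata={"generator": "ads_kernel", "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# Parameter-recovery fixture
# ---------------------------------------------------------------------------

_LINEAR_FIBER_FREQS = (
    0.25, 1.0, 0.5, 2.0, 4.0,
    2.0, 0.25, 4.0, 1.0, 0.5,
    4.0, 0.5, 1.0, 0.25, 2.0,
)


def make_linear_feature_fiber(
    scheme: WindowScheme,
    coefficients: np.ndarray,
    noise_sd: float,
    seed: int,
    *,
    n_points: int = 1000,
    baseline_latency: float = 10.0,
) -> FiberRecord:
    """Synthetic fiber whose latency is an *exact* linear function of its
    own inclusive window-count vector, plus Gaussian noise.

    The ground truth lies inside the degree-1 model class, which makes this
    the canonical parameter-recovery fixture.  The background protocol
    cycles through permuted blocks of several frequencies (0.25–4 Hz) and
    carries randomized extra trains, so every window count — including the
    longest — has real variance, the linear design is well-conditioned, and
    target extremes are spread across all three protocol-aware folds.  A
    burn-in of length ``T_max`` precedes the first emitted latency point,
    so the fixture is stationary from its first row (no truncated-history
    startup ramp); exactly ``n_points`` latency points are emitted.

    ``coefficients`` has length ``N + 1``: intercept first, then one weight
    per window count.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (scheme.n + 1,):
        raise ParameterError(
            f"need {scheme.n + 1} coefficients (intercept first), "
            f"got shape {coefficients.shape}"
        )
    rng = np.random.default_rng(seed)
    n_seg = len(_LINEAR_FIBER_FREQS)
    per_seg = [n_points // n_seg] * n_seg
    per_seg[0] += n_points - sum(per_seg)
    burn_in = (scheme.t_max, _LINEAR_FIBER_FREQS[0])
    seg_spec = (burn_in,) + tuple(
        (pts / f, f) for pts, f in zip(per_seg, _LINEAR_FIBER_FREQS)
    )
    base_spec = ProtocolSpec(segments=seg_spec)
    _, bg_events = build_protocol(base_spec)
    all_bg_times = np.array([e.time for e in bg_events])
    bg_times = all_bg_times[all_bg_times >= scheme.t_max]

    trains = []
    for i in range(2, len(all_bg_times), 4):
        gap = all_bg_times[i] - all_bg_times[i - 1]
        dist_ms = rng.uniform(10.0, min(4000.0, 500.0 * gap))  # <= half the gap
        head = gap - dist_ms / 1000.0 - 0.05 * gap
        if rng.random() < 0.25:
            freq, n_max = 0.0, 1
        else:
            freq = rng.uniform(2.0, 50.0)
            n_max = min(32, 1 + int(head * freq))
        n_pulses = 1 if n_max <= 1 else int(rng.integers(1, n_max + 1))
        if freq != 0.0 and n_pulses == 1 and rng.random() < 0.5:
            freq = 0.0
        if freq == 0.0:
            n_pulses = 1
        trains.append(
            ExtraTrain(
                background_index=i,
                n_pulses=n_pulses,
                pulse_frequency=freq,
                distance_to_next_background=dist_ms,
            )
        )
    spec = ProtocolSpec(segments=seg_spec, extra_trains=tuple(trains))
    segments, stimuli = build_protocol(spec)
    pulse_times = np.sort(
        np.concatenate(
            [
                _electrical_pulse_times(e)
                for e in stimuli
                if e.kind in ("background", "extra_electrical")
            ]
        )
    )
    spikes = SpikeTrain(pulse_times)
    counts = _count_matrix(spikes.times, bg_times, scheme.lengths)
    if scheme.mode == "exclusive":
        counts = np.diff(counts, axis=1, prepend=0)
    norm = coefficients[0] + counts @ coefficients[1:]
    if noise_sd > 0:
        norm = norm + rng.normal(0.0, noise_sd, size=norm.shape)
    raw = baseline_latency * norm
    return FiberRecord(
        fiber_id=f"linear-{seed}",
        segments=segments,
        stimuli=stimuli,
        spikes=spikes,
        latencies=LatencySeries(bg_times, raw, norm),
        baseline_latency=baseline_latency,
        metadata={"generator": "linear_feature", "seed": seed},
    )


# ---------------------------------------------------------------------------
# Protocol presets
# ---------------------------------------------------------------------------


def mes_like_config(
    seed: int,
    *,
    duration_s: float = 4000.0,
    dynamics: GroundTruthDynamics | None = None,
    fiber_id: str | None = None,
) -> SimulationConfig:
    """Electrically stimulated fiber: 0.125 Hz background, an extra train
    before every 10th background pulse (1–32 pulses, single or 2–50 Hz,
    10–4,000 ms before the next pulse)."""
    rng = np.random.default_rng(seed)
    freq = 0.125
    gap = 1.0 / freq
    n_bg = int(math.floor(duration_s * freq - 1e-9)) + 1
    trains = []
    for i in range(10, n_bg, 10):
        dist_ms = rng.uniform(10.0, min(4000.0, 500.0 * gap))
        head = gap - dist_ms / 1000.0 - 0.4
        if rng.random() < 0.3:
            f, n = 0.0, 1
        else:
            f = rng.uniform(2.0, 50.0)
            n = int(rng.integers(1, max(2, min(32, 1 + int(head * f)) + 1)))
            if n == 1:
                f = 0.0
        trains.append(ExtraTrain(i, n, f, dist_ms))
    spec = ProtocolSpec(segments=((duration_s, freq),), extra_trains=tuple(trains))
    return SimulationConfig(
        protocol=spec,
        dynamics=dynamics or GroundTruthDynamics(baseline_latency=5.0),
        seed=seed,
        fiber_id=fiber_id or f"mes-like-{seed}",
    )


def rms_like_config(
    seed: int,
    *,
    dynamics: GroundTruthDynamics | None = None,
    fiber_id: str | None = None,
) -> SimulationConfig:
    """Mechanically stimulated fiber: background frequency steps through
    0.1 / 0.5 / 4 Hz and a mechanical burst (20 spikes in 250 ms) lands
    every 180 s."""
    spec = ProtocolSpec(
        segments=((900.0, 0.1), (900.0, 0.5), (900.0, 4.0)),
        mechanical_bursts=(
            MechanicalBurstTrain(period=180.0, spike_count=20, amplitude=10.0),
        ),
    )
    return SimulationConfig(
        protocol=spec,
        dynamics=dynamics or GroundTruthDynamics(baseline_latency=5.0),
        seed=seed,
        fiber_id=fiber_id or f"rms-like-{seed}",
    )


def hes_like_config(
    seed: int,
    *,
    duration_s: float = 4000.0,
    dynamics: GroundTruthDynamics | None = None,
    fiber_id: str | None = None,
) -> SimulationConfig:
    """Human-like electrically stimulated fiber: 0.25 Hz background with
    4-pulse 10 Hz extra trains 60–3,500 ms before the next pulse."""
    rng = np.random.default_rng(seed)
    freq = 0.25
    n_bg = int(math.floor(duration_s * freq - 1e-9)) + 1
    trains = []
    for i in range(10, n_bg, 10):
        dist_ms = rng.uniform(60.0, min(3500.0, 1000.0 / freq - 300.0 - 200.0))
        trains.append(ExtraTrain(i, 4, 10.0, dist_ms))
    spec = ProtocolSpec(segments=((duration_s, freq),), extra_trains=tuple(trains))
    return SimulationConfig(
        protocol=spec,
        dynamics=dynamics or GroundTruthDynamics(baseline_latency=250.0),
        seed=seed,
        fiber_id=fiber_id or f"hes-like-{seed}",
    )


_PRESETS = {"mes": mes_like_config, "rms": rms_like_config, "hes": hes_like_config}


def preset_config(name: str, seed: int, **kwargs) -> SimulationConfig:
    """Look up a protocol preset (``mes``, ``rms`` or ``hes``) by name."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return factory(seed, **kwargs)
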