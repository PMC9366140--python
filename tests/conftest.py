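import numpy as np
import pytest

from adslow.records import FiberRecord, LatencySeries, ProtocolSegment, SpikeTrain

# Degree-1 ground-truth weights used by the parameter-recovery fixtures:
# intercept first, then one weight per window of the (0.25 s, 7) scheme.
# Magnitudes mirror what single-fiber models typically estimate — large
# weight on the sub-second window, small positive weights on long windows.
TRUTH_COEFFICIENTS = np.array(
    [0.941203, 0.089650, -0.002876, 0.009672, 0.005120, 0.000940, 0.000918, 0.000378]
)


def make_record(
    stim_times,
    raw,
    *,
    norm=None,
    spikes=(),
    segments=None,
    baseline=None,
    fiber_id="test",
) -> FiberRecord:
    """Hand-rolled minimal record for unit tests."""
    stim_times = np.asarray(stim_times, dtype=float)
    if segments is None:
        end = float(stim_times[-1]) + 1.0 if stim_times.size else 1.0
        segments = [ProtocolSegment(0.0, end, 0.25)]
    return FiberRecord(
        fiber_id=fiber_id,
        segments=segments,
        stimuli=[],
        spikes=SpikeTrain(np.asarray(spikes, dtype=float)),
        latencies=LatencySeries(stim_times, raw, norm),
        baseline_latency=baseline,
    )


@pytest.fixture(scope="session")
def linear_record():
    """Noiseless fiber whose latency is exactly linear in its window counts."""
    from adslow.features import WindowScheme
    from adslow.simulate import make_linear_feature_fiber

    scheme = WindowScheme(0.25, 7)
    return scheme, make_linear_feature_fiber(
        scheme, TRUTH_COEFFICIENTS, noise_sd=0.0, seed=1, n_points=1000
    )
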