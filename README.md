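# adslow

Predicting **activity-dependent slowing (ADS)** of C-fiber response latency
from the fiber's own spiking history.

## The problem

In microneurography, single unmyelinated C-fibers in awake humans are
tracked by the *marking method*: continuous low-frequency background
electrical stimulation (typically 0.125–0.25 Hz) evokes responses whose
latency stays near-constant for a quiescent fiber. Whenever the fiber fires
extra action potentials — evoked by additional electrical pulse trains,
mechanical stimulation, or spontaneous neuropathic activity — its conduction
velocity drops and the next background-response latency jumps up, then
relaxes. The latency series is therefore a readout of the fiber's recent
spiking history, and a quantitative model of that mapping supports spike
sorting in noisy multi-fiber recordings and sheds light on the axonal
mechanisms (sub-second membrane recovery vs. slow ionic accumulation).

`adslow` implements that model end to end for a single fiber:

1. **Features.** For each background response at time *t* with normalized
   latency *l* (raw latency ÷ per-fiber baseline), count spikes in a ladder
   of look-back windows of length `T_min·4^k`, k = 0…N−1 (*inclusive*
   counts, so `s_1 ≤ … ≤ s_N`), giving the input vector
   `[s_1, …, s_N]` and target *l*.
2. **Model.** Ordinary least squares on the degree-*d* polynomial expansion
   of the count vector; predictions are clipped to the training-target
   range.
3. **Validation.** Protocol-aware 3-fold cross-validation: within each
   constant-background-frequency segment the time-ordered points are cut
   into three contiguous pieces, so every protocol is represented in every
   fold and no random shuffling breaks the time-series structure. The score
   is R² = 1 − SS_res/SS_tot averaged over folds.
4. **Selection.** Exhaustive grid search over `T_min ∈ {0.125, 0.25, 0.5, 1} s`,
   `N ∈ 5…10`, `d ∈ 1…3`.
5. **Transfer.** Fit on one complete fiber, score on another (each
   normalized with its own baseline), plus an ARX variant
   (`l_t = c + Σ aᵢ·l_{t−i} + b·count(t, 8.1 s)`).

Because single-fiber recordings of this kind are access-restricted, the
package ships a mechanistic **fiber simulator** (`adslow.simulate`):
stimulation protocols in the published parameter ranges, latency dynamics
from fast + slow exponential per-spike kernels with optional supernormality,
drift and observation noise. Every pipeline stage is tested against it.

## Worked example

```bash
adslow simulate --preset mes --seed 7 --out fiber/     # synthetic fiber bundle
adslow fit --bundle fiber/ --out fit/                  # full pipeline
```

prints

```
best: T_min=1 s, N=5, d=1, mean R^2=0.7098
```

i.e. for this simulated, electrically stimulated fiber the best model counts
spikes in windows of 1, 4, 16, 64 and 256 s, is linear (*d* = 1), and
explains ~71 % of the latency variance out of sample. `fit/` then holds
`gridsearch.csv` (all 72 configurations with per-fold R²),
`coefficients.csv` (per-fold weights; for this fiber they decay with window
length — recent spikes slow conduction the most), `folds.csv` and
`predictions.csv` (per-rotation test predictions covering every latency
point exactly once). `adslow transfer --train a/ --test b/ --out t/` reports
the inter-fiber R² under both the train-optimized and the test-optimized
configuration.

Everything is also available as a library:

```python
from adslow import WindowScheme, cross_validate, normalize_latencies, read_fiber_record
rec = normalize_latencies(read_fiber_record("fiber/"))
print(cross_validate(rec, WindowScheme(t_min=0.5, n=6), degree=1).mean_r2)
```

## Data format

A fiber is a directory bundle of plain CSVs — `spikes.csv` (`time_s`),
`stimuli.csv` (`time_s, kind, n_pulses, pulse_freq_hz, distance_ms,
amplitude_mn`), `protocol.csv` (`start_s, end_s, background_hz`),
`latencies.csv` (`stim_time_s, latency_ms`) — plus a `fiber.json` sidecar
with `fiber_id`, free-form metadata and the baseline latency. The simulator
emits exactly this bundle; see `docs/methods.md` for conventions and
modeling details.
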