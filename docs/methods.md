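# Methods

`wheeltrack` models the full measurement chain of a one-pulse-per-revolution
home-cage running-wheel tracker and the analyses built on its logs. This
note records the models, the parameters that matter, the numerical
conventions, and what the synthetic data does and does not emulate.

## Measurement chain

**Ground truth.** A wheel run is a strictly increasing sequence of
rotation-completion times (float seconds from a wall-clock start). In the
robotic mode the wheel turns at piecewise-constant rates, so within a
segment of duration *d* and rate *r* rev/s rotations complete at
*k/r*, *k* = 1..⌊*d·r*⌋ from the segment start. Rotation times stay
continuous until sampling; no discretisation happens in the simulator.

**Sensing.** Each rotation fires one Hall-sensor trigger. Three
imperfection knobs exist for robustness testing — Gaussian timing jitter
(sd in ms), a Bernoulli miss probability, and a refractory period during
which repeat triggers are swallowed. The default configuration is exact
counting with a 50 ms refractory (a wheel would need to exceed 20 rev/s,
~10× a fast mouse, before it loses counts); `SensorConfig.ideal()` sets
refractory to zero for the exactness contracts used throughout the tests.

**Sampling.** The logger reads the cumulative counter at *t = k/f*
(sample 0 at *t* = 0 included; a trigger landing exactly on a sample
instant belongs to that sample). The final log line flushes the counter
state, so triggers in a trailing partial period are still recorded:
sampling delays a count by at most one period and never loses one. The
per-sample deviation from ground truth is therefore bounded by the number
of rotations inside one sample period — the transient multi-sensor
"misalignment" seen when the rotation period beats against the sampling
period, which vanishes whenever the wheel pauses.

**Log dialect.** Plain text, UTF-8, LF. `#`-prefixed `key=value` header
lines (version, ISO-8601 wall_start, sample_period_s, comma-separated
sensor ids and per-sensor circumferences, dialect), then one line per
sample: integer elapsed milliseconds, one tab-separated field per sensor.
The canonical `counts` dialect stores integer cumulative counts — lossless,
with distance derived downstream from the header circumference; a
`distance_cm` dialect is provided for interoperability and round-trips by
dividing by the circumference and rounding to the nearest count.

## Virtual mouse

The behavioural generator is intentionally the simplest process that
produces realistic nocturnal activity curves: rest and run bouts
alternate; bout onsets follow a Poisson process whose rate is
piecewise-constant in the light/dark phase (simulated exactly by
redrawing the memoryless exponential gap at each phase boundary); bout
durations are gamma; each bout runs at a single Gaussian-sampled speed,
clipped below at 0 cm/s to keep rotation rates non-negative.

Default preset (per 12 h dark phase on a 50 cm wheel):

| parameter | default | unit | rationale |
|---|---|---|---|
| dark_bout_rate | 12 | bouts/h | ~60 bouts/night |
| light_bout_rate | 0.5 | bouts/h | strong nocturnality (>90% of rotations in dark) |
| bout_duration_mean | 400 | s | with the rates above, ~7 h running/night |
| bout_duration_shape | 2 | – | right-skewed but not degenerate |
| run_speed_mean / sd | 28 / 6 | cm/s | typical sustained mouse wheel speed |

These place the expected nightly distance near 7 km, mid-way in the
3–16 km band reported for laboratory mice, with seed-to-seed spread
comfortably inside the band.

What the generator does **not** emulate: individual animals within a
group cage (the hardware cannot attribute rotations to a mouse, and
neither does the model), within-bout speed fluctuation, ultradian rhythm
structure, partial rotations (a magnet stopping short of the sensor can
mis-count by one, an error of a few centimetres per event — orders of
magnitude below nightly totals, and ignored here), or wheel inertia and
coasting. Passing tests therefore certify the *measurement and analysis*
chain, not the realism of mouse behaviour beyond total/phase structure.

## Kinematics

Distance is `counts × circumference` (cm internally; km only in
reports). Raw velocity is the per-interval difference quotient with
sample 0 defined as 0. The smoothed velocity is a *trailing* (causal)
moving average, default window 4 samples — at 4 Hz, a one-second
smoother matching streaming acquisition; partial windows average the
samples available so far. Instantaneous smoothed values are quantized in
steps of `circumference / (window × sample_period)`; speed-recovery
checks use that step as their tolerance. Phase summaries attribute each
sample's distance increment to that sample's phase interval, so
per-interval distances telescope to the total exactly. Bouts are maximal
runs of samples with raw velocity ≥ `min_speed` (default 1 cm/s), merging
rests shorter than `min_gap` (default 60 s); both thresholds are
conventions, not measurements, and are overridable everywhere.

## Quality control

QC is advisory and read-only. A *flatline* is ≥ 2 h (default) of zero
count increase during the dark phase while at least one other sensor in
the same log accumulates counts — the signature of a wheel jammed by
bedding; without a comparator sensor the finding is a warning rather than
an exclusion recommendation. A *counter reset* (cumulative column drops)
marks an acquisition restart; the splicer re-bases subsequent counts by
the pre-drop value so totals are preserved, and treats the post-drop
value as counts since the restart. Exclusion is always an explicit caller
decision: the stats layer takes an exclusion list, QC only recommends.

## Paired permutation test

For *n* cages with summed before/after distances, the statistic is the
mean of the per-cage differences. Independently swapping each cage's
before/after labels equals flipping its difference's sign, so the null is
the sign-flip distribution. Monte-Carlo permutations are independent
Bernoulli(½) flip vectors (duplicates allowed), all driven by one seed;
ties with the observed statistic count as at least as extreme
(conservative), with a 1e-9-relative absolute slack so float round-off
cannot drop an exact tie. Default sidedness is one-sided
(greater), matching a directional increase-in-activity hypothesis;
two-sided and lesser variants are exposed.

Three estimators are reported side by side because the tail can be read
off the null sample in more than one way: `empirical` (*k/B*),
`empirical_add_one` ((*k*+1)/(*B*+1), the default — guarantees *p* > 0
and is the correct finite-B estimator), and `density_auc` (tail area of
a Gaussian KDE fitted to the null sample, for workflows that integrate a
fitted density; it agrees with the empirical tail within ~0.02 for
smooth nulls at *n* ≥ 6, *B* ≥ 1000, but splits ties on discrete nulls
and falls back to the add-one value when the null is degenerate).

The exact test enumerates all 2ⁿ assignments (chunked, *n* ≤ 20) and is
the oracle: Monte-Carlo p-values must sit within 3 binomial standard
errors of it. The operating-characteristics driver simulates designs with
differences ~ Normal(effect, sd): at effect 0 it verifies the type-I rate
at α = 0.05; with an effect it measures power, which is exactly 0 for
*n* ≤ 4 because the smallest attainable p, 2⁻ⁿ, then exceeds α — the
discreteness floor that makes small cage counts uninformative.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at desk scale: the
85 s/4 Hz mechanical run, 12–50 h virtual-mouse recordings sampled at
1/60 Hz for multi-day summaries, B = 10³–10⁵ permutations, 1000-replicate
calibration runs, and ≤ 2⁰⁸ exact enumerations — sizes chosen so the full
chain, including property tests over hundreds of random traces, completes
in well under a minute while still exercising every code path. Float
comparisons against sample instants use a 1 ns guard so a rotation landing
exactly on a sample boundary is counted deterministically; rotation counts
per segment use ⌊d·r + 1e-9⌋ for the same reason.

## Known limitations

- The mechanical run's rotation rate is a free choice (0.89 rev/s here,
  giving a 44.5 cm/s plateau on the 50 cm fixture wheel); speed recovery
  is asserted as self-consistency (configured vs recovered), never as an
  external numeric target.
- The log dialect is this package's own; captures from other serial
  loggers need an adapter parser.
- Jammed-wheel intervals are flagged, never imputed or repaired.
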