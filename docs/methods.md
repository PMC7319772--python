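# Methods

This note documents the models, conventions, numerical choices and known
limitations behind each analysis stage, and what the synthetic-session
generator does and does not emulate.

## Filtering and envelopes

All oscillatory analyses work on three bands of the 600 Hz LFP: delta
(1–4 Hz), spindle (6–14 Hz) and ripple (100–275 Hz). Filters are band-pass
FIRs designed with a blackman window and order equal to six times the
sampling-rate/bandwidth ratio, rounded up to the nearest even integer so the
symmetric impulse response has an integer group delay (delta: order 1200;
spindle: 450; ripple: 22). Application is forward–backward after reflect
padding by one filter length, so the net phase is exactly zero and the
effective magnitude response is the squared single-pass response. This
satisfies the band contract we test (gain ≥ 0.95 at band centre, ≤ 0.05 one
octave outside each edge, where an octave above the ripple band exceeds
Nyquist and is not testable); a single compensated pass would leak ~15%
amplitude at 0.5 Hz through the delta filter. The usable flat passband of the
spindle filter is roughly 8.5–11.5 Hz; content at 12–14 Hz is attenuated up
to ~40% — a property of the stated design rule that matters when interpreting
cycle amplitudes near the band edges.

Power envelopes are centred moving averages of the squared filtered trace.
The envelope window for rest-state detection is 10 s: long enough to bridge
the gaps between individual events within a sleep bout, short enough to
resolve bout boundaries to ~10 s.

## Rest-state detection

Rest (non-REM) is the conjunction of high mPFC delta power and high CA1
ripple power: samples where *both* envelopes exceed their own session means,
in contiguous runs of at least 120 s. Comparing each envelope to its own mean
makes the rule invariant to affine rescaling of either channel (no gain
calibration needed). Sub-threshold dips of up to 10 s inside a candidate run
are bridged before the duration test; this replaces the visual confirmation a
human scorer would apply, is the same scale as the envelope window, and is
recorded in run logs. Velocity from the 30 Hz position track (gaps ≤ 300 ms
linearly interpolated, longer gaps masked; speed = Euclidean norm of the
position derivative, Gaussian-smoothed with 250 ms SD, resampled to 600 Hz)
is computed as an immobility sanity check and deliberately not used as a hard
gate.

## Event detectors

All thresholds use the mean and SD of the detection trace itself restricted
to rest intervals — the squared trace for KCs and SWRs, the filtered voltage
for spindle troughs — so each detector is self-calibrating and invariant to
DC offsets of the raw LFP.

* **K-complexes.** The delta-filtered mPFC LFP is rectified (positive values
  zeroed) and squared; local maxima above mean + 4 SD are KCs, with a 250 ms
  refractory period (half a delta period) resolved largest-first so one
  down-state is never counted twice.
* **Spindle troughs and cycles.** Local minima of the spindle-filtered
  voltage at or below mean − 3 SD; successive troughs closer than one period
  of the band's upper edge (1/14 s) collapse to the deeper one. Cycles are
  bounded by the nearest flanking local maxima of the filtered voltage;
  troughs lacking a flank within one period of the lower edge (1/6 s) are
  dropped. Peak-to-trough amplitude is the larger flank minus the trough.
* **SWRs.** The squared ripple-band CA1 trace is smoothed with a 5 ms moving
  average (stabilising the duration test against single-sample dropouts; at
  600 Hz the squared 150 Hz carrier oscillates at 300 Hz and the average
  removes it). Supra-threshold (mean + 3 SD) runs of ≥ 20 ms are events; runs
  separated by < 20 ms merge. The timestamp is the sample with the largest
  absolute ripple-band voltage in the run, so it locks to the strongest
  oscillation peak rather than the run centre.

Degenerate inputs are handled explicitly: no rest intervals give empty event
series with a warning; a flat trace (SD 0) detects nothing.

## Peri-event histograms and the shift-permutation null

PETHs average spike counts in 15 ms bins over events and smooth with a 15 ms
SD Gaussian (both parameterisable; 2 ms bins over ±0.4 s reproduce the
common peri-SWR variant). Significance is expressed per bin in SD units of a
null built by rigidly shifting *all* event timestamps by one shared offset —
magnitude uniform on [1.5, 2.5] s, sign randomised — preserving inter-event
intervals, repeated 100 times; the null SD uses the n−1 denominator, and bins
with zero null SD yield NaN (flagged) rather than infinite z. Because counts
are Poisson-skewed and the null mean and SD are estimated from only 100
permutations, the null z retains a small positive bias (~+0.2 mean) and
slightly heavy tails; the calibration we enforce is that the per-bin |z| > 2
rate over independent sessions stays within [0.01, 0.10]. The asymmetry index
(max_after − max_before)/max(both) over ±0.5 s is antisymmetric under time
reversal and defined as 0 when both windows are silent; the modulation index
(peak − trough)/mean over a centred 200 ms window is NaN when the window mean
is zero.

## Phase locking

Both phase estimators use the cosine convention: phase 0 at the band-signal
peak, ±π at the trough. The analytic-signal method takes the angle of the
Hilbert transform; the extrema method anchors detected peaks at 0 (mod 2π)
and troughs at π (mod 2π) and interpolates linearly, extrapolating at the
edges. This anchor choice is the one that makes the two methods agree on a
sinusoid (within 0.05 rad away from the edges), which we verify, and it fixes
the sign convention for all reported mean directions. Phases at spike times
are interpolated on the *unwrapped* phase, so interpolation across the ±π
wrap stays on the circle.

Non-sinusoidal LFP morphology biases raw phase sampling, so spike-phase
distributions are normalised by the distribution of phases of the whole
filtered trace during rest (36 bins, 10°). For the circular statistics, each
spike phase is weighted by the inverse baseline density of its bin, with
weights scaled to mean 1 so the effective n equals the spike count — the
minimal choice that makes the Rayleigh test and von Mises fit consistent with
the normalised histogram. The Rayleigh statistic is Z = nR² with the
(weighted) resultant length R and p = exp(√(1 + 4n + 4(n² − nZ)) − (1 + 2n));
the von Mises concentration is κ = A⁻¹(R) with A(κ) = I₁(κ)/I₀(κ) inverted by
bracketed root finding on exponentially scaled Bessel functions, capped at
10³ for near-degenerate samples (flagged). Pair phase lags pair each spike of
one unit with the nearest-in-time spike of the other and difference the
unwrapped phases; pairs more than one full cycle apart (|lag| ≥ 2π) are
discarded and counted.

## Correlograms and rhythmicity

Correlograms histogram target-minus-reference lags with bins centred on
integer multiples of the bin width (default 10 ms, ±0.5 s), so a lag of
exactly +10 ms falls in the (+5, +15] ms bin and the zero-lag bin is centred
at 0; auto mode excludes self-pairs. Restriction to intervals (rest, spindle
cycles, inter-spindle epochs) requires both spikes inside. The implementation
is verified bin-exactly against an O(n²) all-pairs oracle. Significance uses
the same shared-shift permutation null as the PETH, shifting the target
train; with ~100 bins per correlogram, the maximum |z| of an independent pair
exceeds 3 about a quarter of the time (an order statistic, not a defect), so
peak significance should be interpreted per bin, where the |z| > 3 rate sits
at its nominal ~0.3%.

Spindle rhythmicity is summarised by the lag of the autocorrelogram maximum
after the first local minimum that follows lag 0 (minimum = first bin with
both neighbours at least as large and one strictly larger; ties toward
smaller lag), flagged as in-band when it falls in [1/14, 1/6] s. A seeded
spike subsample supports matching multi-unit spike counts to the sparsest
unit before comparing rhythmicity.

## Cycle classification, coupling labels, participation

Ripple power within a spindle cycle is the *mean* squared ripple-band sample
over the cycle window — a power density, so cycles of different duration are
comparable (the integrated power alternative would confound power with cycle
length). Cycles are labelled low/high against the session median (or the 75th
percentile for upper-quartile contrasts) of ripple power or peak-to-trough
amplitude; ties go to low, and the split is rank-based, hence invariant to
monotone transforms. A SWR is coupled to spindles iff its single timestamp
falls in a cycle's [start, end) window — membership by timestamp, not by
event-duration overlap, matching how event times are defined. A seeded
without-replacement subsample of uncoupled SWRs matched to the coupled count
supports paired comparisons. Per-cycle spike statistics (percent of cycles
with ≥ 1 spike, mean spikes per cycle) are reported per class label.

## Poisson GLM

CA1 event/spike counts and thalamic spike counts are binned over rest in
250 ms bins tiled from each interval start (trailing partial bins dropped,
half-open membership). The model log μ = β₀ + β₁X is fitted by iteratively
reweighted least squares (convergence |Δβ| < 10⁻⁸ or 100 iterations) with
standard errors from the observed information and a Wald (normal) test on β₁.
X is in counts per bin; the per-1-spike/s interpretation uses Δx = 0.25
counts, and 100·(exp(β₁Δx) − 1) converts a coefficient into a percent rate
change. Counts-vs-rate scaling of X changes only β₁'s units, not the Wald p.
A constant predictor is a degenerate design and raises. No overdispersion
correction is applied (pure Poisson).

## Synthetic sessions: what is and is not emulated

The generator is statistical, not biophysical. A session is 600 s at 600 Hz
with one 440 s sleep bout (80–520 s) by default; all randomness comes from a
single seed and regeneration is bit-identical.

* **mPFC** carries 1/f background noise (exponent 1) plus, during sleep, an
  ongoing bounded-amplitude slow rhythm (1.7–2.6 Hz, ±5% amplitude
  modulation). K-complexes are planted as negative cosine half-waves (250 ms)
  at troughs of that rhythm — a KC is modelled as an extreme down-state of
  the ongoing slow oscillation, which is also what keeps the combined trough
  aligned with the planted time. KC times thin the rhythm troughs to ~0.15 Hz
  with a 2.5 s minimum and an 8 s maximum gap within a bout (non-REM keeps a
  steady slow-oscillation supply; without it the rest detector's
  both-above-mean conjunction starves in long event-free stretches). 80% of
  KCs are followed (0.2–0.4 s) by a spindle packet of 3–8 cycles at a
  frequency drawn from 8.5–11.5 Hz — the flat passband of the 6–14 Hz
  filter — starting and ending at zero crossings so every planted trough has
  both flanking peaks.
* **CA1** carries 1/f noise plus a ripple-band noise floor elevated 2.5× in
  sleep (standing in for the elevated non-REM ripple-band power that the rest
  detector relies on), 150 Hz ripple bursts (Gaussian envelope, ~50 ms)
  planted at spindle troughs with probability 0.5 per cycle and von Mises
  phase jitter (κ = 2), and a 0.15 Hz background ripple rate; a minimum
  80 ms separation prevents planted events from merging.
* **Amplitude calibration.** Planted amplitudes are expressed in multiples of
  the *background* (pre-planting) rest SD of the exact trace each detector
  thresholds, measured empirically by filtering the background channels: KC 8
  (squared-trace SD), spindle troughs and ripples 9 (voltage SD). These sit
  well above the detection thresholds because the detectors' timestamp
  tolerances (5–10 ms) demand voltage SNRs near 7–9: at lower planted
  amplitudes the noise-induced jitter of any threshold detector exceeds those
  tolerances.
* **Spikes** are exact inhomogeneous Poisson (per-sample Poisson counts with
  uniform within-sample placement). The intensity multiplies a state-dependent
  base rate, a 0.15× down-state suppression during KC half-waves, a von Mises
  spindle-phase factor exp(κ cos(φ − μ))/I₀(κ) inside participated cycles
  (per-cycle Bernoulli participation, optionally with a refractory of
  suppressed cycles after a participated one), and a multiplicative gain
  during ripples (> 1 for CA1 units, < 1 for thalamic). Rebound bursts (2–5
  spikes at 3 ms ISIs) are planted after down-states with background spikes
  cleared from the preceding 70 ms so every planted burst satisfies the
  detection criterion.
* **Participation refractory.** Sparse units that rarely fire in adjacent
  cycles are essential to reproducing the population-level result that pooled
  multi-unit activity is spindle-rhythmic while single units are not: with
  independent per-cycle participation, a unit's autocorrelation is flat
  across integer-cycle lags and its peak lag is essentially random. A
  one-cycle participation refractory moves single-unit peaks to ≥ 2 cycle
  lags (outside the spindle band) while cross-unit coincidences — which scale
  with the square of the population size — keep the pooled peak at one cycle.
  The packeted structure (3–8 cycles) is equally essential: in a continuous
  oscillation all integer-cycle lags are equally represented and no single
  pooled peak dominates. The population-level demonstration uses 16 units at
  participation 0.25; below ~12 units the same-unit two-cycle term competes
  with the cross-unit one-cycle term and the pooled peak is unstable.

Not emulated: conductance-based thalamocortical dynamics, waveform-level
spike shapes and sorting errors, REM and transitional states, theta-band
activity during wakefulness, electrode drift, and inter-animal variability.
Passing tests therefore demonstrate that the estimators recover known
structure of this statistical kind at realistic amplitudes and rates — not
that the detectors are robust to every artefact of real recordings.

## Problem sizes

The validation suite runs on desk-scale problems chosen to give each
statistic adequate power: one 600 s session per detector check (~60 KCs,
~250 spindle cycles, ~160 SWRs), 200 independent sessions for the PETH null
calibration, 1000 replicates for the Rayleigh type-I error, 100 replicates of
n = 2000 for von Mises recovery and n = 5000 bins for GLM recovery, 100
random instances for the correlogram oracle, and a 16-unit population over
300 s for the sparse-participation reconstruction.
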