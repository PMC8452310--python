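# Methods

This note documents the models, detection rules, numerical choices and
known limitations of `slowswitch`.

## Slow-wave detection

The EEG is band-passed to 0.3–4.0 Hz before detection.  The filter is
realized as a zero-phase spectral-gain filter: the rFFT of the signal is
multiplied by a real, non-negative amplitude response built from
half-cosine transition ramps solved so the gain is exactly −3 dB at
0.3/4.0 Hz and −23 dB at 0.1/4.2 Hz.  A real symmetric transfer function
adds no phase, which matters because the peak times feed the
transition-delay statistic; an IIR forward–backward design meeting the
same −23 dB point at 4.2 Hz (a 5 % transition) would need an impractically
high order.

Candidate waves are delimited by successive negative-going zero crossings
of the filtered trace (crossing times refined by linear interpolation, so
durations are sub-sample).  The negative deflection runs from the first
crossing to the intervening positive-going crossing, the positive
deflection is the remainder.  A wave is kept iff, inclusively:
negative peak < −40 µV, peak-to-peak > 75 µV, negative deflection within
125–1500 ms, positive deflection ≤ 1000 ms — all evaluated on the filtered
trace, restricted to artifact-free N2/N3 epochs (the artifact mask is
applied at the 30-s epoch level, the resolution at which records are
scored).  Peak times and amplitudes are refined by parabolic interpolation
around the extremum sample, reducing the 1/sr quantization of τ and
f<sub>τ</sub>.

## Spindle detection and co-occurrence

The sigma band (10–16 Hz) uses a linear-phase windowed-sinc FIR applied
with group-delay compensation; the nominal cutoffs are calibrated
numerically (a few fixed-point iterations on the measured response) so the
−3 dB points sit on 10 and 16 Hz.  The Hilbert envelope is smoothed with a
200-ms moving average; the threshold is the channel-wise 75th percentile
of the smoothed envelope over artifact-free N2/N3 samples only.
Supra-threshold runs separated by < 100 ms are merged, then runs of
0.5–3 s become spindles.  Note that the duration criterion applies to the
supra-threshold run: band-pass ringing and envelope smoothing widen a
physical burst by roughly 0.3–0.4 s, so a very intense burst slightly
shorter than 0.5 s can still produce a valid event.  A spindle co-occurs
with a slow wave when its onset maps to the wave phase interval
[−π, π/2].

## Wave phase and transition frequency

Each wave's internal phase is the unwrapped angle of the analytic signal
of the 0.16–4 Hz-filtered trace, anchored to 0 at the depolarization
maximum, spanning [−3π/2, π/2] from wave start to end.  The two bands are
deliberate: 0.3–4.0 Hz for detection, the wider 0.16–4 Hz for phase, so
long waves keep a monotone phase course.  The Hilbert transform is
evaluated on a window extending one wave length beyond the wave on each
side, then cropped, suppressing edge transients; waves whose padding
window does not fit in the record, whose unwrapped phase regresses by more
than 0.2 rad, or whose span overshoots the admissible range by more than
0.35 rad are flagged and excluded from connectivity (counted in the logs).
τ is the (parabolic-refined) delay between the filtered wave's peaks and
f<sub>τ</sub> = 1/(2τ).

## Switcher mixture

The per-subject f<sub>τ</sub> sample (≥ 50 values) is fitted with a
Gaussian mixture via EM (scikit-learn): k-means++ initialisation, 10
restarts, convergence at a 1e-6 log-likelihood gain, at most 500
iterations, and a variance floor of 1e-3 Hz².  The floor is deliberately
above machine scale: without it, extra components can collapse onto
near-duplicate values and win the AIC comparison spuriously; at 1e-3 Hz²
(a 0.03 Hz standard deviation, far below either mode's spread) AIC
reliably selects two components on bimodal samples and one on unimodal
ones.  AIC = 2·(3k − 1) − 2·logL for k one-dimensional components.  During
order selection a candidate k whose EM stalls is scored +∞ rather than
aborting the scan.

f\* solves the quadratic obtained by equating the two weighted Gaussian
log-densities; of the up to two roots, the one strictly between the means
is kept (no such root — e.g. two near-identical components fitted to
unimodal data — leaves f\* undefined).  Classification is
slow iff f<sub>τ</sub> < f\*, with the boundary value assigned fast.  On
pooled multichannel event tables the AIC-selected order can exceed two
because the same physical wave is detected on several channels and the
sample is not independent; the switcher model itself is always the
two-component mixture.

## Event-locked PLI connectivity

At each of six wave phases ({−π, −3π/4, −π/2, −π/4, 0} along the
transition and +π/4 after the depolarization maximum; the sixth point is
configurable since "after the maximum" is otherwise unconstrained), the
directed PLI of detection channel n is the mean over its waves of
sign sin(φ<sub>n</sub> − φ<sub>m</sub>), with both phases read from the
same full-record analytic signal.  Channels with fewer than 20 usable
waves are dropped from the directed computation (logged).

Symmetrization: pli(n\*, m) and pli(n, m\*) are averaged **in the same
n − m orientation** — reading the waves detected on m, that quantity is
the negative of the detection-first matrix entry D[m, n], so
PLI = (D[n, m] − D[m, n])/2.  True propagation then contributes with equal
signs to both terms while zero-lag (volume-conducted) synchrony cancels;
the stored matrix mirrors the n < m orientation and the magnitude is
orientation-free.  Thresholding and the GCI use |PLI|, making the result
direction-agnostic; the GCI sums |PLI| over significant upper-triangle
pairs and is therefore non-negative and monotone in the mask.

Significance uses a max-statistics null at p = 0.01 with 1000 resamples by
default (empirical quantile, linear interpolation).  In each resample the
non-detection channels' phases are redrawn uniformly on (−π, π] per event
and channel, and the maximum |PLI| over all pairs is recorded.  A
permutation of the other channel's phase vector across events — the more
conventional pairing-destruction scheme — is *invalid* for this statistic:
the detection channel's phase at a sampled wave phase is constant across
events by construction, so the PLI is almost invariant under such
permutations and nothing could ever reach significance.  Under the uniform
null the sign of sin(Δφ) is a fair coin, the family-wise error rate
measured over 500 independent-phase null datasets is 0.010 at p = 0.01,
and a planted constant lag is recovered.  Connectivity is computed
separately for slow and fast switchers by default, optionally further
stratified by spindle co-occurrence.

## Cycle dynamics

For each switcher class, the percentage of its waves in each sleep cycle
(relative to the class's whole-night total) is fitted over cycles 1–3 —
later cycles are unreliable in real cohorts — with either
y = a·e<sup>−rt</sup> (decay) or y = a − b·e<sup>rt</sup> (reduction,
a, b ≥ 0), t the 1-based cycle index.  The amplitude parameters are
profiled out by (bounded) linear least squares, so each fit is a 1-D
bounded search over r ∈ [0, 20] at 1e-12 resolution; noise-free
model-generated percentages are recovered to better than 1e-6.  In the
reduction form a and b are capped at 4·max|y|: without the cap the family
degenerates as r → 0 into an arbitrary straight line (a, b → ∞) with a
meaningless rate.  When no form is specified both are fitted and the
higher-R² one returned (ties to decay).  A class absent from a cycle
contributes a 0 % point, which an exponential decay cannot reach — the
reduction form then legitimately wins the comparison.

## Synthetic polysomnography

The generator is the package's test bed and emulates exactly the structure
the analysis assumes:

* **Background**: per-channel independent 1/f<sup>α</sup> Gaussian noise
  (α = 1, 10 µV RMS) — amplitude chosen so the delta-band noise
  (~6 µV RMS) perturbs but never mimics the 120 µV waves.
* **Slow waves**: half-sine negative lobe then half-sine positive lobe,
  both lasting τ by default (peaks at the lobe centers, so the
  peak-to-peak delay equals τ exactly); τ drawn per class from truncated
  normals (slow: 0.556 ± 0.12 s → f<sub>τ</sub> ≈ 0.9 ± 0.19 Hz; fast:
  0.278 ± 0.05 s → ≈ 1.8 ± 0.32 Hz), i.e. the two modes straddle the
  ~1.2 Hz boundary.  Truncation to [0.15, 0.95] s keeps every injected
  wave within the detector's duration criteria.  For this template
  f<sub>τ</sub> = 1/T identically; real waves with peaks displaced from
  the lobe centers decouple the two (covered by a dedicated test).
* **Rates**: per cycle c and class, counts are Poisson with mean
  3 · e<sup>−r(c−1)</sup> events per artifact-free NREM minute, with
  r = 1.3 (slow) and 1.6 (fast) — the steeper fast-switcher dissipation
  regime of young adults.  Events are placed uniformly in artifact-free
  N2/N3 with a 3-s minimum separation (no measurable placement loss at
  default rates).
* **Hypnogram**: deterministic blocks per cycle — N2, then N3, then one
  REM block (20 % of the cycle); no wake/N1 noise, no artifacts by
  default, 20 min per cycle, 3 cycles.
* **Connectivity ground truth**: all non-reference channels carry the
  events delayed by one constant 30-ms propagation lag (within the
  physiological 10–80 ms range and large enough to dominate the noise
  phase jitter).  Pairs involving the reference channel therefore have a
  constant non-vanishing lag (detectable by PLI); pairs among lagged
  channels have exactly zero lag (invisible to PLI, by design).
* **Spindles**: with probability 0.5 per wave, a Hann-windowed 13 Hz burst
  (25 µV, uniform 0.5–1.5 s) starting at wave phase −π/4.
* **Seeding**: one master seed; `SeedSequence(seed).spawn(2)` gives child
  0 to the event plan and child 1 to the noise, so the plan can be redrawn
  cheaply and identical configs are bit-identical.

What the generator does **not** emulate: realistic sleep microstructure
(K-complexes, arousals, stage transitions), scalp topographies from
volume conduction, amplitude/τ correlations within waves (assumed
independent; not asserted as physiology), inter-subject variability, or
wake/movement artifacts.  Passing tests therefore demonstrate that the
pipeline recovers the planted statistical structure under its own model
assumptions — not that detection criteria or connectivity thresholds are
optimal for any particular clinical recording.

## Problem sizes and defaults

The acceptance script analyzes one full-size synthetic night (19
channels, 3 × 20 min cycles, ≈ 2300 wave detections) with 500
max-statistics resamples, estimates the family-wise error rate from 200
independent-phase null datasets of 6 channels × 60 events (200 resamples
each), and uses n = 2000 samples and 20 replicates for the mixture
recovery checks; the test suite uses 6-channel, 8-min-cycle nights for
end-to-end checks and 500 null datasets for the FWER property.  All
file outputs are written with a fixed float format, and every stochastic
step draws from a seed derived from the single run seed, so reruns are
byte-identical.

## Known limitations

* EDF export writes 16-bit records at 0.1 µV resolution with whole-second
  records (integer sampling rates only).
* The detector's duration criteria are evaluated inclusively at the
  boundaries; the printed criteria do not specify strictness.
* Cluster statistics pool events across a cluster's channels rather than
  averaging signals; with near-synchronous waves this multiplies
  correlated events (see the mixture-order remark above).
* The reduction-form rate is only interpretable when the fitted curve is
  genuinely exponential within the amplitude caps; three cycle points
  cannot distinguish rich families.
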