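# Methods

This note documents the models, conventions and numerical choices behind
`trawlpam`, what the synthetic soundscapes do and do not emulate, and the
known limits of the processing chain.

## Signal model and units

All audio is mono, held as float samples normalized to digital full scale
(±1); integer PCM maps by division by 2^(bits−1), so the most negative code
is exactly −1. Normalization is ratio-preserving: every quantity the chain
computes (SNR, clipping fractions, class comparisons) is invariant under a
common gain, so results are identical on raw PCM counts. Times are seconds
from the start of the recording; intervals are half-open `[start, end)`.

## Noise filtering

Vessel noise (propeller, engine, flow) dominates below ~10 kHz. The chain
removes it with an 8th-order Butterworth high-pass at 10 kHz, −48 dB/octave
in its one-pass form. Default application is zero-phase (forward–backward,
`scipy.signal.sosfiltfilt`) so detected click times are not delayed by the
filter's group delay; this doubles the effective roll-off to −96 dB/octave
and, because the effective impulse response is symmetric, spreads a strong
transient's near-cutoff energy both before and after the click
(~0.5 ms of ringing at 10 kHz). A `zero_phase=False` flag restores causal
one-pass filtering. Recordings shorter than the filter warm-up
(3×(2·sections+1) = 27 samples for order 8) are rejected.

## Noise level and SNR conventions

The noise level is `NL = sqrt(mean(x²))` of a mean-removed, vocalization-free
60-s block. Block choice is the operator's (an explicit index); automatic
mode picks the block minimizing the 99th percentile of |sample|, a tail
statistic that clicks and whistles inflate but stationary noise does not.

Per-sample SNR supports two dB mappings:

* `eq1_literal` (default): `SNR(t) = 10·log10(|x(t)|/NL)` — the amplitude
  ratio under a 10·log10 map, kept as the default because it is the printed
  form of the formula this chain follows;
* `power`: `20·log10(|x(t)|/NL)`, the physically conventional mapping.

Zero-amplitude samples take a finite floor (−100 dB) so window means stay
defined. The SNR series carries its NL and convention, so a detected peak's
linear amplitude can be recovered exactly.

## Peak detection

The SNR series is cut into consecutive, non-overlapping 2-ms windows aligned
to the block start. Window w is a peak iff `mean(w) > Th` and both
`mean(w−1) < Th` and `mean(w+1) < Th`; boundary windows have a missing
neighbor and are never peaks. The isolation (neighbor) rule is what rejects
whistles and other sustained sounds: they raise many consecutive windows,
clicks raise one.

**Window statistic.** The window "mean SNR" is computed in the linear
domain: `10·log10(mean(10^(v/10)))` over the per-sample dB values `v`.
Averaging the dB values themselves (available as `mean_mode="db"`) makes the
detector inert for realistic transients: a 192-kHz, 2-ms window holds 384
samples and a click only ~15, so the dB-domain mean is pinned near the noise
floor at any physical click amplitude — the per-window sum of dB values
needed to cross a 10-dB threshold would require per-sample levels in the
hundreds of dB. Linear-domain averaging is energy-like and lets a short
transient raise its window in proportion to its actual energy.

**Threshold selection.** Peak counts are swept over Th = 4…16 dB in 0.5-dB
steps (25 points, inclusive). The selected threshold is the smallest grid
point from which the relative drop in count stays within 5% over the next
four grid points (2 dB); with no such plateau the grid midpoint is returned
with a warning. The plateau position is a property of the soundscape: the
decay at low thresholds comes from weak impulsive events (gear transients,
distant clicks), so a scene with a different transient budget plateaus at a
different Th.

**Boundary blind zone.** A click falling within a few tens of µs of a window
edge splits its energy between two adjacent windows; at 20 dB window SNR,
once ≥ ~9% of the click's energy leaks across the edge both windows exceed
Th = 10 dB and the isolation rule rejects both. With an 80-µs click
(envelope time constant 20 µs) the dangerous zone is ~50 µs of the 2-ms
window per leak direction, i.e. an intrinsic ~2–5% per-click miss rate for
uniformly placed clicks (larger under zero-phase filtering, whose
pre-ringing leaks energy backwards as well). This is a property of the
detection rule itself, measured on synthetic scenes; the detector-level
recall tests therefore run on passband scenes without the high-pass stage,
which has its own tests.

## Click trains

Reverberation copies are removed first: scanning the time-sorted peak stream
left to right, a peak is dropped iff it lies within 5 ms after the most
recently retained peak *and* its amplitude is below 0.5× that peak's. Both
parameters are configurable; the defaults are chosen so genuine feeding-buzz
clicks (comparable amplitudes a few ms apart) survive while decaying
surface/net echoes do not. The filter never removes the first peak and is
idempotent.

Trains are segmented with an adaptive rule: the next peak joins the current
train iff its gap is ≤ min(250 ms, 3 × running median of the train's ICIs);
a train with no ICI history yet accepts any gap up to 250 ms, the dataset's
stated minimum separation between trains. Fragments with fewer than 3 peaks
(2 intervals) are discarded — below that a mean ICI is meaningless.

**Gap healing.** A detector miss (boundary blind zone above) leaves a gap
close to an integer multiple of the train's typical interval and would
inflate the mean ICI by `ICI/(n−2)` per miss. Train statistics are therefore
computed on healed intervals: a gap within 15% (relative) of k× the train's
median interval, k = 2 or 3, is counted as k intervals of gap/k. Regular
trains pass through unchanged (with ICI jitter up to ±15%, a genuine
interval ratio never exceeds 1.35 while a double gap lies in 1.7–2.3×).
The raw inter-peak gaps are kept alongside the healed statistics.

Behavioral phases follow the ICI progression of foraging echolocation. The
literature ranges overlap (approach 10–40 ms vs lock-on 30–50 ms); the
mapping is disjointized at 30 ms so every train receives exactly one label:
[0, 10) feeding buzz, [10, 30) approach, [30, 50) lock-on, [50, 500] search,
above 500 ms unclassified. Mean-ICI histograms use 5-ms bins labeled by
upper edge and count *trains* (the natural unit once trains exist; a
per-click weighting is a trivial variant).

Per-block summary rows attribute a train to the block containing its start;
block ICI min/mean/max pool all healed intervals of those trains. Undefined
ICI cells are written as empty strings, never 0 — zero is a legal value and
must not encode absence.

## Whistle catalog

Whistle detection is a human act (visual inspection of 4-s spectrogram
views); the package manages the resulting catalog. A segment's mean SNR
averages the linear amplitude ratio |x|/NL over the segment and converts to
dB — so a pure tone of peak amplitude A reads
`10·log10((A/NL)·2/π)`, the 2/π being the mean of |sin| (this linear-domain
averaging is what makes that closed form hold; a dB-domain mean would
instead add the mean of log|sin| ≈ −3.0 dB). Per-class statistics are mean ±
SE with SE = SD/√n, undefined below n = 2. Class comparisons default to
Welch's t (no equal-variance assumption) with Mann–Whitney U as the
distribution-free option; the test choice is a package decision, as is the
50% spectrogram overlap (Hann, 1024 points, 187.5-Hz bins at 192 kHz).
When the pipeline runs on a synthetic scene, ground-truth whistles carry no
human quality class; a stand-in class is assigned by mean-SNR terciles,
mirroring the real catalog's property that class tracks signal strength.

## Clipping

"Signal peak" is read as the global maximum |sample| of the analyzed
recording (a full-scale-relative variant exists, since a 16-bit recorder
rails at exactly full scale). Samples with |s| ≥ threshold×peak are counted,
with ≥ rather than > so exact-rail samples count. Reports are produced at
0.99 and 0.90, and percentages are stated to 2 decimals.

## The synthetic soundscape

The generator emulates the *statistical* structure the chain assumes, not
underwater physics:

* **Vessel noise**: low-pass-shaped Gaussian noise (8th-order Butterworth at
  8 kHz, two passes) mixed with white noise under power weights, rescaled to
  an exact target RMS. The shaping cutoff sits below the 10-kHz analysis
  cutoff so the "vessel" component genuinely vanishes under the analysis
  filter (<5% residual RMS); real vessel spectra are redder and
  nonstationary.
* **Clicks**: exponentially decaying sinusoids, default carrier 60 kHz
  (within the 40–80 kHz dominant band reported for this species), default
  duration 80 µs, envelope time constant a quarter of the duration. Click k
  of a train is placed at start + sum of the first k ICIs; ground truth
  stores exact placement times. No beam pattern, no off-axis spectral
  change, no propagation loss.
* **Whistles**: phase-continuous FM tones following a breakpoint or callable
  contour in 1–30 kHz, with 10-ms raised-cosine ramps; concurrent whistles
  are logged with their overlap count (the "MW" notion).
* **Clipping**: gain then hard limiting, with the maximal runs of limited
  samples returned as ground-truth spans.
* **Calibration**: `click_amplitude_for_window_snr` inverts the window
  statistic so scenes can be built with clicks at a stated *detection-level*
  SNR — a click's window-mean SNR is far below its per-sample peak SNR
  because it occupies ~1/25 of a 2-ms window.

The bundled 140-s demo scene mirrors the study conditions at reduced scale:
two full 60-s blocks plus a 20-s remainder; a first block free of dolphin
vocalizations (the noise block); a buzz-dominated behavioral mixture with
approach/lock-on trains, a few slow search trains and one very slow train;
whistles of 0.4–0.8 s including one concurrent pair; sparse impulsive gear
transients at 3.5–9.5 dB detection SNR (without them the sensitivity curve
over Gaussian noise is flat and has no meaningful plateau); and overload
that clips only the strongest clicks, leaving whistles and transients
untouched. Scene defaults (noise RMS 0.0015 of full scale with 99.5% of its
power below 10 kHz, click amplitude ~0.6 before overload gain, whistle
amplitudes 0.05–0.07) were set so that near-full-scale clicks sit above a
Th = 10 dB window threshold over the post-filter noise floor with a margin
of a couple of dB — the regime the study recording was in. Overload trims
the strongest click crests and therefore *lowers* click SNR slightly (the
rails cap the clicks while the gain scales the noise in full), which is why
the margin is set at the noise bed, not at the limiter.

Passing tests on these scenes show the chain recovers what it assumes:
isolated broadband transients over locally stationary noise. They do not
show robustness to surface reverberation beyond simple decaying echoes,
overlapping trains from multiple animals clicking simultaneously at similar
amplitude, nonstationary noise, or real hydrophone/recorder responses.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is bit-reproducible.
The test suite and the acceptance script use reduced problem sizes chosen to
exercise the full chain: recovery scenes of ~30–90 s at 96 kHz with 12
clicks per train and two seeds per run (≈170 ground-truth clicks across mean
ICIs 5–120 ms), the 140-s demo scene at 192 kHz, and a rate-reduced
(1 kHz) 5900-s recording for segmentation arithmetic, which depends only on
durations. Detection-level figures quoted anywhere in the documentation are
produced by those runs, not transcribed from elsewhere.

## Known limitations

* The sensitivity-curve plateau, and hence an auto-selected Th, is
  scene-dependent; on the demo scene it lands at 7.5 dB, not at any
  particular canonical value.
* Recall at the detection margin degrades gracefully but trains placed near
  the threshold can drop below the 3-peak minimum and vanish (the demo scene
  loses 1 of 13 trains this way).
* The reverb filter cannot separate two animals clicking interleaved at
  comparable amplitude; such streams segment into a single train with mixed
  ICIs.
* Social burst pulses with predominantly low-frequency energy are outside
  the chain's reach by construction: the 10-kHz high-pass removes them.
* Whistle quality classes on synthetic runs are an SNR-tercile stand-in, not
  a perceptual classification.
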