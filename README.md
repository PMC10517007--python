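# trawlpam

Passive-acoustic analysis of bottlenose dolphin (*Tursiops truncatus*)
vocalizations recorded during trawl-fishery interactions — and a synthetic
underwater soundscape simulator that makes every stage of the analysis
testable without the original multi-gigabyte recording.

Dolphins depredating a trawl emit three sound families: narrow-band
frequency-modulated **whistles** (≈1–30 kHz, 0.4–0.8 s), broadband
**echolocation clicks** (tens of µs, dominant energy ≈40–80 kHz) organized in
trains, and burst pulses including **feeding buzzes**. The inter-click
interval (ICI) of a train indexes the animal's behavioral phase: slow search
trains (ICI > 50–80 ms), lock-on (30–50 ms), approach (10–40 ms), and the
terminal feeding buzz (ICI < 10 ms). This package implements the processing
chain used on such recordings:

1. **High-pass filtering** — Butterworth, order 8, cutoff 10 kHz
   (−48 dB/octave), removing propeller/engine noise.
2. **Block segmentation** — consecutive 60-s analysis blocks (a 98-min-20-s
   recording gives 98 full blocks plus one 20-s block).
3. **SNR computation** — per sample, against the noise level
   `NL = sqrt(mean(NOISE(t)²))` of a vocalization-free block:
   `SNR(t) = 10·log10(SIGNAL(t)/NL)` with `SIGNAL(t)` the mean-removed
   sample magnitude (a 20·log10 power convention is available).
4. **Peak detection** — mean SNR over consecutive 2-ms windows; a window is
   a peak iff its mean exceeds a threshold *Th* while both neighboring
   window means stay below *Th* (clicks are transient; whistles and noise
   are not). *Th* is chosen where the count-vs-threshold sensitivity curve
   (4–16 dB in 0.5-dB steps) plateaus.
5. **Click-train classification** — reverb/overlap filtering by amplitude
   ratio within a 5-ms echo window, adaptive ICI segmentation
   (gap ≤ min(250 ms, 3 × running median ICI)), per-train mean ICI, 5-ms-bin
   histograms, and behavioral phase labels.
6. **Whistle catalog statistics** — per-quality-class (1–3) duration and
   mean SNR with standard errors, pairwise class comparisons, and
   1024-point Hann spectrograms in a 4-s view.
7. **Clipping analysis** — fraction of samples at ≥99% and ≥90% of the
   signal peak, quantifying recorder overload from close-range vocalizing.

The simulator (`trawlpam.synth`) generates scenes with ground truth —
vessel noise, impulsive gear transients, phase-structured click trains,
concurrent whistles, deliberate overload — so detection recall and ICI
recovery are measured against known answers.

## Worked example

```python
import trawlpam as tp

scene, gt = tp.demo_scene(seed=1)            # 140-s scene with ground truth
filtered = tp.highpass(scene)
blocks = tp.split_blocks(filtered)
idx = tp.select_noise_block(blocks)
noise = tp.estimate_noise_level(blocks.blocks[idx], idx)
series = [tp.compute_snr(b, noise, block_index=i)
          for i, b in enumerate(blocks.blocks)]
curve = tp.threshold_sweep(series)
th = tp.select_threshold(curve)
peaks = [p for s in series for p in tp.detect_peaks(s, th)]
trains = tp.segment_trains(tp.filter_reverbs(peaks))
```

Running `python examples/02_click_detection.py` (which is the above plus
printing) gives:

```
3 blocks; noise block 0, NL = 4.53e-04 (-66.9 dBrms)
sweep: 207 peaks at 4 dB -> 0 at 16 dB; plateau threshold Th = 7.5 dB
182 peaks -> 12 click trains (ground truth: 210 clicks, 13 trains)
mean-ICI histogram (bin upper edge ms: trains): {'5': 3, '10': 3, '25': 1, '30': 2, '40': 1, '85': 1, '120': 1}
6 feeding buzzes (mean ICI < 10 ms) — close-range prey capture next to the codend
```

Reading: the quietest 60-s block sets the noise floor; the sensitivity curve
decays (low thresholds also collect gear transients) and plateaus at 7.5 dB
for this scene; 12 of the 13 placed trains are recovered, with the 5/10-ms
histogram bins dominating — the buzz-heavy signature of dolphins inspecting
the net at close range. One placed train sits near the detection limit and
is lost, which is what a threshold detector does at its margin.

The other scripts in `examples/` cover soundscape simulation, whistle-class
statistics, clipping reports and the one-call pipeline
(`tp.run_pipeline({...})`), which writes the deposit-style artifact set:
`results.csv`, `clicks.txt` / `whistles.txt` (Audacity label tracks),
`sweep.csv`, `ici_histogram.csv`, `whistle_stats.csv`, `clipping.csv`,
spectrogram PNGs and a run log. A thin CLI wraps the same calls
(`trawlpam --help`).

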