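# Methods

## What the simulator emulates

The generator stands in for a seven-button P300 selection system recorded
from seven dry electrodes (Fz, Pz, Oz, P3, P4, PO7, PO8) at 300 Hz against a
left-ear reference. One *selection* flashes every button `n_blinks` times
(30 in training, 20 online) in blockwise-random order — each round of seven
flashes is a fresh permutation, which guarantees equal button counts and
bounds target-to-target spacing, standard speller practice. Flashes last
100 ms with a 100 ms gap, so the stimulus-onset asynchrony is exactly
200 ms; the onset is the instant the button toggles to its highlight colour.

Every *target* flash adds a Gaussian bump to each channel:

- `peak_amplitude_uv` (default 5.09 µV) scaled per channel by a posterior-
  dominant topography (Pz 1.0, P3/P4 0.8, PO7/PO8 0.7, Oz 0.6, Fz 0.5),
- `peak_latency_ms` (default 415.88 ms) post-onset,
- `width_ms` = 100 ms full width at half maximum.

The defaults mirror the grand-average peak statistics of the 17-subject
outcome tables packaged with the library. Non-target flashes add nothing.

Background activity is additive and independent per channel (and for the
reference electrode), seeded explicitly:

| component | default | what it exercises |
|---|---|---|
| 1/f ("pink") noise | 6 µV SD | the dominant EEG background; low-frequency power that the classifier must average out |
| white noise | 3 µV SD | sensor noise; mostly removed by the 30 Hz lowpass |
| alpha rhythm | 3 µV SD | 8–12 Hz narrowband noise; survives the bandpass untouched |
| drift | 2 µV·√s random walk | electrode drift; removed by the 0.1 Hz highpass |
| artifacts | off (rate 0/min) | 100 ms bipolar transients for the QC rules |

The alpha component is narrowband-filtered noise rather than a sinusoid: a
pure 10 Hz tone would be exactly periodic with the 200 ms SOA, hence
phase-locked to every flash, and would never average out of ERPs — real
alpha is not stimulus-locked. Artifact pulses are single sine cycles
(zero-mean, fundamental ≈ 10 Hz) so their peak amplitude survives both
baseline correction and the analysis bandpass.

The noise defaults are the package's "moderate noise" study condition,
calibrated once so that decoding a 5 µV P300 lands in the 85–95 % accuracy
range typical of healthy subjects, and kept fixed thereafter.

What the simulator does **not** model: trial-to-trial latency and amplitude
variability of the P300 (every target response is identical), habituation,
eye blinks/EMG with realistic morphology, inter-channel noise correlation,
or any rendering difference between the two "environments" (they differ
only in noise seeds — the null hypothesis of the environment comparison is
true by construction). Passing tests therefore show the *pipeline* is
correct and well-behaved, not that real-EEG performance would match.

## Signal processing

Stage order follows the online system: re-reference → bandpass → epoching →
baseline correction → consecutive averaging → decimation.

- **Filtering** is applied to the continuous recording (before epoching)
  with a 5th-order Butterworth bandpass, 0.1–30 Hz, implemented as
  second-order sections for numerical stability at the 0.1 Hz corner.
  Causal (forward-only) filtering is the default, mirroring what an online
  decoder could compute; zero-phase forward–backward filtering is available
  and is used for ERP waveform analysis, where the causal group delay
  (~10–15 ms at the P300's frequency content) would bias peak latency.
- **Epochs** span 0–1000 ms from each onset (300 samples at 300 Hz); events
  whose epoch would overrun the recording are dropped, not zero-padded, and
  counted. Note that at a 200 ms SOA consecutive epochs overlap.
- **Baseline correction** subtracts each epoch's whole-window per-channel
  mean — the epoch starts at the stimulus, so no pre-stimulus interval
  exists. This removes slow amplitude shifts but also removes the ERP's own
  mean (≈ 0.5 µV for the default bump), a known small negative bias on
  measured peak amplitude.
- **Consecutive averaging** groups epochs by (selection, button), ordered by
  onset, and never crosses selection boundaries. *Sliding* mode (step 1) is
  the training default: 30 blinks → 11 averaged exemplars per button per
  selection, a standard augmentation that reconciles "continuous" averaging
  with limited training data. *Block* mode is used online: the 20 blinks per
  button form exactly one averaged feature epoch.
- **Decimation** keeps every 3rd sample from index 0 (300 → 100 Hz). No
  extra anti-alias filter: the 30 Hz lowpass already bounds content well
  below the new 50 Hz Nyquist.

Every stage is linear, so the pipeline commutes with scaling/addition of
recordings sharing a schedule; the tests check this to 1e-6 relative
tolerance.

## Classification

Features are the flattened averaged epoch (7 channels × 100 samples = 700).
The two-class discriminant is w = Σ̂⁻¹(μ₁ − μ₀) with the pooled within-class
covariance shrunk toward (tr S/p)·I at the analytic Ledoit–Wolf intensity —
plain LDA is singular here because features far outnumber exemplars. A
pseudo-inverse variant is provided for comparison. Training data with *no*
within-class scatter (noise-free simulations) degrade to the matched filter
w = μ₁ − μ₀, the limit of the shrunk solution as scatter vanishes.

At decision time each button's epoch scores (w·x + b) are summed and the
highest sum wins; ties break to the lowest button index. Summing raw
discriminant values keeps the rule invariant to positive scaling and to
per-epoch constant shifts when button counts are equal.

## Quality control

Screening runs on baseline-corrected, un-averaged epochs at the native rate
(averaging would dilute the transients it should catch; decimation could
miss their peaks): an epoch is bad iff max |amplitude| over all channels and
samples **strictly exceeds** 80 µV; a selection is contaminated iff bad
epochs **strictly exceed** 50 % of its epochs; a subject is excluded iff
**at least** 10 of the 15 selections in either environment are contaminated.
The strict/inclusive readings are deliberate and pinned by boundary tests
(80 µV exactly → good; 70 of 140 → clean; 10 of 15 → excluded).

## ERP measurement

Grand averages use single-blink target epochs (zero-phase filtering,
decimated to 100 Hz). Peak measurement is automated: the maximum positive
value on a designated channel (default Pz, the classic P300 site; a
"mean-parietal" Pz/P3/P4 policy is available) within a 250–600 ms window,
ties to the earliest sample. Direction-wise summaries use the mean amplitude
over 300–500 ms inclusive.

At moderate noise the argmax latency on the 100 Hz grid retains a jitter of
roughly ±1 sample (±10 ms) and occasionally ±15 ms: after averaging 300
epochs the trace keeps ~0.4–0.5 µV of sample noise while the filtered bump
is only ~0.27 µV higher at its peak than 15 ms away. Multi-channel decoding
is considerably more noise-efficient than single-channel peak picking, so
conditions calibrated by decoding accuracy leave peak estimates close to
their resolution limit — a limitation to keep in mind when interpreting
per-subject latencies.

## Statistics

- `describe` reports the mean and the **population** standard deviation
  (divisor n), the convention that reproduces the packaged tables' summary
  rows from their own columns; reporting rounds halves away from zero to
  2 dp.
- Wilcoxon signed-rank: zero differences dropped, midranks for ties, exact
  null distribution (dynamic programming over doubled ranks, valid under
  ties) for ≤ 25 usable pairs, tie-corrected normal approximation with
  continuity correction beyond. Two-sided p = min(1, 2·min(lower, upper)).
- Wilcoxon rank-sum: same construction over all subsets for combined
  n ≤ 20, normal approximation beyond.
- Kolmogorov–Smirnov normality screening fits the sample's own mean/SD and
  uses the asymptotic p-value (a pragmatic screen, as in common practice,
  though fitting inflates p slightly).
- FDR adjustment is Benjamini–Hochberg step-up (via statsmodels), order
  preserved, verified against a hand-coded step-up oracle.
- α = 0.05 throughout.

The environment comparison reports, per field (accuracy, latency,
amplitude): KS screening per environment, the paired signed-rank test, raw
and FDR-adjusted p-values, and the verdict. Fields with identical paired
values are reported as degenerate rather than tested. The preference-group
summary reports all four group-by-environment mean cells as recomputed from
the table — consumers should trust these recomputed values over any
externally quoted cross-group numbers.

## Degenerate inputs and tie-breaks (summary)

- Selection decision ties → lowest button index.
- Peak ties → earliest sample; monotone traces peak at the window edge.
- Zero within-class scatter → matched-filter LDA (descriptor records it).
- All-zero paired differences, zero-variance samples → signalled as
  degenerate errors, never silently tested.
- Empty epoch groups in consecutive averaging → zero outputs, logged.

## Problem sizes

Simulation studies default to the protocol's own sizes: 5 training
selections × 30 blinks, 15 online selections × 20 blinks per environment
(300 target epochs per ERP average), 20 seeded repetitions for recovery
studies, and 200 selections for chance-level checks.
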