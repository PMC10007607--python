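# Methods

`affectstream` implements a streaming pipeline for binary emotion
classification from consumer-grade EEG: per-window signal cleaning,
tumbling-window band-power features, thresholded valence/arousal labels,
incremental classifiers, and prequential evaluation in both the
immediate-label and delayed-label regimes. This note records the model,
the defaults and why they were chosen, the numerical conventions, and
what the synthetic experiments do and do not demonstrate.

## Signal model and preprocessing

Input is a multichannel EEG stream (microvolts) from one of three device
profiles: Muse S (4 channels @ 256 Hz), Neurosity Crown (8 @ 256 Hz),
Emotiv EPOC (14 @ 128 Hz). Cleaning is deliberately minimal — it must
run per window in real time — and consists of, in order:

1. **Notch filter**: second-order IIR notch at `f0 = 50` Hz (mains;
   configurable to 60 Hz), quality factor `q = 30` (narrow, ~1.7 Hz
   bandwidth).
2. **Band-pass**: fifth-order Butterworth, 0.5–45 Hz, removing DC drift
   and high-frequency noise.
3. **Common average reference (CAR)**: per sample, the mean across
   channels is subtracted from every channel, so each row sums to zero.

Filters are applied *statelessly per tumbling window*: no filter state
crosses window boundaries, which keeps windows causally independent and
makes the streaming computation embarrassingly simple. The cost is an
edge transient at every window start. Filtering is causal
(forward-only) by default because that is the only variant realizable
sample by sample in a live system; zero-phase forward–backward filtering
is a configuration option for offline work. Attenuation contracts
(e.g., "50 Hz suppressed below 0.1× RMS") are steady-state,
frequency-response properties and are tested on the settled portion of
the signal; within a 1-s window the notch transient has not fully
decayed, which is an accepted property of the causal per-window design,
not a defect.

## Features

The stream is segmented into tumbling windows of `l` seconds
(`l * sf` samples, no overlap; trailing partial windows dropped).
Where a stimulus interval is known, windows are aligned backward from
the stimulus end, giving `floor(duration / l)` windows per stimulus;
otherwise pre-existing windows wholly inside the interval are used.

Per window and channel, a Welch PSD (Hann taper, segment length
`min(window, 1 s)`, 50% overlap — so the primary 1-s setting degenerates
to a single full-length segment) yields 16 features:

* powers in Delta (0.5–4 Hz), Theta (4–8), Alpha (8–16), Beta (16–32),
  Gamma (32–45) — the Alpha band is deliberately wider than the textbook
  8–13 Hz and is kept as this pipeline's convention;
* total power over 0.5–45 Hz;
* the 10 unordered pairwise band-power ratios `band_i / (band_j + ε)`,
  `i < j` in the fixed band order, `ε = 1e-12` guarding silent channels.

Band powers integrate the PSD over bins whose centers fall in the
half-open band `[low, high)`, as `sum(psd) * Δf`. The rectangle rule was
chosen over trapezoidal quadrature so that the five bands exactly
partition the 0.5–45 Hz range: total power equals the sum of the band
powers to machine precision, which is both physically sensible and an
exact testable invariant. Feature vectors are channel-concatenated:
64 / 128 / 224 values for the 4- / 8- / 14-channel profiles.

Amplitude scaling `x → a·x` multiplies all powers by `a²` and leaves all
ratios unchanged — a tested invariant that makes the ratio features
gain-invariant across devices.

## Labels

Ratings arrive per stimulus and affect dimension (valence, arousal) as
delayed tuples `(dimension, rating, t_start, t_end)` on the unit scale;
1–9 SAM ratings are first mapped affinely to [0, 1] so the scale
midpoint 5 lands on 0.5. A single threshold at 0.5 defines *low* and
*high* classes; ties go to *high* (configurable). A window receives a
tuple's class iff it lies wholly inside the tuple's interval;
overlapping tuples within one dimension are rejected as ambiguous.

## Classifiers

All learners satisfy a learn-one/predict-one contract (predict never
mutates; scores are P(high); an untrained model answers high at 0.5,
consistent with the tie rule).

* **Online logistic regression** (written here from first principles):
  one unregularized SGD step on the log-loss per sample,
  `w += lr (y − p) x`, learning rate 0.1.
* **Adaptive forest** (`arf`): online bagging (Poisson(6) example
  weighting) over incremental Hoeffding trees; each leaf draws a fresh
  random feature subset of size √F; each tree carries a DDM-style error
  monitor (running error rate p and binomial SD s; drift when
  `p + s > min(p + s) + 3·s_min`) and is replaced by a fresh tree when
  it fires.
* **Random patches** (`srp`): the same bagged trees, but each ensemble
  member is confined to one fixed random 60% subset of the features for
  its lifetime.

The Hoeffding tree itself accumulates per-class Gaussian sufficient
statistics per candidate feature at each leaf (Welford updates), scores
10 equally spaced thresholds per feature by information gain estimated
through the Gaussian CDFs, and splits when the best candidate beats the
runner-up by more than the Hoeffding bound
`sqrt(ln(1/δ) / 2n)` (δ = 1e-7) or the bound falls below the
tie-break τ = 0.05; a grace period of 200 (weighted) examples separates
split attempts, depth is capped at 20, and leaves predict
Laplace-smoothed class frequencies. These defaults are the standard
VFDT settings. The ensembles are compact implementations of the
adaptive-random-forest and streaming-random-patches ideas — bagging,
per-node or per-member feature randomization, drift-triggered member
replacement — not feature-complete ports (no background trees, no ADWIN;
the DDM reset plays the drift-adaptation role).

## Evaluation protocols

**Progressive (test-then-train) validation**: each labeled vector is
classified by the current model, the prediction is scored into a running
confusion matrix, and only then does the model train on it. Every sample
serves both roles; the trajectory records cumulative accuracy, per-class
F1 and macro F1 after every scored prediction.

Metrics: `accuracy = (TP + TN) / (TP + TN + FP + FN)`;
`F1 = TP / (TP + (FP + FN)/2)`; macro F1 averages F1 with *high* positive
and with *low* positive. A degenerate F1 (no positives anywhere) is
defined as 0 with a warning. The final trajectory values are required
(and tested) to equal an independent offline recomputation from the
logged (prediction, label) pairs.

**Delayed progressive validation**: vectors are classified on arrival
and buffered; when a label tuple arrives, all buffered predictions
inside its interval are scored (one metric update per prediction, in
window order) and the model then trains on those samples in window
order. A label arriving at exactly a window's end is processed *after*
that window's prediction, so with zero delay the protocol reproduces
progressive validation exactly — a tested equivalence. Label tuples
matching no buffered prediction raise a warning, not an error.

**Shuffle-repeats**: consecutive windows share a stimulus label for up
to minutes at a time, and a model streamed such data can score well by
merely repeating the previous label; shuffling windows (with their
labels) among one another destroys that shortcut. The immediate-label
experiment therefore runs k = 10 seeded shuffles of the full labeled
set, each evaluated prequentially on a fresh classifier, reporting mean
and SD of the final macro F1 and accuracy. This is the streaming
analogue of k-fold cross-validation that keeps every sample usable for
both testing and training; a classic 9/1 split is deliberately not the
default because it would discard the test fold from training, which the
prequential setting renders unnecessary.

**Induced delay**: to emulate production label latency on an otherwise
immediate-label session, the session replays in time order and every
window's true label arrives a fixed lag late (default 86 windows — the
mean stimulus length in seconds at 1-s windows).

## Synthetic sessions

The generator emulates the study design the pipeline targets: 16 videos
(durations normal with mean 86.7 s, SD 27.8 s, clamped to 51–150 s),
four per valence–arousal quadrant, seeded random order, 15–30 s
questionnaire gaps, one rating per dimension delivered at each video's
end. The signal is a sum of five in-band sinusoids (seeded frequency,
per-channel random phase so CAR cannot cancel them), 1/f pink noise
(spectrally shaped white noise, 6 µV RMS), and 50 Hz mains interference
with ±20% per-channel amplitude spread (so the notch, not the
reference, must remove it). Class structure is multiplicative on band
amplitudes — by default high/low valence scales the alpha amplitude by
1.6/0.625 and high/low arousal scales beta likewise — hence ~2.56× on
band power, a strong but not degenerate effect expressed in exactly the
features the schema measures. Ratings are the quadrant's nominal value
(0.75 high, 0.25 low) plus clipped Gaussian noise (SD 0.08), so the 0.5
threshold occasionally flips a label — a small, controllable label-noise
rate (~0.1% per tuple at the default SD).

What passing synthetic tests shows: the pipeline recovers configured
band-power class structure through the full stream path (cleaning,
windowing, features, labels, prequential evaluation), reports chance
when no structure exists, and degrades under label delay. What it does
not show: performance on real EEG, where effects are weaker,
non-stationary, subject-specific, and contaminated by ocular/muscle
artifacts the minimal preprocessing does not remove, and where true
band topography matters. Synthetic macro F1 values are not comparable
to results on recorded datasets.

## Problem sizes and numerical choices

Tests and the acceptance script run full-length default sessions (16
videos ≈ 1300 one-second windows at 256 Hz) for the recovery and delay
checks, ten seeds for the null check, and 4-video sessions (~2 min of
signal) elsewhere; these sizes give stable statistics while keeping the
whole suite in the minutes range. Windows are half-open `[t, t + l)`;
timestamps are float seconds from stream start with a 1e-9 tolerance on
interval comparisons; device profiles carry the sampling rate so window
sizing never infers it from timestamps. Classifier state serializes to
a versioned pickle blob for the two-part live protocol.

## Known limitations

* EDF/recording-app import is not implemented; CSV is the recording
  interchange format.
* The ensembles are compact re-implementations (see above), so their
  numbers will not bit-match any particular reference library's ARF/SRP.
* Per-window stateless filtering leaves an edge transient inside every
  window; with 1-s windows the notch does not reach its steady-state
  rejection within the window.
* Statistical comparison between devices or classifiers (t-tests) is
  out of scope; the run artifacts expose per-repeat metrics for external
  analysis.
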