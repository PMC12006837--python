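# Methods

This note documents the models behind the synthetic data, the
quantification conventions where the field's verbal descriptions are
ambiguous, the numerical choices, and the known limitations — in
particular what the synthetic recovery results do and do not demonstrate
about real recordings.

## Burst detection

### Conventions

The detector works on 100-ms spike counts with a 500-ms window stepped
one bin at a time. All edge conventions are deterministic:

- window rate = (sum of 5 bin counts) / 0.5 s;
- a burst opens at the first window with rate **strictly greater** than
  8 Hz ("exceeded") and closes at the first window **strictly below**
  4 Hz ("fell below"); windows in between, at or above 4 Hz, sustain it;
- onset = start time of the opening window; offset = start time of the
  last sustaining window + 0.5 s; the next event search resumes at the
  first window starting at or after that offset, so events never overlap;
- events with duration ≥ 1.5 s are "long", otherwise "short"; a duration
  of exactly 1.5 s is long;
- bins are half-open `[t, t+0.1)`: a spike exactly on an edge belongs to
  the later bin.

Choices the verbal description leaves open, fixed here: Butterworth order
4, applied forward–backward (zero phase) so spike times are not skewed;
filtering precedes ×10 decimation (the 1000-Hz band edge is below the
decimated Nyquist of 1250 Hz, so anti-aliasing is inherent); the MAD is
computed over the full analyzed span, not per segment; no merging of
bursts separated by a single sub-threshold window; spike detection uses
negative-going crossings only, with a 2-ms refractory period to
de-duplicate multi-sample crossings of one spike; the MAD carries no
1.4826 Gaussian-consistency factor. The analysis span is configurable
(`DetectorConfig.analysis_span`); recordings analyzed in practice use
5–60 min after the baseline period.

### Duration smearing is a property of the convention

A window straddling a burst edge can already (or still) satisfy the rate
criterion, so reported events are systematically longer than the
underlying elevated-rate epoch: the onset leads it by up to ~0.3 s and
the offset trails it by ~0.3–0.45 s. On synthetic bursts the measured
duration bias is +0.49 s, essentially all of the 0.50-s mean absolute
duration error. Users comparing event durations across conditions are
unaffected (the bias is common), but absolute durations include this
constant.

### The 5×MAD threshold on Gaussian noise implies ~1 Hz of false spikes

For Gaussian noise the unscaled MAD is 0.674 σ, so the 5×MAD threshold
sits at 3.37 σ. At the 2.5-kHz decimated rate this yields a spurious
downward-crossing rate of about 1 Hz *independent of the noise scale*
(the threshold adapts to σ) and nearly independent of its spectrum (the
crossing rate is bounded below by the 300-Hz filter-band floor times the
Gaussian tail mass; empirically 1.0–1.1 Hz for white, low-passed and
brown input noise). Two consequences, both visible in the recovery
numbers:

- occasional 0.5-s windows collect ≥ 5 spurious spikes and appear as
  false events; at the default conditions this puts the event-level
  false-discovery rate near 0.035 (fluctuating roughly 0.03–0.06 over
  seeds);
- a pair of spurious spikes in the window after a burst reaches the 4-Hz
  sustain rate and chains the offset outward, so a few percent of short
  (0.6–0.8 s) events are reported ≥ 1.5 s and cross the short/long
  boundary. Short/long classification against ground truth is therefore
  ~96–99% rather than 100%, a floor set by the detector's own threshold
  rule, not by implementation error. Real recordings, whose background
  is not Gaussian and whose bursts are not bracketed by known truth, are
  affected analogously through baseline-dependent false-event rates.

### Synthetic extracellular model

Gaussian noise (default σ = 10 µV at 25 kHz) plus a biphasic spike
template (0.45-ms negative lobe, 0.75-ms positive lobe at 40% amplitude;
peak −80 µV). Background activity is Poisson at 0.05 Hz outside bursts.
Inside declared burst intervals spikes fire as a jittered clock (interval
= 1/rate ± 10%) at 12 Hz by default — epileptiform population discharges
are rhythmic, and clock-like intra-burst spiking also keeps window counts
near their expectation so that detector edge behavior is testable; a
Poisson intra-burst mode is available. Default event plan per 10-min
trace: 12 bursts, short events uniform on 0.6–0.8 s (probability 0.6) and
prolonged discharges uniform on 2.2–3.0 s, separated by ≥ 8 s — the two
duration classes are placed on either side of the 1.5-s boundary far
enough that the window-convention lengthening described above cannot, by
itself, move an event across it. The generator does not model biophysical
waveform diversity, bursts with graded onsets/offsets, electrode drift,
or non-Gaussian background "hash"; passing recovery tests demonstrates
the detector implements its stated conventions, not that those
conventions are optimal for any particular preparation.

## Spine-volume quantification

### Measurement chain

Per timepoint: maximum-intensity z-projection (the description of the
projection step is ambiguous between max and sum; max is the default and
a sum projection is one switch away — for relative volumes the two agree
exactly in the noise-free limit); integer-translation registration to the
first timepoint estimated by phase cross-correlation (rotation is out of
scope); 20×20-px ROI sums. Background is measured at 3 structure-free
ROIs, averaged per pixel and subtracted (`corrected = raw − 400·b(t)`),
which makes the measurement exactly invariant to any spatially uniform
offset. Global fluctuations (laser power, photobleaching) are measured at
4 stable reference ROIs: each is background-corrected and divided by its
own baseline mean, the four are averaged into `g(t)`, and spine values
are divided by `g(t)` — exactly cancelling any global multiplicative
gain. Each spine is finally expressed as % of its own baseline mean
(all baseline timepoints, 30 min).

### Drift exclusion

A least-squares line is fitted to the baseline of the session-mean
normalized trace; drift % = |fit(last) − fit(first)| / mean(fit) × 100;
sessions above 7% are excluded. The exclusion unit is the experiment
(session), which is also why the decision is made on the across-spine
mean trace: averaging suppresses single-ROI shot noise so the rule
responds to genuine preparation drift. Per-spine QC values are reported
alongside. With fewer than 3 baseline points the QC is undefined and the
series is flagged, not silently passed.

### Synthetic imaging model

Dendrite ridge (Gaussian cross-section, σ = 2 px) plus 3-D Gaussian-blob
spines (σxy = 1.6 px, σz = 1.2 µm) and 4 stable reference blobs, placed
on a 26-px grid so every ROI holds one structure; spine ROIs keep clear
of the ridge (constant non-spine fluorescence inside a spine ROI would
bias the relative-volume ratio — references are immune because they are
normalized to their own baseline). True volumes step to the shrink
fraction (default 0.8) at timepoint 8 (32 min). Bleaching is a global
multiplicative exponential (2%/timepoint) — exactly the structure the
4-reference correction is designed to remove; stage jitter is an integer
translation within ±3 px; shot noise is Poisson on intensities. Default
integrated spine brightness is 60 000 counts, giving per-timepoint
measurement noise of ~0.5% so that the 7% drift rule operates far from
the noise floor. The residual-drift parameter injects a linear ramp into
baseline spine volumes only (ramp to 1+d across the baseline ≈ drift of
d/(1+d/2)·100%: d = 0.10 → ≈ 9.5%, d = 0.04 → ≈ 3.9%). Not modeled:
optical PSF and depth attenuation, dendrite remodeling, spine turnover,
rotational drift, detector offset drift. Analyses and tests run
128×128×8 frames with 3 spines per session (the generator's default is
the full 512×512×15 with 15 spines); ground truth is relative volume, so
frame size does not enter the recovered quantities.

## fEPSP analysis

The initial slope is fitted by least squares over the contiguous samples
between 20% and 80% of peak negativity on the falling phase (fractions
configurable), after a 1-ms post-stimulus blanking window; the baseline
level and noise floor come from the pre-stimulus segment, and sweeps with
no deflection beyond 5 baseline SDs are flagged missing rather than
fitted. Normalization divides by the baseline-window mean (×100); LTD
magnitude is the mean normalized slope in the post window (defaults:
last 10 min of baseline; 50–60 min post induction; a variant using the
last 10 min of the recording against the pre-drug baseline is a window
choice, not a code path). Percent block of isolated responses is
computed from response amplitudes/means supplied by the user — whether
those means are amplitudes or slopes is the caller's convention.

The synthetic session: one sweep per 30 s; fEPSP modeled as a difference
of exponentials (rise 1.5 ms, decay 8 ms, peak −1 mV) 1.5 ms after a
0.4-ms biphasic stimulus artifact; synaptic strength 1.0 through the
baseline, stepping to the depression fraction at induction, with
multiplicative per-sweep noise (default CV 5%). Fiber volleys,
population spikes, paired-pulse structure and slow drifts are not
modeled.

## Metabolic labeling

Incorporation rate = triplicate CPM mean / mg protein (triplicate SD is
retained for QC but not used in the estimate). Each rate is divided by
the labeling-dose activity and then by the batch mean of dose-corrected
rates (the two divisions commute); batch means are 100% to machine
precision by construction. An anchored variant expresses values relative
to a designated group's mean (e.g. WT = 100%) instead of the all-slice
mean. The generator draws lognormal slice effects (CV 10% default),
lognormal protein amounts, and a multiplicative group effect; with two
equal-n groups of true ratio r, the normalized group means are exactly
200/(1+r) and 200r/(1+r) in the noise-free limit (93.0% and 107.0% at
r = 1.15).

## Statistics

- Outlier rule: one pass, on the full input; drop x with
  |x − mean| > 2·SD (sample SD); values exactly at the boundary are
  retained. The rule is applied to raw group values before testing.
- SEM = sample SD/√n, undefined (flagged) at n = 1.
- t-tests: classical pooled-variance Student (not Welch) for unpaired
  data; one-sample t on differences for paired. Zero variance with equal
  means returns p = 1 by convention.
- One-way ANOVA: classical F; post hoc pairwise pooled-t p-values are
  Bonferroni-multiplied by the number of comparisons and capped at 1.
- Fisher exact, two-sided, point-probability rule: sum of hypergeometric
  probabilities over all tables with the observed margins whose
  probability is at most that of the observed table; ties included with
  a 1 + 1e-7 relative tolerance (the convention GraphPad and scipy
  share). Probabilities are computed with log-factorials; a
  rational-arithmetic enumeration oracle in the test suite confirms
  agreement to 1e-12. Degenerate margins give p = 1. On the published
  seizure-incidence counts (2/15 vs 9/11 seized; 9/11 vs 5/16) this
  reproduces p = 0.0009 and p = 0.018 at printed precision.

## Pipeline and reproducibility

All analysis constants (band, MAD factor, bin/window widths, hysteresis
rates, class threshold, ROI geometry and counts, drift threshold,
analysis windows, outlier k) are named defaults on config objects, never
literals inside algorithms. Every generator consumes a single seeded
`numpy.random.Generator`; `run_pipeline` writes a manifest with a config
hash and SHA-256 checksums of every output, and identical config + seed
reproduce identical checksums. `make_fixtures` writes a canonical small
dataset, including the audiogenic-seizure cohort with the published
incidence counts written verbatim (2/15 WT-saline, 9/11 KO-saline,
5/16 KO-Glyx-13, and the WT-Glyx-13 group at 2/15 — its exact published
count is not stated, so the WT incidence is reused; neither planned
Fisher comparison involves that group).

## Known limitations

- Reported burst durations include the ≈ +0.5 s window-convention
  lengthening; short/long classification near the 1.5-s boundary is
  limited by spurious MAD-threshold crossings (see above), so counts of
  long events on quiet recordings are slightly anticonservative.
- Registration is integer-translation only; rotation or non-rigid tissue
  movement will degrade ROI integrity silently (the drift QC is the
  backstop).
- The synthetic generators are designed for testability of the
  measurement chains: they reproduce the statistical structure each
  stage assumes (rates, steps, gains, noise families), not biophysics.
  Recovery results validate the implementations against their stated
  conventions; they are not evidence about biological effect sizes.
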