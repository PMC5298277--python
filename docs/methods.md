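# Methods

This note documents the models and numerical choices behind `casbdr`: what
each stage assumes, which parameters matter, and what the synthetic
validation does and does not demonstrate.

## Signal model and preprocessing

A recording couples four dimensionless acoustic channels (contact
microphones on the posterior chest) with a pneumotachograph flow signal
(L/s, positive = inspiration) on one clock at 12 500 samples/s. Chest-wall
filtering confines useful wheeze energy below ~1600 Hz, so channels are
band-passed 70–2000 Hz and decimated by 4 to 3125 samples/s.

The band-pass family/order is not dictated by the recording model; the
default is a 4th-order-per-edge Butterworth applied forward–backward
(`sosfiltfilt`), chosen to be phase-preserving — component onset times feed
duration estimates downstream. Decimation uses scipy's order-8 Chebyshev-I
anti-aliasing stage, zero phase. The flow channel is low-passed at 20 Hz
(breathing dynamics live below ~5 Hz) and decimated identically.

## Respiratory phases and flow quartiles

Phases come from a zero-crossing detector on a 50 ms moving-average copy of
the flow. Runs shorter than 0.2 s or with peak |flow| under 5% of the
maneuver maximum are merged into their predecessor — breathing cannot
reverse in under 200 ms, and near-zero shoulders otherwise fragment the
crossings. All three defaults are config fields.

"Flow quartiles" divide each side's pooled peak-flow **range** (pre- and
post-bronchodilator maneuvers together) into four equal-width intervals;
they are deliberately *not* statistical quartiles of the peak-flow
distribution. Bins are half-open with the top edge closed; a zero-width
range degenerates to a flagged single-bin scheme.

## EEMD and the Hilbert spectrum

Each phase×channel slice is decomposed by ensemble empirical mode
decomposition: white noise at 0.2 of the signal SD is added, each noisy copy
is sifted into intrinsic mode functions (cubic-spline envelopes through
local extrema, mirrored end extrema, Huang's SD < 0.2 stop rule, at most 12
siftings and 10 modes), and modes are averaged index-wise over the ensemble.
The default ensemble size is 100; the validation suites use 30 as a
problem-size choice (the residual unaveraged noise scales as
`0.2/sqrt(ensemble)` — 3.7% of signal SD at 30, which the recovery suite
shows is already sufficient).

Two numerical details matter and are easy to get wrong:

* **Oversampled sifting.** Near the top of the wheeze band a 3125-Hz record
  has ~3 samples per period, and spline envelopes through sampled extrema
  systematically distort such tones (we measured a deterministic −15 Hz
  F_Mean bias at 950 Hz). Sifting therefore runs on a 2× polyphase-resampled
  copy and the averaged modes are anti-alias decimated back
  (`eemd(..., upsample=2)`), which removes the bias at ~2× cost.
* **IF smoothing is stage-specific.** The phase-derivative IF of a mode
  spikes exactly where its envelope dips (beat nulls between the dominant
  tone and weaker in-mode content). For *spectrum binning* the IF is
  smoothed with an IE²-weighted 31-sample moving average — this keeps a
  tone's ridge in adjacent bins so region growing can follow it. For
  *candidate detection* the IF keeps only an 11-sample median: weighted
  smoothing flattens the IF of narrowband noise too and would erase the
  dispersion contrast the detector relies on.

The Hilbert spectrum accumulates IE² into 5 Hz frequency bins (0 to the
1562.5 Hz Nyquist) at one-sample time resolution, per respiratory phase.
Total spectrum energy equals summed IE² exactly. 5 Hz trades pitch
resolution (< ±2.5 Hz centroid error for a clean ridge) against array size.

## Candidate segments and analysis areas

CAS lock a mode's IF onto the pitch, so IF dispersion (0.1 s sliding SD)
drops when they appear. Maximal runs with dispersion < 40 Hz lasting
≥ 0.1 s become candidate segments; each is summarized by IF/IE statistics
and labeled `cas_segment` (median dispersion < 25 Hz and duration ≥ 0.15 s)
or `normal_segment` by the default rule. Each segment yields an analysis
area: mean IF ± one SD IF (minimum half-width one bin) over the segment's
time span. Both area kinds seed ridge growing; the label only selects the
region-linking tolerances. These thresholds are this package's defaults —
the final component classifier is the safeguard against over-detection at
this stage.

## Ridge segmentation and features

Seeds are 3×3 local maxima above the 75th percentile of in-area energy,
processed in descending energy order. Regions grow with 8-connectivity
while a neighbor's energy is ≥ 10% of the running region mean and the
per-column thickness stays ≤ 4 bins; each point belongs to the first region
that claims it. Fragments link when their time gap and end-centroid
frequency jump are within (50 ms, 20 Hz) for CAS areas or (20 ms, 10 Hz)
for normal areas — continuity is expected of a genuine CAS, so CAS-area
tolerances are looser. Components with D ≤ 100 ms are discarded (strict
inequality: 100 ms exactly is rejected).

Features are computed per component over its point set, with "outside"
energy restricted to the same phase's spectrum. The intensity ratio squares
the stored H values by default (`intensity_square_h=True`); since H already
accumulates squared envelopes the convention is ambiguous, and the switch
ships both behaviors. Duration uses the time-index extremes even across
linked internal gaps.

## Component classification

Feature vectors are (D, F_Mean, I, σ_F, σ̄_F, area kind). Features are
standardized by training-subset mean/SD — not part of the original
protocol description, but necessary when mixing seconds, hertz and decibels
in one RBF kernel; the kernel scale maps to `gamma = 1/(2σ²)`.

The dataset splits 65/35 stratified per (subject × label); singleton strata
go to training. Candidate (C, σ) pairs are the local minima (4-neighborhood,
plus the global minimum) of the 10-fold stratified CV loss over the
33 × 17 grid, computed on the first partition's training subset; every
candidate is then retrained and validated on each of the (default 100)
random partitions, and the pair with the highest mean test sensitivity +
PPV wins. The shipped model is the single-partition model with the best
sensitivity + PPV at the winning pair. Running the CV tuning once rather
than per partition is this package's reading of the protocol; repeating it
per partition would only re-derive the candidate set at ~100× the cost.

## BDR quantification

`#CAS` counts pool a session's maneuvers: the denominator is the number of
phases of the matching side (one inspiratory + one expiratory phase per
cycle), the numerator the retained CAS components (label `cas`,
F_Mean ≥ 200 Hz) in those phases, so polyphony can push the percentage
past 100. Per-side changes are absolute values; ΔCAS_Glob is their maximum
and defines the dominant side. The nΔCAS_Glob denominator is the
**dominant side's** pre-bronchodilator count, consistent with the notation
chain that defines Glob through the maximizing side (configurable).
Inclusion requires #CAS_GlobPre-BD strictly above 5%; categorization is
L1 ≤ 33% < L2 ≤ 66% < L3. The spirometric comparator is the standard
FEV₁ criterion (> 12% *and* > 200 mL, both strict).

## Synthetic data

The generator emulates the recording protocol: per maneuver, sin² half-cycle
flow lobes whose per-cycle peak ramps triangularly between the configured
range (normal → deep → normal; deeper cycles 25% faster), defaults of 20
cycles per maneuver, 3 + 3 maneuvers, 4 channels. Normal respiratory sounds
are 70–250 Hz Gaussian noise amplitude-gated by |flow|. CAS are raised-cosine
enveloped sinusoids with optional linear pitch drift and a second harmonic
at −12 dB (configurable; "sinusoidal-like" rather than pure), scaled so that
component power over the injected interval sits at the requested SNR
relative to the concurrent normal-sound power — local audibility is what
determines detectability. Background transients are band-passed noise
bursts plus damped-oscillation clicks. Post-bronchodilator sessions reuse
the guided flow profiles and keep a random subset of the pre-session CAS
(`removal_fraction` removes `round(f·N)` of N). Real-recording SNR ranges
are not documented anywhere we know of; the 0–15 dB default is a choice
exposed in the config.

## Validation suites and their limits

`casbdr.validation` fixes three scaled-down study conditions (single
channel, 8 cycles, 1–2 maneuvers per session, EEMD ensemble 30; minutes of
CPU): pure-tone CAS recovery (pitch 220–980 Hz, SNR 10–15 dB) with ±10 Hz /
±20% feature tolerances, false-detection rates on CAS-free recordings with
transients, and end-to-end L3/L2/L1 categorization for removal fractions
1.0/0.5/0.2. The recovery suite uses pure tones because F_Mean is the
ridge's energy centroid: with the −12 dB harmonic the centroid sits ~6%
above the fundamental by construction (the harmonic rides in the same IMF),
so a pitch-accuracy check on harmonic waveforms would measure waveform
harmonicity, not segmentation accuracy.

What passing these suites shows: phase segmentation, EEMD/Hilbert feature
extraction, dispersion detection, ridge growing and the BDR arithmetic are
internally consistent and recover known ground truth under clean but
non-trivial conditions (flow-gated noise, multiple CAS per phase, background
transients). What it does not show: performance on recorded lung sounds —
real CAS have time-varying amplitude and waveform, heart sounds and crackles
are absent from the generator, channel cross-talk is off by default, and the
synthetic feature distributions used for the classifier exercise are
cleaner than the empirical clusters. Published cohort-level numbers (the
selected (C, σ), per-patient responses, group statistics) depend on the
original recordings and are correspondingly out of scope here.

## Degenerate inputs and tie rules

Zero flow yields no phases; constant signals yield no modes and residue =
signal; zero outside-energy flags the intensity and uses an epsilon floor;
equal-peak quartile schemes degrade to a flagged single bin; channel
selections break ties toward the lowest index; the dominant BDR side breaks
ties toward inspiration; undefined classifier ratios report NaN, never 0.
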