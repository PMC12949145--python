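# Methods

This note documents the models, algorithms and numerical choices behind
`uteromap`, in the order data flows through the pipeline.

## Recording model and geometry

A recording is an (n_samples × n_channels) matrix in mV with a sampling
rate and an `ElectrodeGrid`. The default grid stacks the two taped 8×4
arrays lengthwise along the uterine horn — 16 rows × 4 columns at 0.95 mm
pitch (≈14.25 mm of horn, consistent with the ~16 mm coverage of the
physical arrays). Row index and the +y axis increase from the ovarian to
the cervical end, so ovarian→cervical propagation has positive
y-velocity; `ovarian_row` flips the orientation for arrays applied in
reverse. Whether the two physical arrays were stacked lengthwise or side
by side is not observable from the recordings themselves, so the
geometry is fully configurable; the 16×4 convention is the default.

## Synthetic recordings

The generator emulates the statistical structure the analysis assumes;
it is not a biophysical tissue model.

**Events.** Inter-event intervals are truncated-normal draws (rejection
below 5 s, so consecutive 40 s analysis windows cannot engulf two whole
events); the first onset sits at half the first sampled interval, and
events are placed while at least 10 s of recording remains. Each event
draws, from its stage preset: a propagation pattern, a speed, a slow-wave
duration, burst presence, and a burst duration.

**Stage presets** carry the per-stage values observed in vivo:

| stage | interval (s) | speed (mm/s) | burst prevalence | ov→cerv / cerv→ov / other |
|---|---|---|---|---|
| pro-oestrus | 49.1 ± 3.7 | 0.57 ± 0.07 | 0.72 | 0.40 / 0.20 / 0.40 |
| oestrus     | 46.5 ± 5.0 | 0.82 ± 0.09 | 0.92 | 0.92 / 0.00 / 0.08 |
| metoestrus  | 60.5 ± 2.6 | 0.93 ± 0.23 | 0.82 | 0.52 / 0.08 / 0.40 |
| dioestrus   | 40.2 ± 5.6 | 0.57 ± 0.08 | 0.70 | 0.44 / 0.00 / 0.56 |

Slow-wave (19.9 ± 2.2 s) and burst (10.2 ± 3.0 s) durations do not vary
systematically between stages and share one set of defaults. The "other"
probability is split equally between three generated patterns: colliding
(plane waves from both ends meeting mid-horn), centre-origin (diverging
from the middle row) and disorganised (per-channel activation jitter,
SD 5 s, no coherent gradient).

**Waveforms.** The slow wave is one full sine cycle A·sin(2πt/D) over its
duration D — a smooth biphasic pulse whose maximum negative gradient sits
exactly at D/2, which the generator records as the channel's nominal
activation time; ground truth is therefore directly comparable to the
detector's output. The burst is a 3 Hz carrier (centre of the 1–5 Hz
analysis band) under a Tukey envelope (taper α = 0.25) centred on the
activation time. The ground-truth burst duration is the envelope's full
width at half maximum — the well-defined quantity a half-height threshold
on the envelope trend recovers; the envelope support (≈1.14 × FWHM) is
kept within 90 % of the slow-wave duration. Amplitudes (slow wave 1 mV,
burst 0.4 mV, noise SD 0.05 mV) are free choices: the emulated recordings
are reported only in normalised units, so only their ratios (SNR ≈ 20 for
the slow wave, 8 for the burst) matter.

**Artefacts.** `add_artefacts` adds, per channel: baseline drift (a
low-passed random walk below 0.05 Hz, RMS 0.5 mV), respiration (0.8 Hz)
and heart (5.5 Hz) sinusoids at 0.1 mV with random phase, and white
noise; declared dead channels (8 by default in study-scale simulations,
mirroring the typical 56-of-64 retained) are replaced by pure noise.

**What the generator does not emulate**, and hence what passing recovery
tests do not show about real data: waveform-shape variability between
events and animals, amplitude gradients along the horn, motion artefacts,
non-stationary event rates, partial or curved wavefronts, and
between-animal variance beyond event-level sampling (see Statistics).

## Preprocessing

- **Downsampling** (512 → 30 Hz when needed): polyphase FIR resampling
  with an explicit anti-alias design — passband to ~93 % of the output
  Nyquist, stopband from Nyquist, > 50 dB attenuation — so a 14 Hz
  component survives while 20 Hz is removed.
- **Detrending**: a centred 10 s moving median estimates the baseline and
  is subtracted. Window edges shrink at the record boundaries; even
  windows use the lower median, a fixed documented convention verified
  exactly against a brute-force sorted-median oracle. The median is a
  pure baseline estimator only for deflections shorter than about half
  the window; it partially attenuates and reshapes our smooth 20 s slow
  waves (as it must any method's), which is why duration *measurement* is
  validated on undetrended event windows while detection and interval
  recovery are validated through the full detrended pipeline. Re-applying
  the filter changes the RMS by < 1 % in its design regime (impulsive
  deflections on drift).
- **Channel screening** replaces the visual judgement used with real
  recordings by two automated rules: a channel is rejected when its
  high-band (> 5 Hz) RMS exceeds 3× the cross-channel median (noisy
  electrodes), or when its spectral event content is absent — for a
  poor-contact electrode recording only broadband noise, the slow-band
  (< 0.5 Hz) RMS equals the flat-spectrum prediction from its high-band
  RMS (ratio ≈ 1), while live channels carry 15–20× more; the threshold
  is 3.0. Both thresholds are config-exposed. A correlation-against-
  median-template rule was tried first and abandoned: biphasic detrended
  residuals cancel in the cross-channel median under propagation delays,
  and disorganised events admit no single alignment lag, so live and dead
  channels overlap in correlation. If screening rejects every channel the
  pipeline stops with a diagnostic.

## Event detection

The channel signal is low-passed at 0.5 Hz and differentiated; local
gradient minima below −θ become activation marks, where θ is the larger
of an amplitude floor (min_amp/4 mV/s, the peak slope of a 0.2 mV
deflection over ~25 s) and k = 4 robust SDs of the gradient noise. The
noise scale is the lower quartile of absolute gradient deviations scaled
to a Gaussian SD — a plain MAD would absorb event slopes when events
occupy half the trace, as they do at dioestrus rates. Minima closer than
10 s merge keeping the steeper; marks within 2 s of the record edges are
discarded (zero-phase filter settling).

Marks cluster into events by temporal gaps: sorted marks split wherever
consecutive marks are > 10 s apart (channels within one event activate
densely; events are separated by quiescence). Groups wider than 45 s —
longer than any physiological traversal of the array (~40 s at the
slowest generated speeds) plus marking error — are split at their largest
internal gap. One mark per channel (the earlier wins); groups on < 3
channels are discarded (velocity estimation needs ≥ 2 spatial
neighbours). A 40 s half-open window [t−20 s, t+20 s), 1200 samples at
30 Hz, is extracted per mark, truncated and flagged at record edges.

On artefact-free recordings the detector recovers event counts exactly in
≥ 95 % of simulations and activation times to well under one sample
period. Through the full artefact-laden pipeline, the median-detrend
residual has two descents of similar steepness, giving per-channel
marking errors of ± 3–4 s; interval and rate metrics are insensitive to
this (the event reference time is the median mark), and the acceptance
studies quantify the net effect.

## Component durations

Each window is split by frequency with zero-phase 4th-order Butterworth
filters (1–5 Hz band-pass for the burst; 0.5 Hz low-pass for the slow
wave); zero-phase filtering preserves activation timing.

**SSA trends.** Both measurements operate on a singular-spectrum-analysis
trend: embed the series in an L×K trajectory matrix, keep the leading
components of its SVD, reconstruct by diagonal averaging, min–max
normalise (a constant series returns zeros). The burst envelope trend
uses L = 3 s of samples and 1 component. The slow-wave trend uses
L = 2 s and 2 components with plateau tolerance ε = 2.5×10⁻³: these
three values were calibrated against closed-form templates with known
stationary points — with a 10 s window the diagonal-averaging leakage
pushes the zero-gradient landmarks ~5 s outward (a 20 s pulse reads as
~29 s), while the calibrated settings read it as 20.0 ± 0.1 s and carry
a bias of +0.1 ± 0.15 s on noisy generator events. All three are
config-exposed.

**Burst.** Rectify the band-passed window, take the SSA trend. If the
raw trend's range is below 1.0× its median level the band carries no
significant or prolonged magnitude variation and the window has no burst
(this guard is what keeps noise-only windows, whose min–max normalisation
would otherwise amplify fluctuations into apparent structure, from
producing false positives; measured false-positive and false-negative
rates on generator windows are both ≈ 0). Otherwise normalise, binarise
at the Otsu threshold (256-bin between-class-variance maximisation,
verified exactly against an exhaustive-search oracle, ties toward the
lowest bin), find the trend peak nearest the activation time (ties to the
earlier peak): if it lies in a supra-threshold segment, the burst
duration is that segment's length; otherwise the window has no burst.

**Slow wave.** Take the SSA trend of the low-passed window and the trend
peak nearest activation. Zero-gradient instants are sign changes of the
first difference (local extrema) plus plateaus where |Δtrend| < ε for
≥ 3 consecutive samples (flat shoulders a pure sign-change rule misses);
a pre-peak plateau contributes its end, a post-peak plateau its start.
The duration runs from the nearest zero-gradient instant before the peak
(initiation) to the second one after it (the first is the event trough,
the second the return to baseline). Missing landmarks yield an absent
measurement with a diagnostic, never an exception. Both measurements are
invariant to window amplitude scaling.

## Velocity fields and direction

Activation times are arranged on the grid as T(row, col). The gradient at
each marked electrode is the slope of a least-squares plane fitted to the
available entries of its 3×3 neighbourhood (≥ 3 points spanning both
axes required). This is the package's "smoothed finite difference": for
plane waves it is exact on every channel including grid edges and around
missing electrodes — a neighbour-mean smoothing pass followed by central
differences, the more common formulation, biases edge rows of a linear
surface by up to 2× and was rejected for that reason. Channels with
|∇T| < 10⁻³ s/mm (near-synchronous activation, implying unbounded speed)
get no estimate; an event whose gradients are all degenerate raises an
error. Event speed is the arithmetic mean of per-channel speeds 1/|∇T|.

Direction follows the column-mean rule: all four column-mean
y-velocities positive → ovarian→cervical, all negative →
cervical→ovarian, otherwise *other*; additionally *other* when ≥ 30 % of
all per-channel y-components oppose the sign of the mean y-component.
The 30 % criterion is applied globally across the event by default; a
per-column variant sits behind `per_column_direction` since the original
column convention is ambiguous. Isochronal maps quantise activation
times into 2 s bands from the earliest activation, red→blue, masking
unmarked channels.

## Statistics

The animal is the statistical unit. Per recording: interval = mean of
successive differences of event reference times (rate = 60/interval cpm,
converted to Hz by /60); speed = mean of per-event mean speeds;
durations = means over channel-event measurements; burst presence = % of
analysed windows flagged burst-present (an event-level denominator is a
config alternative); direction counts per class. Stages are compared
with one-way ANOVA and Tukey-HSD-adjusted pairwise tests (unadjusted and
Bonferroni variants available), Shapiro–Wilk on pooled within-stage
residuals, all cross-checked against independent reference
implementations to 10⁻⁶. Zero-variance input produces a diagnostic
report rather than an exception.

The replicated study design (5/4/5/5 animals, one 300 s recording each)
draws per-animal metrics at the event level, so between-animal spread is
purely sampling noise (SD/√n_events) — tighter than real between-animal
variability, which has physiological components the generator does not
model. The qualitative outcome pattern (metoestrus–dioestrus interval
difference significant; slow-wave duration differences not) is therefore
reproduced with more power than the original design would have.

## Problem sizes and determinism

Acceptance studies use five 300 s recordings per stage for intervals and
rates (the study's own per-stage design), 200 events or windows for
duration/direction/prevalence recovery, 50 plane waves per speed target
and 100 replicates of the cohort design — sizes at which each
recovered mean's sampling error is a few percent of its target. Every
random draw descends deterministically from a single seed; identical
seeds give bit-identical recordings and byte-identical output files.
Interval estimates from fixed-length recordings carry a small
length-bias (short intervals are slightly over-represented in a 300 s
window), visible as ~1 s at the dioestrus interval CV and negligible at
metoestrus.

## Known limitations

- The moving-median detrend attenuates smooth deflections comparable to
  its window; in-pipeline duration metrics on the generator's sinusoidal
  templates under-read by several seconds, so duration recovery is
  validated on undetrended windows (real slow waves, being more
  impulsive, are less affected — but this is an assumption, not a tested
  property).
- Per-channel activation marking on detrended smooth templates is
  bimodal (± ~3 s); velocity recovery at study scale is therefore
  validated with the prescribed 0.2 s timing jitter rather than through
  the detrend path.
- EDF ingestion is not implemented; the native format is TSV + JSON.
- The generator's plane-wave patterns cannot produce curved or partial
  wavefronts, so the direction classifier's behaviour on such events is
  untested.
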