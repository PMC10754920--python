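# Methods

This note documents the models, conventions and numerical choices behind
`fetal-qeeg`: what is simulated, how the quantitative EEG (qEEG) features are
defined, how phase summaries and statistics are computed, and where the design
was genuinely open and a choice had to be made.

## The experimental model being emulated

The pipeline targets the standard near-term fetal-sheep preparation for
progressive intrapartum hypoxia: after a one-hour stability (baseline) period,
total umbilical-cord occlusions of one minute are repeated at increasing
frequency over three one-hour phases — every 5 min (phase A, mild), every
3 min (phase B, moderate), every 2 min (phase C, severe) — with a 5-min
occlusion-free pause every 20 min, and the run is aborted once an arterial
blood sample shows pH < 6.90. Fetal EEG is recorded from four subperiosteal
electrodes (left/right frontal, left/right parietal) at 256 Hz, band-limited
0.5–70 Hz; heart rate (HR), mean blood pressure (MBP) and arterial blood
gases complete the picture.

The published protocol does not state how occlusion cycles and pauses
interleave within the hour. We divide each phase into 20-min blocks — 15 min
of occlusion cycles followed by one 5-min pause — and start a cycle only if
the *entire* cycle (occlusion plus recovery gap) fits in the 15-min sub-block.
This satisfies both stated rules and yields 9/15/21 occlusions per phase for
A/B/C; the remaining 60 s of each phase-C sub-block is inter-occlusion time.
The layout is a convention of this package and every duration is a named
configuration key, so alternative layouts are expressible.

## Synthetic data generator

No recording of this preparation is publicly deposited, so the generator is
the canonical input source. It is deliberately phenomenological: it
reproduces the statistical structure the analysis stage assumes, not any
biophysical mechanism (no ODE cardiovascular model, no ECG waveform, no
heart-rate-variability structure).

**EEG.** Background activity is coloured noise with a prescribed band
spectrum, synthesised in the frequency domain: white noise is Fourier
transformed, multiplied by a piecewise-constant gain equal to the square root
of each band's power density, inverse transformed and normalised to unit RMS.
This is exactly a sum of ideally band-passed noise components; the FFT route
was chosen because it is fast enough to simulate the thousands of subjects the
statistical-calibration studies require and because it makes the spectral
edge analytically controllable. The default stability spectrum (0.5–30 Hz,
most power below 10 Hz) puts the stability-phase 95% spectral edge near
10–11 Hz, inside the range reported for this preparation.

Each hemisphere pair is built as a shared *common* component plus/minus half
a *difference* component, so the bipolar derivation computed downstream
equals the difference component exactly and its amplitude (default 15 µV RMS)
is directly interpretable. Phase severity enters through two per-phase
multipliers: a **slowing factor** applied to the band edges (default
1/0.95/0.85/0.75 for S/A/B/C) and an **amplitude scale** (same default
ladder). During each occlusion, the neural signal is multiplied — after a
configurable latency (default 5 s, 2 s in the scaled presets) — by the
phase's **suppression depth**, the fraction of amplitude retained (default
0.8/0.5/0.1 for A/B/C), with 1-s raised-cosine ramps; occlusion onset and
release may add a damped ~1-Hz high-amplitude transient wave (default 40 µV,
probability 0.5 per boundary). A 0.3-µV-RMS additive noise floor represents
the acquisition chain, and every channel is finally band-passed 0.5–70 Hz
(zero-phase Butterworth), which keeps supra-70-Hz power below 1% of total.

**Haemodynamics.** HR (default 186 bpm) drops to a phase-specific bradycardia
level during each occlusion (85/80/79 bpm) with short ramps; MBP (default
48 mmHg) rises toward a phase-specific hypertensive level during pauses
(+10/+14/+16 mmHg, half of it between occlusions) and is pulled to a
phase-specific per-occlusion level (56/54/37 mmHg — collapse in the severe
phase). Gaussian noise (3 bpm, 2 mmHg) is added at 1 Hz.

**Blood gases.** pH, pCO2, pO2 and lactate follow per-phase targets anchored
at the sampling times — the stability midpoint and the midpoint of the last
pause of each phase, the published sampling scheme. Defaults track the
reported cohort medians (pH 7.39 → 7.28 → 7.10 → 6.98; lactate 2.3 → 15.9;
pO2 stable). The stop rule truncates the schedule at the first *sample* with
pH < 6.90; because samples exist only at those anchor times, truncation can
only occur there, and a subject whose pH crosses at phase B's last pause
loses phase C entirely — reproducing the n = 8 phase-C columns typical of
this preparation. Subjects are simulated physiology-first so that a stopped
subject's EEG ends at the truncation point.

**Cohorts.** Per-subject jitter is drawn from named substreams of one master
seed (SHA-256-keyed `SeedSequence` spawn keys), so adding a channel never
perturbs another channel's stream and every artifact is bit-reproducible
given (n, seed). A latent standard-normal *vulnerability* factor couples a
subject's suppression depth, background slowing, occlusion bradycardia,
occlusion hypotension and acidosis — the couplings the Spearman stage is
meant to recover. Setting `jitter=0` collapses the cohort to identical
parameters (distinct noise streams only).

**What the generator does not emulate.** Sleep-state cycling and EEG
lability, movement artefacts from the ewe, electrode failures, the
EEG–cardiac synchronisation patterns described in related work, and any
vendor-specific behaviour of commercial qEEG software (in particular the
"30 Hz when isoelectric" artefact of some spectral-edge implementations —
our SEF is explicitly undefined there, see below). Passing tests therefore
demonstrate the pipeline's correctness and its ability to recover planted
structure, not performance on real recordings.

## qEEG features

All three features are computed on consecutive, non-overlapping 2-s intervals
aligned to the start of the recording (the interval grid is a convention; the
source material does not state overlap), on the two bipolar derivations
(left−right frontal, left−right parietal), then averaged across derivations.
Averaging precedes the window medians.

* **Amplitude envelope (CFM/aEEG stand-in).** The commercial envelope
  algorithm is unpublished. Ours is documented and testable: zero-phase
  2–20 Hz Butterworth band-pass (order 4, applied forward-backward, ≥ 40 dB
  one octave outside the band), absolute value, sliding 125-ms maximum,
  0.5-s moving average. For signals ≥ 4 Hz of constant amplitude the envelope
  converges to the peak amplitude; below ~4 Hz the 125-ms maximum window
  underestimates peaks, a known property of short-window envelopes.
* **min AI** — minimum of that envelope over the interval (µV).
* **BSR** — suppression is a maximal run with envelope < 10 µV (strict)
  lasting > 500 ms (strict). Runs are detected on the continuous timeline and
  intersected with intervals, so suppressions straddling interval edges are
  not lost. The amplitude criterion is evaluated on the envelope, not raw
  samples — a raw oscillation crosses any threshold twice per cycle, which
  would make the verbatim rule degenerate. BSR is the percentage of the
  interval covered. Envelope smoothing erodes run edges by up to ~0.3 s;
  planted suppression fractions are recovered within 5 percentage points for
  suppressions of a few seconds or longer, the regime occlusion suppressions
  actually occupy.
* **SEF** — 95% spectral edge from a Hann-tapered periodogram of the 2-s
  interval (0.5-Hz resolution at 256 Hz), cumulative power over 0.5–70 Hz.
  An interval whose in-band power is below a floor (default: the total power
  of a 1-µV-RMS signal) returns an *undefined* marker (NaN), never a numeric
  edge — deliberately unlike the commercial behaviour that reports ~30 Hz on
  isoelectric input. Undefined values are excluded from medians and from the
  channel average (undefined only if both derivations are). Note that the
  Hann taper spreads a pure spectral line over three bins, so the 95% edge of
  a noiseless sinusoid reads one 0.5-Hz bin above the line frequency.

## Windows, summaries, tables

Per subject, features are summarised in protocol-defined windows: the
stability hour, each whole phase (occlusion intervals included — the closer
spacing of severe occlusions legitimately raises whole-phase BSR), the last
*completed* occlusion (1 min) and last *completed* pause (5 min) of each
phase. Under truncation, "last" means last completed before the truncation
point; partial events are discarded, and a phase with no completed event of
a kind simply has no such window.

Summaries are median (Q1; Q3) with linear interpolation between order
statistics (R type 7, numpy's default) — the convention matters at n = 9 and
is centralised in one function. Cohort cells are the across-subject median
(Q1; Q3) of the per-subject medians ("median of medians"), with the number of
contributing subjects recorded per cell.

## Statistics

* **Friedman** across S/A/B/C (A/B/C only for per-occlusion features), on
  complete-case rows, mid-rank ties, tie-corrected rank-ANOVA statistic,
  chi-square approximation with k−1 degrees of freedom. A fully tied grid is
  reported as statistic 0, p = 1 (degenerate) rather than 0/0.
* **Wilcoxon signed-rank** post-hoc for all phase pairs, run only when the
  Friedman p ≤ α (0.05) in pipeline mode: zero differences dropped,
  mid-ranks, exact two-sided p by full 2^n sign-pattern enumeration for
  n ≤ 15, tie-corrected normal approximation with continuity correction
  above (the two agree within 0.02 at the cutoff). No multiple-testing
  correction by default, matching the original analysis; Holm adjustment is
  available behind a flag.
* **Spearman** correlations between the six qEEG markers and eight
  physiological markers, pooled over subject × occlusion-phase observations
  (27 for an untruncated cohort of 9 — consistent with the pair counts
  implied by the published correlation table). rho is the product-moment
  correlation of mid-ranks; p is exact (all n! permutations) for n ≤ 8, the
  t approximation above. Cells with under 3 complete pairs are marked
  missing; zero rank variance is an undefined-correlation flag.

Under summary-level null cohorts (no phase effect) the Friedman stage
rejects at ≈ 4% at the 5% level (n = 9, k = 4); under the default severity
ladder its power for the whole-phase spectral edge is ≈ 100%.

## Problem sizes and scaled protocols

The full-scale protocol (3600-s phases, ~118 MB of EEG per subject) is the
default for the command-line pipeline. For repeated-simulation studies the
package provides time-scaled presets that preserve the block structure and
all rates/amplitudes: `short_protocol()` (720-s phases, 12-s occlusions,
same 9/15/21 occlusion counts) and `tiny_protocol()` (240-s phases, 2/4/6
occlusions per phase). The test suite and the acceptance script run the
nine-subject ladder cohort on the short protocol and the 200-cohort Friedman
power study on the tiny protocol, with suppression latency shortened to 2 s
so that 12-s occlusions still develop suppression; these sizes are this
package's choice of desk-scale problem and are stated here so results are
read at the right scale.

## Numerical choices and edge cases

* Zero-phase filtering throughout (no group delay; attenuation doubles).
* EDF output uses 16-bit samples over ±1000 µV (≈ 0.03 µV steps), 1-s
  records, fixed header date (simulated data; keeps files byte-reproducible).
  Reading goes through MNE; the in-house writer exists because no EDF writer
  is otherwise available in the dependency set, and MNE serves as the
  independent reader in round-trip tests.
* Interval membership is half-open [start, end); an event ending exactly at
  the truncation point counts as incomplete (strict inequality).
* Suppression gating guards the degenerate case where latency exceeds the
  occlusion: the occlusion then simply never suppresses.
* All random draws go through named substreams; no global RNG state.

## Known limitations

* The envelope and SEF conventions are documented stand-ins for unpublished
  vendor algorithms; absolute minAI/BSR levels are therefore not comparable
  to vendor numbers (directions and orderings are).
* The generator's couplings are linear-in-latent-factor; real inter-subject
  variability is richer, so correlation magnitudes are not calibrated —
  only their signs are meaningful.
* Truncation can only occur at blood-sampling times, a faithful consequence
  of the sampling scheme; a continuously monitored pH would stop earlier.
* With four conditions and n = 9, the Friedman chi-square approximation is
  slightly conservative; exact Friedman p-values are not implemented.
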