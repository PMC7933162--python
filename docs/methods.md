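# Methods

`hgmod` implements the statistical chain used to measure event-related
high-gamma (65–95 Hz) amplitude modulations in intracranial EEG during a
phrase-by-phrase auditory sentence-comprehension task, together with a
synthetic cohort generator that makes every stage verifiable against
known ground truth.

## Task and data model

Each trial plays a three-phrase spoken question in one of two phrase
orders — beginning with a concrete phrase (`concrete_first`) or with a
wh-interrogative (`wh_first`) — and the listener answers overtly.  A
trial is fully described by eight event times (sentence onset = 1st
phrase onset, the six phrase boundaries, response onset), its sentence
type, wh-word and correctness.  Recordings are electrode × time voltage
matrices at 1,000 Hz; electrodes carry a hemisphere, one of eight
region-of-interest (ROI) labels per hemisphere (or `others`), and a
status flag — only `analyzable` sites (outside seizure-onset, spiking
and lesional zones) enter any statistic.

## Synthetic cohort

The generator emulates the study conditions the analysis assumes:

* **Stimulus timing.** Phrase and gap durations are truncated normal
  (mean ± 3 SD, positive), with defaults equal to the stimulus set's
  acoustic statistics: concrete-first 546±80 / 168±57 / 538±83 / 155±49
  / 410±50 ms; wh-first 436±56 / 181±62 / 487±100 / 157±60 / 554±75 ms.
  Both orders sum to ≈1.8 s.
* **Session structure.** 96 trials per patient (48 per type), presented
  pseudorandomly with no two consecutive trials sharing a wh-word and
  each wh-word used equally often within each type.  The inter-trial
  interval is uniform 3–5 s from response onset (the task description
  leaves it open), which also guarantees the 400-ms baseline window is
  free of evoked effects.  Response latency is log-normal with median
  1.5 s; correctness is i.i.d. Bernoulli(0.979).
* **Electrode layout.** Defaults reproduce a 23-patient reference
  layout: 626 left / 493 right analyzable sites distributed round-robin
  over the patients sampling each hemisphere (14 left, 12 right).
  Patient covariates (age, epilepsy-onset age, sex, drug count, FIQ,
  congenital lesion) are drawn from distributions matching the cohort's
  published medians and SDs.
* **Signals.** Each electrode sums (i) 1/f-shaped Gaussian background
  (PSD ∝ f^−1, 15 µV RMS), (ii) mains interference (60 Hz, 10 µV,
  random phase; configurable to 50 Hz), and (iii) a 65–95 Hz
  band-limited Gaussian carrier (15 µV RMS) whose envelope is
  `hg_background_level × (1 + m(t))`.  `m(t)` is the sum of the
  requested event-locked effects: ramped boxcars per trial, per
  sentence type.  The carrier is amplitude- (not phase-) modulated so
  the stored `m(t)` is an exact oracle for the quantity the pipeline
  estimates.  Overlapping effects on one electrode are an error unless
  declared additive.

What the generator does **not** emulate: evoked low-frequency
potentials, spectral tilt changes, epileptiform transients, electrode
drift/artifacts beyond a status flag, or any dependence of behaviour on
sentence type.  Passing tests therefore certify the statistical chain,
not robustness to those real-data features.

A note on amplitudes: with these defaults the 1/f background leaks
≈14 µV² into the 65–95 Hz band against the carrier's 225 µV², so an
injected +10% envelope change is measured as ≈+9.5% band-amplitude
change.  This dilution is a property of the forward model (any real
recording has it too) and stays well inside the ±2-point recovery band.

## Time–frequency decomposition

Complex demodulation on a 10-ms / 5-Hz grid: for each frequency center
f, multiply the signal by `exp(-2πi f t)`, low-pass the product with a
zero-phase linear-phase FIR (−6 dB at 2.5 Hz — half the bin spacing;
default one second of taps), and report `2·|baseband|`, so a unit
cosine at f reads amplitude 1.  The demodulate–filter–decimate chain is
evaluated in the frequency domain with one shared FFT per recording;
this is algebraically identical to per-center zero-phase FIR filtering
(frequency centers are snapped to the FFT grid, a sub-mHz offset that
only rotates phase).  The first/last half filter lengths are NaN, never
extrapolated.  High-gamma amplitude is the unweighted mean of the seven
bin centers 65, 70, …, 95 Hz (closed interval; configurable).  Mains
components at 50/60 Hz lie outside every member bin's ±2.5 Hz passband
and perturb the band amplitude by <0.1%.

## Percent change, alignment, aggregation

Percent change is `100·(A − B)/B` with the baseline B computed **per
electrode** as the mean band amplitude over all correct trials'
[−600, −200) ms pre-stimulus windows (half-open, bin centers).  A
per-trial baseline is available as an option but is high-variance with
400-ms windows.  Traces are re-anchored to any trial event by
nearest-bin re-indexing (ties toward −∞); bins a trial does not cover
are missing (NaN), not zero.  ROI time courses are mean ± SE across
electrode-level trial-averaged traces pooled over patients — the
electrode, not the trial, is the statistical unit.  Composite ROIs
(posterior prefrontal = posterior MFG ∪ posterior IFG; anterior
prefrontal = anterior MFG ∪ orbitofrontal) are derived on request.

## Pointwise inference

Per-bin significance of the across-electrode mean uses a sign-flip
permutation test (default n = 1000): one random sign per electrode per
permutation, applied to the electrode's whole trace, preserving
temporal correlation; two-sided p with the add-one convention
`(1 + #{|mean*| ≥ |mean|})/(n+1)`, so p = 0 is unattainable.
Benjamini–Hochberg FDR correction is applied across the time window
(451 bins for a 4,500-ms epoch); the family is one ROI × sentence type
× anchor.  Surviving bins are grouped into maximal same-sign runs and
kept only if their extent — counted as n_bins × 10 ms, so six bins =
60 ms — reaches the minimum duration (default 60 ms).

The rate of rise is the OLS slope of the mean trace in a sliding
600-ms window, in %/s, with a percentile bootstrap CI over electrodes;
the reported argmax is the earliest center on ties.  Because the 2.5-Hz
low-pass sets the temporal resolution of the trace, any slope landmark
should be compared against a reference smoothed the same way; the
validation suite pushes the generator's envelope through the identical
estimator for exactly this reason.

## Window contrasts and the mixed model

Eleven 100-ms windows tied to phrase onsets/offsets (for phrase N:
[−100,0) and [0,100) around onset and offset, omitting the one window
that falls in the pre-stimulus period) are compared between sentence
types with a studentized bootstrap (bootstrap-t): electrodes resampled
within groups, Welch standard error as the pivot's scale, two-sided p
from the |t*| null, percentile-t 95% CI, default 2,000 resamples,
BH-FDR across the windows × ROIs family.  The window placement is fully
configurable since labels beyond the default convention are
underdetermined.

The mixed model re-tests each contrast on electrode-level window means
(two rows per electrode): fixed effects sentence type, age,
epilepsy-onset age, sex, antiepileptic-drug count, FIQ, congenital
lesion; random intercept per patient; REML estimation (statsmodels
MixedLM).  Inference is Wald-t with patient-count-based degrees of
freedom (n_patients − n_fixed) — deliberately conservative for
patient-level covariates.  Rank-deficient fixed-effect designs raise an
error; near-zero random-intercept variance is flagged as singular but
reported.  `detectable_effect_size(n, α, β)` solves the noncentral-t
power equation for the smallest standardized one-sample effect.

## Behaviour

Response time = response onset − 3rd phrase offset, correct trials
only.  Per-patient medians per sentence type are compared with the
Wilcoxon signed-rank test: zero differences dropped before ranking,
exact null distribution up to 25 non-zero pairs (and no ties), normal
approximation with continuity correction above.

## Validation experiments and problem sizes

`hgmod.validate` packages the simulation experiments the test suite and
the reproduction script run:

* Null calibration: 200 datasets each for the permutation test (25
  electrodes) and bootstrap contrast (20 per group); rejection at the
  two-sided 5% level should sit inside the binomial 95% band.
* Bootstrap-t CI coverage: 300–500 Gaussian datasets, n = 20 per group.
* Full-chain recovery: 100 synthetic sessions, each 30 electrodes and
  24 trials per sentence type, with a +10%, 300-ms augmentation (50-ms
  ramps) 150 ms after the 1st phrase offset.  Reported: the fraction of
  sessions with a ≥60-ms significant augmentation epoch overlapping the
  true interval, and the median peak error and median slope-argmax
  error against the smoothed ground-truth envelope.  Medians are used
  because single-session landmarks are noise-limited.
* Mixed-model recovery: 200 replicates of 12 patients × 5 electrodes,
  +5% effect, 3% intercept SD, 5% residual SD; CI coverage of the true
  effect.

These sizes were chosen to give tight Monte-Carlo error while keeping
the whole suite comfortably runnable on one CPU; every routine accepts
larger sizes.

## Numerical choices and edge cases

* All randomness flows through `numpy.random.Generator`; every public
  stochastic function takes a seed or generator, and identical seeds
  give bit-identical outputs.
* Time stamps are bin centers in integer-friendly ms; anchor alignment
  rounds to the nearest bin with ties toward −∞.
* A non-positive electrode baseline raises an error naming the
  electrode; an all-incorrect patient × sentence-type cell warns and is
  dropped downstream; a single-electrode ROI reports SE = 0 with an
  explicit unreliability warning; a single electrode is rejected by the
  permutation test (no exchangeability).
* EDF input is read through MNE when installed (optional extra);
  recordings are otherwise stored in an HDF5 container with channel
  names, µV units and sampling rate, which round-trips exactly.

## Known limitations

* The synthetic carrier is strictly band-limited and
  amplitude-modulated; real high-gamma activity is broadband and mixed
  with evoked potentials, so absolute amplitudes are not comparable to
  patient data — only the statistical behaviour of the chain is.
* The permutation and bootstrap tests treat electrodes as exchangeable
  and independent; spatial correlation between neighbouring contacts is
  not modelled (the mixed model's patient intercept absorbs only the
  patient-level share).
* The eleven-window placement follows a documented convention; other
  placements are configurable but not exhaustively tested.
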