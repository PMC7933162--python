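# hgmod — event-related high-gamma modulation analysis for iEEG

`hgmod` measures when and where cortical activity rises or falls while a
listener comprehends a spoken three-phrase question, using the
event-related high-gamma (65–95 Hz) amplitude of intracranial EEG as the
readout.  It is written for electrophysiologists and statisticians who
want the complete analysis chain of such experiments — from raw
multi-electrode voltage to region-of-interest (ROI) statistics — as
tested, seedable library code, together with a synthetic cohort
generator that makes every stage verifiable against known ground truth
(patient recordings of this kind are rarely shareable).

## The analysis

For electrode *e* and time bin *t* (10-ms grid), complex demodulation
gives the band amplitude $A_e(t)$ as the mean over the seven 5-Hz bins
in 65–95 Hz, and the quantity analysed is the baseline-normalized
percent change

$$\Delta_e(t) = 100\,\frac{A_e(t) - B_e}{B_e},\qquad
B_e = \text{mean } A_e \text{ over } [-600, -200)\text{ ms pre-stimulus, correct trials.}$$

Traces are aligned to phrase onsets/offsets, trial-averaged per
electrode, and pooled across patients into ROI mean ± SE time courses.
Inference proceeds in three tiers:

1. **Pointwise:** a sign-flip permutation test (n = 1000, electrodes
   exchangeable, whole-trace flips) of mean = 0 per bin, two-sided 5%
   level, Benjamini–Hochberg FDR across the time window (451 bins per
   4,500 ms), keeping only significant runs lasting ≥ 60 ms; plus the
   OLS slope of the mean trace in a sliding 600-ms window (%/s) with a
   bootstrap CI, to time the steepest rise.
2. **Between sentence types:** studentized bootstrap (bootstrap-t)
   contrasts of per-electrode means in eleven 100-ms windows tied to
   phrase boundaries, FDR across windows × ROIs.
3. **Covariate-adjusted:** a linear mixed model on electrode-level
   window means — fixed effects for sentence type, age, epilepsy-onset
   age, sex, drug count, FIQ and congenital lesion, random intercept
   per patient (REML) — confirming that sentence-type differences
   survive patient-profile adjustment.

The synthetic cohort reproduces the study conditions (two phrase orders
with realistic phrase/gap timing, 48 counterbalanced trials per type
with a no-repeated-wh-word constraint, a 23-patient / 1,119-electrode
reference layout, 1/f background + mains noise + band-limited
high-gamma carrier with exactly known envelope modulation), so injected
effects can be recovered end to end.  See `docs/methods.md` for the
full model description.

## Worked example

`examples/03_detect_modulations.py` synthesizes one patient (30
electrodes in the left posterior middle-frontal gyrus, 48 trials) with a
+10% high-gamma augmentation 150–450 ms after the 1st phrase offset,
then runs the full chain:

```
peak percent change in the true interval: 8.6% (injected +10%)
significant augmentation: 110 to 600 ms (500 ms)
slope of rise maximal at 110 ms (18%/s)
```

The recovered peak sits within two points of the injected effect (the
1/f background dilutes a +10% envelope change to ≈+9.5% measured band
amplitude), the detected epoch overlaps the true 150–450 ms interval,
and the slope landmark falls on the smoothed rising edge.  The other
examples cover cohort generation, the demodulation grid, window
contrasts, the mixed model and behavioural summaries; each prints what
it computes and what the numbers mean.

A thin CLI runs the same stages file-to-file from a YAML config
(`hgmod simulate|tf|analyze|compare|lmm|behavior|report -c
examples/config.yaml`), writing tidy TSV tables and per-ROI plots.

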