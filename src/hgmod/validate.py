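"""Simulation-based validation experiments for the analysis chain.

These routines quantify, on data with known ground truth, the operating
characteristics the pipeline relies on: type-I error calibration of the
permutation and bootstrap tests, recovery of an injected high-gamma
augmentation (detection, peak amplitude, slope timing) through the full
signal chain, bootstrap-t confidence-interval coverage, and mixed-model
coverage of a simulated sentence-type effect.  They are used by the test
suite and by the reproduction script; problem sizes are arguments, so the
same experiment can be run larger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from hgmod.cohort import Electrode, _as_rng, generate_patient_schedules
from hgmod.epoching import align, filter_trials, percent_change, roi_aggregate
from hgmod.pointwise import detect_epochs, permutation_mean_test, slope_estimate
from hgmod.simulate import EffectSpec, NoiseSpec, synthesize_recording
from hgmod.timefreq import BandAmplitude, high_gamma_amplitude
from hgmod.windows import fit_window_lmm, studentized_bootstrap_contrast


def permutation_calibration(n_datasets: int = 200, n_electrodes: int = 25,
                            n_perm: int = 1000, alpha: float = 0.05,
                            rng_seed=None) -> float:
    """Type-I error of the sign-flip permutation test under a symmetric
    null (i.i.d. standard normal electrode values, one bin)."""
    rng = _as_rng(rng_seed)
    rejections = 0
    for _ in range(n_datasets):
        x = rng.standard_normal((n_electrodes, 1))
        p = permutation_mean_test(x, n_perm, rng)[0]
        rejections += p < alpha
    return rejections / n_datasets


def bootstrap_calibration(n_datasets: int = 200, n_per_group: int = 20,
                          n_boot: int = 1000, alpha: float = 0.05,
                          rng_seed=None) -> float:
    """Type-I error of the studentized bootstrap contrast under equal
    Gaussian groups."""
    rng = _as_rng(rng_seed)
    rejections = 0
    for _ in range(n_datasets):
        a = rng.standard_normal(n_per_group)
        b = rng.standard_normal(n_per_group)
        r = studentized_bootstrap_contrast(a, b, n_boot, rng)
        rejections += r["p"] < alpha
    return rejections / n_datasets


def bootstrap_ci_coverage(n_datasets: int = 500, n_per_group: int = 20,
                          delta: float = 1.0, n_boot: int = 1000,
                          rng_seed=None) -> float:
    """Coverage of the 95% percentile-t CI for a true group difference."""
    rng = _as_rng(rng_seed)
    covered = 0
    for _ in range(n_datasets):
        a = rng.standard_normal(n_per_group) + delta
        b = rng.standard_normal(n_per_group)
        lo, hi = studentized_bootstrap_contrast(a, b, n_boot, rng)["ci"]
        covered += lo <= delta <= hi
    return covered / n_datasets


@dataclass
class RecoveryResult:
    detected: bool          # >= min-duration epoch overlapping the true interval
    peak_error: float       # max mean %-change in the interval minus injected %
    argmax_error_ms: float  # slope argmax vs noiseless-oracle argmax
    peak_pct: float
    n_epochs: int


def _oracle_timecourse(truth, schedules, electrodes, retained_mask,
                       anchor, window, time_step_ms=10.0,
                       lowpass_hz=2.5):
    """ROI time course of the noiseless ground-truth envelope, pushed
    through the same percent-change / align / aggregate machinery.

    The envelope is smoothed with the demodulation low-pass FIR so the
    oracle carries the same temporal resolution as the measurement.
    """
    from scipy.signal import fftconvolve, firwin
    numtaps = int(truth.sfreq) + 1
    h = firwin(numtaps, lowpass_hz, fs=truth.sfreq)
    env_full = fftconvolve(1.0 + truth.modulation.astype(float),
                           h[None, :], mode="same", axes=1)
    n_bins = int(truth.modulation.shape[1] * 1000 / truth.sfreq // time_step_ms)
    times = np.arange(n_bins) * time_step_ms
    idx = np.clip(np.round(times * truth.sfreq / 1000.0).astype(int),
                  0, env_full.shape[1] - 1)
    env = env_full[:, idx]
    band = BandAmplitude(amplitude=env, band=(65.0, 95.0),
                         member_freqs=np.arange(65, 100, 5.0), times=times,
                         sfreq=truth.sfreq, channels=list(truth.channels))
    tr = percent_change(band, schedules)
    tr = tr.select_trials(retained_mask)
    tr = align(tr, anchor, window)
    return roi_aggregate(tr, electrodes,
                         sentence_type=schedules[0].sentence_type,
                         rois=[(electrodes[0].roi, electrodes[0].hemisphere)])[0]


def recovery_replicate(
    rng_seed,
    *,
    n_electrodes: int = 30,
    n_trials_per_type: int = 12,
    amplitude: float = 0.10,
    onset_lag_ms: float = 150.0,
    duration_ms: float = 300.0,
    ramp_ms: float = 100.0,
    anchor: str = "p1_offset",
    sentence_type: str = "concrete_first",
    roi: str = "posterior_MFG",
    hemisphere: str = "left",
    noise_spec: NoiseSpec | None = None,
    n_perm: int = 1000,
    slope_window_ms: float = 600.0,
) -> RecoveryResult:
    """One full-chain recovery experiment.

    Synthesizes a single-patient recording with one injected augmentation,
    runs demodulation, percent change, alignment, ROI aggregation,
    permutation/FDR/duration detection and slope estimation, and compares
    against the generator's stored envelope.
    """
    rng = _as_rng(rng_seed)
    scheds = generate_patient_schedules("P01", rng, n_per_type=n_trials_per_type)
    elecs = [Electrode(f"P01_E{i:03d}", "P01", hemisphere, roi)
             for i in range(n_electrodes)]
    effect = EffectSpec(roi, hemisphere, sentence_type, anchor,
                        onset_lag_ms, onset_lag_ms + duration_ms,
                        amplitude, ramp_ms=ramp_ms)
    rec, truth = synthesize_recording(scheds, elecs, [effect], noise_spec,
                                      rng_seed=rng)
    band = high_gamma_amplitude(rec.data, rec.sfreq, channels=rec.channels)
    trace = percent_change(band, scheds)
    retained = filter_trials(scheds)
    trace = trace.select_trials(retained)
    window = (-600.0, onset_lag_ms + duration_ms + 900.0)
    anchored = align(trace, anchor, window)
    tc = roi_aggregate(anchored, elecs, sentence_type=sentence_type,
                       rois=[(roi, hemisphere)])[0]

    result = detect_epochs(tc, n_perm=n_perm, rng_seed=rng)
    lo, hi = onset_lag_ms, onset_lag_ms + duration_ms
    detected = any(
        ep.sign == "augmentation" and ep.start_ms <= hi and ep.end_ms >= lo
        for ep in result.epochs)

    in_interval = (tc.times >= lo) & (tc.times <= hi)
    peak = float(np.nanmax(tc.mean[in_interval]))

    sl = slope_estimate(tc, slope_window_ms, n_boot=100, rng_seed=rng)
    oracle_tc = _oracle_timecourse(truth, scheds, elecs, retained,
                                   anchor, window)
    oracle_sl = slope_estimate(oracle_tc, slope_window_ms, n_boot=10,
                               rng_seed=0)
    return RecoveryResult(
        detected=detected,
        peak_error=peak - 100.0 * amplitude,
        argmax_error_ms=sl.argmax_time - oracle_sl.argmax_time,
        peak_pct=peak,
        n_epochs=len(result.epochs),
    )


def recovery_experiment(n_replicates: int = 100, rng_seed=None,
                        **kwargs) -> pd.DataFrame:
    """Run repeated recovery replicates; one row per replicate."""
    rng = _as_rng(rng_seed)
    rows = []
    for _ in range(n_replicates):
        r = recovery_replicate(rng, **kwargs)
        rows.append({"detected": r.detected, "peak_error": r.peak_error,
                     "argmax_error_ms": r.argmax_error_ms,
                     "peak_pct": r.peak_pct, "n_epochs": r.n_epochs})
    return pd.DataFrame(rows)


def lmm_recovery(n_replicates: int = 200, *, n_patients: int = 12,
                 n_electrodes_per_patient: int = 5, effect: float = 5.0,
                 intercept_sd: float = 3.0, residual_sd: float = 5.0,
                 rng_seed=None) -> pd.DataFrame:
    """Parameter recovery for the window mixed model.

    Each replicate simulates electrode-level window values for both
    sentence types with a Gaussian per-patient random intercept, fits the
    mixed model, and records the sentence-type estimate, its CI and
    whether the CI covers the true effect.
    """
    rng = _as_rng(rng_seed)
    rows = []
    for _ in range(n_replicates):
        recs = []
        for p in range(n_patients):
            u = rng.normal(0.0, intercept_sd)
            for e in range(n_electrodes_per_patient):
                for stype, shift in (("concrete_first", effect), ("wh_first", 0.0)):
                    recs.append({
                        "value": u + shift + rng.normal(0.0, residual_sd),
                        "sentence_type": stype,
                        "patient_id": f"P{p:02d}",
                    })
        fit = fit_window_lmm(pd.DataFrame(recs))
        coef = fit.sentence_type_effect
        rows.append({
            "estimate": coef["estimate"],
            "ci_low": coef["ci_low"], "ci_high": coef["ci_high"],
            "p": coef["p"],
            "covered": coef["ci_low"] <= effect <= coef["ci_high"],
            "singular": fit.singular,
        })
    return pd.DataFrame(rows)


def lmm_calibration(n_replicates: int = 200, rng_seed=None,
                    **kwargs) -> float:
    """Type-I error of the mixed-model sentence-type test (zero effect)."""
    df = lmm_recovery(n_replicates, effect=0.0, rng_seed=rng_seed, **kwargs)
    return float((df["p"] < 0.05).mean())
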