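"""Per-bin significance of ROI high-gamma modulation and slope-of-rise.

Significance of the across-electrode mean at each 10-ms bin is assessed
with a sign-flip permutation test (electrodes are the exchangeable units;
one sign per electrode per permutation, applied to its whole trace so
temporal correlation is preserved), followed by Benjamini-Hochberg FDR
correction across the time window and a minimum-duration criterion
(default 60 ms) on the surviving runs.

The rate of rise is the ordinary-least-squares slope of the mean trace in
a sliding window (default 600 ms), in percent per second, with a
percentile bootstrap CI over electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from hgmod.cohort import _as_rng


@dataclass
class Epoch:
    start_ms: float     # center of the first significant bin
    end_ms: float       # center of the last significant bin
    sign: str           # "augmentation" or "suppression"
    n_bins: int
    duration_ms: float  # n_bins * bin step (bin width counted)


@dataclass
class SignificanceResult:
    roi: str
    hemisphere: str
    sentence_type: str
    anchor: str
    times: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    epochs: list[Epoch]


@dataclass
class SlopeTrace:
    roi: str
    hemisphere: str
    sentence_type: str
    anchor: str
    times: np.ndarray       # valid window centers, ms
    slope: np.ndarray       # %/s
    ci_low: np.ndarray
    ci_high: np.ndarray
    argmax_time: float      # ms; earliest center on ties


def permutation_mean_test(samples: np.ndarray, n_perm: int = 1000,
                          rng_seed=None) -> np.ndarray:
    """Two-sided sign-flip permutation p-value per bin for mean == 0.

    ``samples`` is electrodes x bins.  Each permutation draws one random
    sign per electrode shared across all bins.  P-values use the add-one
    convention p = (1 + #{|mean*| >= |mean|}) / (n_perm + 1).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be 2-D (electrodes x bins)")
    n_elec, n_bins = samples.shape
    if n_elec < 2:
        raise ValueError("need at least 2 electrodes for exchangeability")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = _as_rng(rng_seed)
    obs = np.abs(samples.mean(axis=0))
    signs = rng.integers(0, 2, size=(n_perm, n_elec)) * 2 - 1
    null = np.abs(signs @ samples) / n_elec          # (n_perm, n_bins)
    exceed = (null >= obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (n_perm + 1.0)


def fdr_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def duration_filter(sig_mask: np.ndarray, times: np.ndarray,
                    min_duration_ms: float = 60.0,
                    mean: np.ndarray | None = None) -> list[Epoch]:
    """Keep maximal runs of significant bins lasting >= min_duration_ms.

    A run of n bins on a step-ms grid counts as n * step ms (the bin width
    is included), so six consecutive 10-ms bins meet a 60-ms criterion.
    When ``mean`` is given, runs are additionally split wherever the sign
    of the mean changes, and each epoch is labelled augmentation or
    suppression accordingly.
    """
    sig = np.asarray(sig_mask, dtype=bool)
    times = np.asarray(times, dtype=float)
    if sig.shape != times.shape:
        raise ValueError("mask and times must have the same shape")
    if sig.size < 2:
        return []
    step = float(times[1] - times[0])

    if mean is not None:
        signs = np.sign(np.asarray(mean))
    else:
        signs = np.ones_like(times)

    epochs: list[Epoch] = []
    i = 0
    n = sig.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and signs[j + 1] == signs[i]:
            j += 1
        n_bins = j - i + 1
        dur = n_bins * step
        if dur >= min_duration_ms:
            epochs.append(Epoch(
                start_ms=float(times[i]),
                end_ms=float(times[j]),
                sign="suppression" if signs[i] < 0 else "augmentation",
                n_bins=n_bins,
                duration_ms=dur,
            ))
        i = j + 1
    return epochs


def detect_epochs(timecourse, *, n_perm: int = 1000, alpha: float = 0.05,
                  min_duration_ms: float = 60.0, rng_seed=None) -> SignificanceResult:
    """Permutation + FDR + duration pipeline on one ROI time course."""
    vals = timecourse.electrode_values
    keep = ~np.all(np.isnan(vals), axis=0)
    p_raw = np.full(vals.shape[1], np.nan)
    p_fdr = np.full(vals.shape[1], np.nan)
    p_raw[keep] = permutation_mean_test(vals[:, keep], n_perm, rng_seed)
    p_fdr[keep] = fdr_adjust(p_raw[keep])
    sig = np.zeros(vals.shape[1], dtype=bool)
    sig[keep] = p_fdr[keep] < alpha
    epochs = duration_filter(sig, timecourse.times, min_duration_ms,
                             mean=timecourse.mean)
    return SignificanceResult(
        roi=timecourse.roi,
        hemisphere=timecourse.hemisphere,
        sentence_type=timecourse.sentence_type,
        anchor=timecourse.anchor,
        times=timecourse.times,
        p_raw=p_raw,
        p_fdr=p_fdr,
        epochs=epochs,
    )


def _sliding_slope(y: np.ndarray, times: np.ndarray, half: int) -> np.ndarray:
    """OLS slope of y against time in each centered window, in %/s.

    y may be 1-D (bins,) or 2-D (rows, bins); valid centers only.
    """
    y2 = np.atleast_2d(y)
    n = y2.shape[1]
    w = 2 * half + 1
    step = times[1] - times[0]
    t = (np.arange(w) - half) * step            # ms, centered
    denom = np.sum(t ** 2)
    # slope[c] = sum_k t_k * y[c-half+k] / denom  (per ms); correlate does this
    num = np.apply_along_axis(np.correlate, 1, y2, t, "valid")
    slope_ms = num / denom
    return (slope_ms * 1000.0)[0] if y.ndim == 1 else slope_ms * 1000.0


def slope_estimate(timecourse, window_ms: float = 600.0, *,
                   n_boot: int = 500, ci: float = 0.95,
                   rng_seed=None) -> SlopeTrace:
    """Sliding-window slope of the ROI mean trace with bootstrap CI.

    The slope is fit to the across-electrode mean within each centered
    window; the CI resamples electrodes with replacement and refits.  The
    reported ``argmax_time`` is the earliest window center attaining the
    maximum slope.
    """
    times = np.asarray(timecourse.times, dtype=float)
    step = times[1] - times[0]
    half = int(round(window_ms / 2.0 / step))
    if 2 * half + 1 < 3:
        raise ValueError("window must span at least 3 bins")
    if 2 * half + 1 > times.size:
        raise ValueError("slope window exceeds the trace span")
    vals = np.asarray(timecourse.electrode_values, dtype=float)
    mean = np.nanmean(vals, axis=0)
    if np.any(np.isnan(mean)):
        raise ValueError("trace contains all-NaN bins inside the span")

    slope = _sliding_slope(mean, times, half)
    centers = times[half:times.size - half]

    rng = _as_rng(rng_seed)
    n_elec = vals.shape[0]
    boots = np.empty((n_boot, slope.size))
    for b in range(n_boot):
        idx = rng.integers(0, n_elec, size=n_elec)
        boots[b] = _sliding_slope(np.nanmean(vals[idx], axis=0), times, half)
    lo, hi = np.nanpercentile(
        boots, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2], axis=0)

    return SlopeTrace(
        roi=getattr(timecourse, "roi", ""),
        hemisphere=getattr(timecourse, "hemisphere", ""),
        sentence_type=getattr(timecourse, "sentence_type", ""),
        anchor=getattr(timecourse, "anchor", ""),
        times=centers,
        slope=slope,
        ci_low=lo,
        ci_high=hi,
        argmax_time=float(centers[int(np.argmax(slope))]),
    )
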