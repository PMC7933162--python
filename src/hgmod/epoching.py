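"""Baseline percent-change traces, event alignment and ROI aggregation.

The percent change of high-gamma amplitude is computed per electrode
relative to the mean amplitude over a resting baseline window (default
-600 to -200 ms before sentence onset, half-open) pooled across the
patient's correct trials.  Traces can then be re-aligned to any trial
event (phrase onsets/offsets, response onset) on the 10-ms grid and
aggregated into per-ROI mean/SE time courses, with the electrode — not the
trial — as the statistical unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hgmod.cohort import Electrode, TrialSchedule, EVENT_NAMES, ROI_BASE
from hgmod.timefreq import BandAmplitude

#: Composite prefrontal ROIs available from :func:`roi_aggregate`.
COMPOSITE_ROIS = {
    "posterior_prefrontal": ("posterior_MFG", "posterior_IFG"),
    "anterior_prefrontal": ("anterior_MFG", "orbitofrontal"),
}


@dataclass
class HighGammaTrace:
    """Per-trial percent-change high-gamma traces locked to an anchor event.

    ``data`` is trial x electrode x time-bin, in percent; bins a trial does
    not cover are NaN.  ``continuous`` keeps the underlying per-electrode
    continuous percent-change series (electrode x absolute bin) so the
    trace can be re-anchored without recomputation.
    """

    data: np.ndarray
    times: np.ndarray               # ms relative to anchor, bin centers
    anchor: str
    trial_ids: list[str]
    channels: list[str]
    sentence_types: np.ndarray      # per trial
    correct: np.ndarray             # per trial, bool
    continuous: np.ndarray | None = None    # (n_elec, n_abs_bins), percent
    abs_times: np.ndarray | None = None     # ms, absolute bin centers
    event_bins: pd.DataFrame | None = None  # trial x event -> absolute bin index
    baseline: np.ndarray | None = None      # per-electrode baseline amplitude

    @property
    def time_step(self) -> float:
        return float(self.times[1] - self.times[0])

    def select_trials(self, mask: np.ndarray) -> "HighGammaTrace":
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            trial_ids=[t for t, m in zip(self.trial_ids, mask) if m],
            sentence_types=self.sentence_types[mask],
            correct=self.correct[mask],
            event_bins=None if self.event_bins is None else self.event_bins.loc[mask].reset_index(drop=True),
        )


@dataclass
class ROITimeCourse:
    """Across-electrode mean/SE percent-change trace for one ROI."""

    roi: str
    hemisphere: str
    sentence_type: str
    anchor: str
    times: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_electrodes: int
    n_patients: int
    electrode_values: np.ndarray    # (n_electrodes, n_bins) trial-averaged traces
    channels: list[str] = field(default_factory=list)


def _nearest_bin(t_ms: np.ndarray | float, step_ms: float) -> np.ndarray:
    """Nearest-bin index on a uniform grid; ties broken toward -inf."""
    return np.ceil(np.asarray(t_ms) / step_ms - 0.5).astype(int)


def percent_change(
    band: BandAmplitude,
    schedules: list[TrialSchedule],
    *,
    baseline_window: tuple[float, float] = (-600.0, -200.0),
    epoch_window: tuple[float, float] = (-600.0, 3900.0),
    per_trial_baseline: bool = False,
) -> HighGammaTrace:
    """Percent change of band amplitude relative to the pre-stimulus baseline.

    The baseline value B is, per electrode, the mean amplitude over the
    half-open ``baseline_window`` (ms relative to sentence onset) pooled
    across all *correct* trials; with ``per_trial_baseline=True`` each
    trial uses its own 400-ms window instead.  Returns a trace locked to
    ``p1_onset`` over ``epoch_window`` (endpoints inclusive).
    """
    step = band.time_step
    amp = band.amplitude
    n_elec, n_abs = amp.shape
    chans = band.channels if band.channels is not None else [f"ch{i}" for i in range(n_elec)]

    onset_bins = np.array([
        _nearest_bin(s.event_times["sentence_onset"], step) for s in schedules])
    base_offsets = np.arange(*(_nearest_bin(b, step) for b in baseline_window))
    correct = np.array([s.correct for s in schedules], dtype=bool)

    def _trial_baseline(tb: int) -> np.ndarray:
        idx = tb + base_offsets
        if idx.min() < 0 or idx.max() >= n_abs:
            raise ValueError("baseline window outside the recorded span")
        return np.nanmean(amp[:, idx], axis=1)

    per_trial_B = np.stack([_trial_baseline(tb) for tb in onset_bins], axis=0)
    if per_trial_baseline:
        B = per_trial_B  # (n_trials, n_elec)
    else:
        if not correct.any():
            raise ValueError("no correct trials to compute the baseline from")
        B = np.nanmean(per_trial_B[correct], axis=0)  # (n_elec,)
        bad = ~(B > 0)
        if bad.any():
            names = [chans[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"non-positive baseline amplitude at electrodes {names}")

    rel_bins = np.arange(_nearest_bin(epoch_window[0], step),
                         _nearest_bin(epoch_window[1], step) + 1)
    n_bins = rel_bins.size
    data = np.full((len(schedules), n_elec, n_bins), np.nan)
    for k, tb in enumerate(onset_bins):
        idx = tb + rel_bins
        valid = (idx >= 0) & (idx < n_abs)
        denom = B[k] if per_trial_baseline else B
        data[k, :, valid] = (100.0 * (amp[:, idx[valid]] - denom[:, None]) / denom[:, None]).T

    continuous = None
    if not per_trial_baseline:
        continuous = 100.0 * (amp - B[:, None]) / B[:, None]

    event_bins = pd.DataFrame({
        e: [_nearest_bin(s.event_times[e], step) for s in schedules]
        for e in EVENT_NAMES})

    return HighGammaTrace(
        data=data,
        times=rel_bins * step,
        anchor="p1_onset",
        trial_ids=[s.trial_id for s in schedules],
        channels=list(chans),
        sentence_types=np.array([s.sentence_type for s in schedules]),
        correct=correct,
        continuous=continuous,
        abs_times=band.times,
        event_bins=event_bins,
        baseline=None if per_trial_baseline else B,
    )


def align(trace: HighGammaTrace, anchor: str,
          window: tuple[float, float]) -> HighGammaTrace:
    """Re-anchor the trace to another trial event.

    Each trial is re-indexed by the nearest 10-ms bin of its anchor time;
    bins outside the recorded span come out NaN.
    """
    if trace.continuous is None or trace.event_bins is None:
        raise ValueError("trace does not carry continuous data; cannot re-anchor")
    if anchor not in trace.event_bins.columns:
        raise ValueError(f"unknown anchor event {anchor!r}")
    step = trace.time_step
    rel_bins = np.arange(_nearest_bin(window[0], step),
                         _nearest_bin(window[1], step) + 1)
    n_trials = trace.data.shape[0]
    n_elec, n_abs = trace.continuous.shape
    data = np.full((n_trials, n_elec, rel_bins.size), np.nan)
    anchor_bins = trace.event_bins[anchor].to_numpy()
    for k, ab in enumerate(anchor_bins):
        idx = ab + rel_bins
        valid = (idx >= 0) & (idx < n_abs)
        data[k, :, valid] = trace.continuous[:, idx[valid]].T
    return replace(trace, data=data, times=rel_bins * step, anchor=anchor)


def filter_trials(schedules: list[TrialSchedule]) -> np.ndarray:
    """Boolean retention mask: correct trials only.

    Logs retention counts per patient and sentence type; warns for any
    patient x sentence-type cell with zero retained trials.
    """
    mask = np.array([s.correct for s in schedules], dtype=bool)
    df = pd.DataFrame({
        "patient": [s.patient_id for s in schedules],
        "stype": [s.sentence_type for s in schedules],
        "correct": mask,
    })
    for (pat, st), grp in df.groupby(["patient", "stype"]):
        if grp["correct"].sum() == 0:
            warnings.warn(
                f"patient {pat}, sentence type {st}: no correct trials "
                f"retained; cell will be dropped downstream", stacklevel=2)
    return mask


def trial_average(trace: HighGammaTrace,
                  sentence_type: str | None = None) -> np.ndarray:
    """Per-electrode trial-averaged trace (n_electrodes x n_bins)."""
    if sentence_type is None:
        tmask = np.ones(len(trace.trial_ids), dtype=bool)
    else:
        tmask = trace.sentence_types == sentence_type
    if not tmask.any():
        raise ValueError(f"no trials of sentence type {sentence_type!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        return np.nanmean(trace.data[tmask], axis=0)


def aggregate_electrodes(
    elec_avg: np.ndarray,
    channels: list[str],
    electrodes: list[Electrode],
    *,
    sentence_type_label: str,
    anchor: str,
    times: np.ndarray,
    rois: list[tuple[str, str]] | None = None,
    include_composites: bool = False,
    min_electrodes: int = 1,
) -> list[ROITimeCourse]:
    """Across-electrode mean/SE per ROI from trial-averaged traces.

    ``elec_avg`` rows may come from several patients' recordings; only
    analyzable electrodes enter, and ROIs with no electrodes are omitted
    with a warning.
    """
    by_id = {e.electrode_id: e for e in electrodes}
    elec_meta = [by_id.get(c) for c in channels]

    if rois is None:
        rois = [(r, h) for h in ("left", "right") for r in ROI_BASE]
    targets: list[tuple[str, str, tuple[str, ...]]] = [
        (r, h, (r,)) for r, h in rois]
    if include_composites:
        for name, members in COMPOSITE_ROIS.items():
            for h in ("left", "right"):
                targets.append((name, h, members))

    out: list[ROITimeCourse] = []
    for name, hemi, members in targets:
        sel = [i for i, m in enumerate(elec_meta)
               if m is not None and m.analyzable
               and m.hemisphere == hemi and m.roi in members]
        if len(sel) < min_electrodes:
            warnings.warn(f"ROI {hemi} {name}: no electrodes; omitted",
                          stacklevel=2)
            continue
        vals = elec_avg[sel]
        n = len(sel)
        mean = np.nanmean(vals, axis=0)
        if n > 1:
            se = np.nanstd(vals, axis=0, ddof=1) / np.sqrt(n)
        else:
            se = np.zeros_like(mean)
            warnings.warn(
                f"ROI {hemi} {name}: single electrode; SE set to 0 and "
                f"unreliable", stacklevel=2)
        out.append(ROITimeCourse(
            roi=name,
            hemisphere=hemi,
            sentence_type=sentence_type_label,
            anchor=anchor,
            times=times,
            mean=mean,
            se=se,
            n_electrodes=n,
            n_patients=len({elec_meta[i].patient_id for i in sel}),
            electrode_values=vals,
            channels=[channels[i] for i in sel],
        ))
    return out


def roi_aggregate(
    trace: HighGammaTrace,
    electrodes: list[Electrode],
    *,
    sentence_type: str | None = None,
    rois: list[tuple[str, str]] | None = None,
    include_composites: bool = False,
    min_electrodes: int = 1,
) -> list[ROITimeCourse]:
    """Aggregate one trace's electrode traces into ROI mean/SE time courses.

    Each electrode contributes its trial-averaged trace (trials of the
    requested sentence type; correct-only filtering is assumed done); the
    mean and standard error are then taken across electrodes.  For pooling
    electrodes across several patients' recordings, compute
    :func:`trial_average` per recording and feed the stacked matrices to
    :func:`aggregate_electrodes`.
    """
    elec_avg = trial_average(trace, sentence_type)
    return aggregate_electrodes(
        elec_avg, trace.channels, electrodes,
        sentence_type_label=sentence_type if sentence_type else "both",
        anchor=trace.anchor,
        times=trace.times,
        rois=rois,
        include_composites=include_composites,
        min_electrodes=min_electrodes,
    )
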