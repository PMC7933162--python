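"""Behavioural summaries: response times, accuracy, paired comparisons.

The response time of a trial is the latency from sentence offset (3rd
phrase offset) to response onset.  Per-patient medians are compared
between the two sentence types with a Wilcoxon signed-rank test (exact
null distribution up to n = 25 pairs, normal approximation above; zero
differences are dropped before ranking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hgmod.cohort import TrialSchedule, SENTENCE_TYPES

EXACT_N_MAX = 25


@dataclass
class BehavioralSummary:
    per_patient: pd.DataFrame   # patient_id x (median_rt_*, accuracy_*)
    rt_p: float                 # paired Wilcoxon on median response times
    accuracy_p: float           # paired Wilcoxon on accuracies


def response_times(schedules: list[TrialSchedule]) -> pd.DataFrame:
    """Per-trial response times (ms), correct trials only.

    Trials whose response onset precedes the sentence offset are flagged
    invalid and excluded, with a count in a warning.
    """
    rows = []
    n_invalid = 0
    for s in schedules:
        rt = s.event_times["response_onset"] - s.event_times["p3_offset"]
        if rt <= 0:
            n_invalid += 1
            continue
        rows.append({
            "trial_id": s.trial_id,
            "patient_id": s.patient_id,
            "sentence_type": s.sentence_type,
            "correct": s.correct,
            "rt_ms": rt,
        })
    if n_invalid:
        warnings.warn(f"{n_invalid} trials with response before sentence "
                      f"offset excluded", stacklevel=2)
    df = pd.DataFrame(rows)
    return df[df["correct"]].reset_index(drop=True) if len(df) else df


def paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Exact distribution for n <= 25 non-zero pairs, normal approximation
    (with continuity correction) above.  All-zero differences give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1 by convention",
                      stacklevel=2)
        return 1.0
    ties = np.unique(np.abs(nonzero)).size < nonzero.size
    if nonzero.size <= EXACT_N_MAX and not ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", method=method,
                         correction=(method == "approx"))
    return float(res.pvalue)


def summarize_behavior(schedules_by_patient: dict[str, list[TrialSchedule]]) -> BehavioralSummary:
    """Per-patient RT medians and accuracies plus cohort-level paired tests."""
    rows = []
    for pid, scheds in schedules_by_patient.items():
        rts = response_times(scheds)
        entry: dict = {"patient_id": pid}
        for st in SENTENCE_TYPES:
            sub = [s for s in scheds if s.sentence_type == st]
            entry[f"accuracy_{st}"] = (
                100.0 * np.mean([s.correct for s in sub]) if sub else np.nan)
            sel = rts[rts["sentence_type"] == st] if len(rts) else rts
            entry[f"median_rt_{st}"] = (
                float(sel["rt_ms"].median()) if len(sel) else np.nan)
        rows.append(entry)
    df = pd.DataFrame(rows).set_index("patient_id")
    ok = df.dropna()
    if len(ok) >= 5:
        rt_p = paired_wilcoxon(ok["median_rt_concrete_first"],
                               ok["median_rt_wh_first"])
        acc_p = paired_wilcoxon(ok["accuracy_concrete_first"],
                                ok["accuracy_wh_first"])
    else:
        warnings.warn("fewer than 5 complete patients; paired tests skipped",
                      stacklevel=2)
        rt_p = acc_p = np.nan
    return BehavioralSummary(per_patient=df, rt_p=rt_p, accuracy_p=acc_p)
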