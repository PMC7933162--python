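"""Synthetic study cohort: patients, electrodes and trial schedules.

The generator emulates a multi-patient subdural-grid study of auditory
sentence comprehension.  Each trial plays a three-phrase spoken question in
one of two phrase orders — beginning with a concrete phrase
(``concrete_first``) or with a wh-interrogative (``wh_first``) — and the
patient answers overtly.  Phrase and inter-phrase gap durations are drawn
from truncated normal distributions whose defaults are the acoustic
statistics of the stimulus set; electrode counts per region of interest
(ROI) default to a published 23-patient layout totalling 1,119 analyzable
sites (626 left / 493 right).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

SENTENCE_TYPES = ("concrete_first", "wh_first")
WH_WORDS = ("what", "when", "where")

#: Per-sentence-type acoustic timing of the three phrases and the two
#: inter-phrase gaps, as (mean_ms, sd_ms), in presentation order.
PHRASE_TIMING: dict[str, dict[str, tuple[float, float]]] = {
    "concrete_first": {
        "p1": (546.0, 80.0),
        "gap1": (168.0, 57.0),
        "p2": (538.0, 83.0),
        "gap2": (155.0, 49.0),
        "p3": (410.0, 50.0),
    },
    "wh_first": {
        "p1": (436.0, 56.0),
        "gap1": (181.0, 62.0),
        "p2": (487.0, 100.0),
        "gap2": (157.0, 60.0),
        "p3": (554.0, 75.0),
    },
}

#: Base names of the eight per-hemisphere ROIs; with the two hemispheres
#: these form the 16 analysis ROIs.  ``others`` collects analyzable sites
#: outside the named gyral regions.
ROI_BASE = (
    "posterior_MFG",
    "anterior_MFG",
    "posterior_IFG",
    "orbitofrontal",
    "supramarginal",
    "inferior_precentral",
    "posterior_STG",
    "posterior_MTG",
)
ROI_LABELS = ROI_BASE + ("others",)

HEMISPHERES = ("left", "right")

#: Default analyzable-electrode counts per hemisphere and ROI
#: (left total 626, right total 493, grand total 1,119).
DEFAULT_ELECTRODE_LAYOUT: dict[str, dict[str, int]] = {
    "left": {
        "posterior_MFG": 31,
        "anterior_MFG": 38,
        "posterior_IFG": 30,
        "orbitofrontal": 22,
        "supramarginal": 57,
        "inferior_precentral": 27,
        "posterior_STG": 49,
        "posterior_MTG": 24,
        "others": 348,
    },
    "right": {
        "posterior_MFG": 18,
        "anterior_MFG": 23,
        "posterior_IFG": 20,
        "orbitofrontal": 18,
        "supramarginal": 34,
        "inferior_precentral": 30,
        "posterior_STG": 26,
        "posterior_MTG": 15,
        "others": 309,
    },
}

ELECTRODE_STATUSES = (
    "analyzable",
    "excluded_soz",
    "excluded_spiking",
    "excluded_lesion",
    "excluded_artifact",
)

EVENT_NAMES = (
    "sentence_onset",
    "p1_onset",
    "p1_offset",
    "p2_onset",
    "p2_offset",
    "p3_onset",
    "p3_offset",
    "response_onset",
)

#: Default patient covariate distributions (cohort medians / SDs).
DEFAULT_COVARIATE_PARAMS: dict[str, float] = {
    "age_median": 27.5,
    "age_sd": 10.8,
    "age_min": 8.0,
    "age_max": 65.0,
    "onset_median": 13.8,
    "onset_sd": 11.2,
    "female_rate": 10.0 / 23.0,
    "n_aeds_median": 3.17,
    "n_aeds_sd": 1.05,
    "fiq_median": 81.7,
    "fiq_sd": 14.2,
    "fiq_min": 40.0,
    "congenital_rate": 11.0 / 23.0,
    "accuracy": 0.979,
}

#: Hemisphere-coverage pattern (left-only, right-only, both), cycled over
#: patients; for 23 patients this yields 11 left / 9 right / 3 both, i.e.
#: 14 patients sampling the left hemisphere and 12 the right.
_HEMI_PATTERN = (
    ["left"] * 11 + ["right"] * 9 + [["left", "right"]] * 3  # type: ignore[list-item]
)


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    age: float
    epilepsy_onset_age: float
    sex: str
    n_antiepileptic_drugs: int
    fiq: float
    congenital_lesion: bool
    sampled_hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (self.age > self.epilepsy_onset_age >= 0):
            raise ValueError(
                f"{self.patient_id}: require age > epilepsy_onset_age >= 0"
            )
        if self.n_antiepileptic_drugs < 0:
            raise ValueError(f"{self.patient_id}: negative drug count")
        if self.fiq <= 0:
            raise ValueError(f"{self.patient_id}: FIQ must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"{self.patient_id}: sex must be female/male")
        for h in self.sampled_hemispheres:
            if h not in HEMISPHERES:
                raise ValueError(f"{self.patient_id}: unknown hemisphere {h!r}")


@dataclass(frozen=True)
class Electrode:
    electrode_id: str
    patient_id: str
    hemisphere: str
    roi: str
    status: str = "analyzable"

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.roi not in ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.roi!r}")
        if self.status not in ELECTRODE_STATUSES:
            raise ValueError(f"unknown electrode status {self.status!r}")

    @property
    def analyzable(self) -> bool:
        return self.status == "analyzable"


@dataclass
class TrialSchedule:
    """Event times (ms from recording start) of one sentence trial."""

    trial_id: str
    patient_id: str
    sentence_type: str
    wh_word: str
    event_times: dict[str, float]
    correct: bool = True

    def __post_init__(self) -> None:
        if self.sentence_type not in SENTENCE_TYPES:
            raise ValueError(f"unknown sentence type {self.sentence_type!r}")
        if self.wh_word not in WH_WORDS:
            raise ValueError(f"unknown wh-word {self.wh_word!r}")
        missing = set(EVENT_NAMES) - set(self.event_times)
        if missing:
            raise ValueError(f"{self.trial_id}: missing events {sorted(missing)}")
        t = self.event_times
        if t["p1_onset"] != t["sentence_onset"]:
            raise ValueError(f"{self.trial_id}: p1_onset must equal sentence_onset")
        ordered = [t[e] for e in EVENT_NAMES[1:]]  # p1_onset .. response_onset
        if not all(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError(f"{self.trial_id}: event times not strictly increasing")

    @property
    def response_time_ms(self) -> float:
        """Response latency: response onset minus sentence (3rd phrase) offset."""
        return self.event_times["response_onset"] - self.event_times["p3_offset"]


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float, high: float) -> float:
    """One draw from N(mean, sd) truncated to (low, high) by rejection."""
    if sd < 0:
        raise ValueError("SD must be non-negative")
    if sd == 0:
        if not (low < mean < high):
            raise ValueError("degenerate mean outside truncation bounds")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_schedule(
    sentence_type: str,
    duration_params: dict[str, tuple[float, float]] | None = None,
    rng_seed=None,
    *,
    trial_id: str = "t000",
    patient_id: str = "P00",
    wh_word: str = "what",
    sentence_onset_ms: float = 0.0,
    response_median_ms: float = 1500.0,
    response_sigma: float = 0.35,
    correct: bool = True,
) -> TrialSchedule:
    """Draw one trial schedule.

    Phrase and gap durations come from truncated normal distributions
    (mean ± 3 SD, and strictly positive); the response latency relative to
    the 3rd phrase offset is log-normal with configurable median.
    """
    if sentence_type not in SENTENCE_TYPES:
        raise ValueError(f"unknown sentence type {sentence_type!r}")
    params = duration_params if duration_params is not None else PHRASE_TIMING[sentence_type]
    rng = _as_rng(rng_seed)

    durations: dict[str, float] = {}
    for seg in ("p1", "gap1", "p2", "gap2", "p3"):
        mean, sd = params[seg]
        if mean <= 0 or sd < 0:
            raise ValueError(f"{seg}: mean must be > 0 and SD >= 0")
        low = max(mean - 3.0 * sd, 0.0)
        high = mean + 3.0 * sd
        if sd == 0:
            durations[seg] = mean
        else:
            durations[seg] = _truncnorm(rng, mean, sd, low, high)

    if response_median_ms <= 0:
        raise ValueError("response_median_ms must be positive")
    rt = response_median_ms * float(np.exp(response_sigma * rng.standard_normal()))
    rt = max(rt, 200.0)

    t0 = float(sentence_onset_ms)
    p1_off = t0 + durations["p1"]
    p2_on = p1_off + durations["gap1"]
    p2_off = p2_on + durations["p2"]
    p3_on = p2_off + durations["gap2"]
    p3_off = p3_on + durations["p3"]
    events = {
        "sentence_onset": t0,
        "p1_onset": t0,
        "p1_offset": p1_off,
        "p2_onset": p2_on,
        "p2_offset": p2_off,
        "p3_onset": p3_on,
        "p3_offset": p3_off,
        "response_onset": p3_off + rt,
    }
    return TrialSchedule(
        trial_id=trial_id,
        patient_id=patient_id,
        sentence_type=sentence_type,
        wh_word=wh_word,
        event_times=events,
        correct=correct,
    )


def _trial_sequence(rng: np.random.Generator, n_per_type: int) -> list[tuple[str, str]]:
    """Pseudorandom (sentence_type, wh_word) order, with each wh-word used
    equally often within each sentence type and no two consecutive trials
    sharing a wh-word."""
    if n_per_type % len(WH_WORDS) != 0:
        raise ValueError("trials per type must be divisible by the number of wh-words")
    per_word = n_per_type // len(WH_WORDS)
    items = [
        (stype, word)
        for stype in SENTENCE_TYPES
        for word in WH_WORDS
        for _ in range(per_word)
    ]
    items = list(items)
    for _attempt in range(200):
        order = [items[i] for i in rng.permutation(len(items))]
        ok = _repair_wh_runs(order, rng)
        if ok:
            return order
    raise RuntimeError("failed to build a wh-word-constrained trial order")


def _repair_wh_runs(order: list[tuple[str, str]], rng: np.random.Generator,
                    max_passes: int = 50) -> bool:
    n = len(order)
    for _ in range(max_passes):
        bad = [i for i in range(1, n) if order[i][1] == order[i - 1][1]]
        if not bad:
            return True
        fixed_any = False
        for i in bad:
            if order[i][1] != order[i - 1][1]:
                continue  # already fixed by an earlier swap
            for j in rng.permutation(n):
                j = int(j)
                if j == i:
                    continue
                # swapping i and j must break the run at i without creating
                # new runs at either location
                w_i, w_j = order[i][1], order[j][1]
                if w_j == order[i - 1][1]:
                    continue
                if i + 1 < n and w_j == order[i + 1][1]:
                    continue
                left_j = order[j - 1][1] if j - 1 >= 0 and j - 1 != i else (
                    order[i][1] if j - 1 == i else None)
                right_j = order[j + 1][1] if j + 1 < n and j + 1 != i else (
                    order[i][1] if j + 1 == i else None)
                if w_i in (left_j, right_j):
                    continue
                order[i], order[j] = order[j], order[i]
                fixed_any = True
                break
        if not fixed_any:
            return False
    return not any(order[i][1] == order[i - 1][1] for i in range(1, n))


def generate_patient_schedules(
    patient_id: str,
    rng: np.random.Generator,
    *,
    n_per_type: int = 48,
    accuracy: float = 0.979,
    lead_in_ms: float = 3000.0,
    iti_range_ms: tuple[float, float] = (3000.0, 5000.0),
    duration_params: dict | None = None,
    response_median_ms: float = 1500.0,
) -> list[TrialSchedule]:
    """One patient's full pseudorandom session (default 96 trials, 48/type)."""
    order = _trial_sequence(rng, n_per_type)
    schedules: list[TrialSchedule] = []
    t = float(lead_in_ms)
    for k, (stype, word) in enumerate(order):
        params = None if duration_params is None else duration_params.get(stype)
        sched = generate_schedule(
            stype,
            params,
            rng,
            trial_id=f"{patient_id}_t{k:03d}",
            patient_id=patient_id,
            wh_word=word,
            sentence_onset_ms=t,
            response_median_ms=response_median_ms,
            correct=bool(rng.random() < accuracy),
        )
        schedules.append(sched)
        iti = rng.uniform(*iti_range_ms)
        t = sched.event_times["response_onset"] + iti
    return schedules


def generate_cohort(
    n_patients: int = 23,
    electrodes_per_roi: dict[str, dict[str, int]] | None = None,
    trial_counts: int = 48,
    covariate_params: dict[str, float] | None = None,
    rng_seed=None,
    *,
    iti_range_ms: tuple[float, float] = (3000.0, 5000.0),
    lead_in_ms: float = 3000.0,
) -> tuple[list[PatientProfile], list[Electrode], dict[str, list[TrialSchedule]]]:
    """Generate patients, an electrode table and per-patient trial schedules.

    ``electrodes_per_roi`` maps hemisphere -> ROI -> analyzable-site count
    (default: the 1,119-electrode reference layout).  Electrodes in each
    hemisphere are distributed round-robin over the patients sampling that
    hemisphere.  ``trial_counts`` is the number of trials per sentence type
    per patient (default 48, i.e. 96 trials in total).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    layout = electrodes_per_roi if electrodes_per_roi is not None else DEFAULT_ELECTRODE_LAYOUT
    for hemi, rois in layout.items():
        if hemi not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere in layout: {hemi!r}")
        for roi in rois:
            if roi not in ROI_LABELS:
                raise ValueError(f"unknown ROI label in layout: {roi!r}")
    cov = dict(DEFAULT_COVARIATE_PARAMS)
    if covariate_params:
        unknown = set(covariate_params) - set(cov)
        if unknown:
            raise ValueError(f"unknown covariate parameters: {sorted(unknown)}")
        cov.update(covariate_params)
    rng = _as_rng(rng_seed)

    patients: list[PatientProfile] = []
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        hemis = _HEMI_PATTERN[i % len(_HEMI_PATTERN)]
        hemis = (hemis,) if isinstance(hemis, str) else tuple(hemis)
        age = _truncnorm(rng, cov["age_median"], cov["age_sd"],
                         cov["age_min"], cov["age_max"])
        onset = _truncnorm(rng, cov["onset_median"], cov["onset_sd"],
                           0.0, age - 0.5)
        patients.append(PatientProfile(
            patient_id=pid,
            age=round(age, 1),
            epilepsy_onset_age=round(onset, 1),
            sex="female" if rng.random() < cov["female_rate"] else "male",
            n_antiepileptic_drugs=int(round(_truncnorm(
                rng, cov["n_aeds_median"], cov["n_aeds_sd"], -0.49, 8.0))),
            fiq=round(_truncnorm(rng, cov["fiq_median"], cov["fiq_sd"],
                                 cov["fiq_min"], 140.0), 1),
            congenital_lesion=bool(rng.random() < cov["congenital_rate"]),
            sampled_hemispheres=hemis,
        ))

    electrodes: list[Electrode] = []
    counter: dict[str, int] = {p.patient_id: 0 for p in patients}
    for hemi in HEMISPHERES:
        if hemi not in layout:
            continue
        pool = [p.patient_id for p in patients if hemi in p.sampled_hemispheres]
        if not pool:
            pool = [patients[0].patient_id]
            warnings.warn(
                f"no patient samples the {hemi} hemisphere; assigning its "
                f"electrodes to {pool[0]}", stacklevel=2)
        k = 0
        for roi in ROI_LABELS:
            n_sites = layout[hemi].get(roi, 0)
            for _ in range(n_sites):
                pid = pool[k % len(pool)]
                counter[pid] += 1
                electrodes.append(Electrode(
                    electrode_id=f"{pid}_{hemi[0].upper()}{counter[pid]:03d}",
                    patient_id=pid,
                    hemisphere=hemi,
                    roi=roi,
                ))
                k += 1

    schedules = {
        p.patient_id: generate_patient_schedules(
            p.patient_id, rng,
            n_per_type=trial_counts,
            accuracy=cov["accuracy"],
            lead_in_ms=lead_in_ms,
            iti_range_ms=iti_range_ms,
        )
        for p in patients
    }
    return patients, electrodes, schedules
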