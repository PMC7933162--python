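"""Readers and writers for every artifact the pipeline touches.

Raw recordings travel in an HDF5 array container (float32 voltage matrix
in microvolts, channel names and sampling rate as attributes); EDF files
are read through MNE when available.  Events, electrodes and patient
covariates are tab-separated tables in a BIDS-like layout; results are
tidy TSV per stage.  A :class:`RunConfig` captures every parameter of a
run and is archived alongside the outputs so that a run is reproducible
from its config, inputs and seeds alone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from hgmod.cohort import (
    Electrode,
    PatientProfile,
    TrialSchedule,
    EVENT_NAMES,
    ROI_LABELS,
    SENTENCE_TYPES,
    WH_WORDS,
)
from hgmod.simulate import EffectSpec, GroundTruth, NoiseSpec, Recording
from hgmod.timefreq import BandAmplitude


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run, in one document.

    Unknown keys in a YAML file are rejected so that typos cannot silently
    fall back to defaults.
    """

    # cohort / simulation
    n_patients: int = 2
    trials_per_type: int = 48
    sampling_rate: float = 1000.0
    electrodes_per_roi: dict | None = None
    noise: dict = field(default_factory=dict)       # NoiseSpec overrides
    effects: list = field(default_factory=list)     # list of EffectSpec dicts
    iti_range_ms: tuple[float, float] = (3000.0, 5000.0)
    # time-frequency
    band: tuple[float, float] = (65.0, 95.0)
    freq_step: float = 5.0
    time_step_ms: float = 10.0
    lowpass_hz: float = 2.5
    # epoching
    baseline_window: tuple[float, float] = (-600.0, -200.0)
    epoch_window: tuple[float, float] = (-600.0, 3900.0)
    # statistics
    n_perm: int = 1000
    n_boot: int = 2000
    alpha: float = 0.05
    min_duration_ms: float = 60.0
    slope_window_ms: float = 600.0
    # seeds (one per stochastic stage)
    seed_simulate: int = 1
    seed_permutation: int = 2
    seed_bootstrap: int = 3
    # paths
    out_dir: str = "hgmod_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("iti_range_ms", "band", "baseline_window", "epoch_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        for key, val in doc.items():
            if isinstance(val, tuple):
                doc[key] = list(val)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(**self.noise)

    def effect_specs(self) -> list[EffectSpec]:
        return [EffectSpec(**e) for e in self.effects]


# ---------------------------------------------------------------------------
# recordings

def write_recording(path: str | Path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("data", data=rec.data.astype(np.float32),
                                compression="gzip", compression_opts=1)
        dset.attrs["units"] = "uV"
        f.attrs["sfreq"] = rec.sfreq
        f.create_dataset("channels",
                         data=np.array(rec.channels, dtype="S"))


def read_recording(path: str | Path, *, expected_sfreq: float | None = None,
                   channels: list[str] | None = None) -> Recording:
    """Load a recording from HDF5 (or EDF, if MNE is installed).

    ``expected_sfreq`` guards against silently mixing sampling rates;
    ``channels`` restricts loading to a subset, erroring on unknown names.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path)
    else:
        with h5py.File(path, "r") as f:
            rec = Recording(
                data=f["data"][()],
                sfreq=float(f.attrs["sfreq"]),
                channels=[c.decode() for c in f["channels"][()]],
            )
    if expected_sfreq is not None and not np.isclose(rec.sfreq, expected_sfreq):
        raise ValueError(
            f"{path.name}: sampling rate {rec.sfreq} Hz does not match the "
            f"configured {expected_sfreq} Hz")
    if channels is not None:
        unknown = [c for c in channels if c not in rec.channels]
        if unknown:
            raise ValueError(f"{path.name}: unknown channels {unknown}")
        idx = [rec.channels.index(c) for c in channels]
        rec = Recording(data=rec.data[idx], sfreq=rec.sfreq,
                        channels=list(channels))
    return rec


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' extra") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(data=raw.get_data() * 1e6, sfreq=float(raw.info["sfreq"]),
                     channels=list(raw.ch_names))


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("modulation", data=truth.modulation.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f.attrs["sfreq"] = truth.sfreq
        f.create_dataset("channels", data=np.array(truth.channels, dtype="S"))


def read_ground_truth(path: str | Path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        return GroundTruth(
            modulation=f["modulation"][()],
            sfreq=float(f.attrs["sfreq"]),
            channels=[c.decode() for c in f["channels"][()]],
        )


def write_band_amplitude(path: str | Path, band: BandAmplitude) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitude", data=band.amplitude)
        f.create_dataset("times", data=band.times)
        f.create_dataset("member_freqs", data=band.member_freqs)
        f.attrs["band"] = band.band
        f.attrs["sfreq"] = band.sfreq
        f.create_dataset("channels",
                         data=np.array(band.channels or [], dtype="S"))


def read_band_amplitude(path: str | Path) -> BandAmplitude:
    with h5py.File(path, "r") as f:
        chans = [c.decode() for c in f["channels"][()]]
        return BandAmplitude(
            amplitude=f["amplitude"][()],
            band=tuple(f.attrs["band"]),
            member_freqs=f["member_freqs"][()],
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            channels=chans or None,
        )


# ---------------------------------------------------------------------------
# tabular artifacts

def write_events(path: str | Path, schedules: list[TrialSchedule]) -> None:
    """BIDS-style long-format events table (onsets in seconds)."""
    rows = []
    for s in schedules:
        for ev in EVENT_NAMES:
            rows.append({
                "onset": s.event_times[ev] / 1000.0,
                "duration": 0.0,
                "trial_type": s.sentence_type,
                "wh_word": s.wh_word,
                "event": ev,
                "trial_id": s.trial_id,
                "patient_id": s.patient_id,
                "correct": int(s.correct),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[TrialSchedule]:
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "trial_type", "wh_word", "event", "trial_id",
                "patient_id", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    schedules = []
    for tid, grp in df.groupby("trial_id", sort=False):
        times = {row["event"]: row["onset"] * 1000.0 for _, row in grp.iterrows()}
        first = grp.iloc[0]
        schedules.append(TrialSchedule(
            trial_id=str(tid),
            patient_id=str(first["patient_id"]),
            sentence_type=str(first["trial_type"]),
            wh_word=str(first["wh_word"]),
            event_times=times,
            correct=bool(first["correct"]),
        ))
    return schedules


def write_electrodes(path: str | Path, electrodes: list[Electrode]) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in electrodes]).to_csv(
        path, sep="\t", index=False)


def read_electrodes(path: str | Path, *, analyzable_only: bool = False) -> list[Electrode]:
    df = pd.read_csv(path, sep="\t")
    required = {"electrode_id", "patient_id", "hemisphere", "roi", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"electrode table missing columns: {sorted(missing)}")
    unknown = set(df["roi"]) - set(ROI_LABELS)
    if unknown:
        raise ValueError(f"unknown ROI labels: {sorted(unknown)}")
    out = [Electrode(**row) for row in df.to_dict("records")]
    if analyzable_only:
        n_excl = sum(not e.analyzable for e in out)
        if n_excl:
            warnings.warn(f"excluding {n_excl} non-analyzable electrodes "
                          f"(seizure onset zone / spiking / lesion / artifact)",
                          stacklevel=2)
        out = [e for e in out if e.analyzable]
    return out


def write_covariates(path: str | Path, patients: list[PatientProfile]) -> None:
    rows = []
    for p in patients:
        d = dataclasses.asdict(p)
        d["sampled_hemispheres"] = "+".join(p.sampled_hemispheres)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> list[PatientProfile]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.to_dict("records"):
        row["sampled_hemispheres"] = tuple(row["sampled_hemispheres"].split("+"))
        row["congenital_lesion"] = bool(row["congenital_lesion"])
        out.append(PatientProfile(**row))
    return out


# ---------------------------------------------------------------------------
# results bundle

def _epochs_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        for ep in r.epochs:
            rows.append({
                "roi": r.roi, "hemisphere": r.hemisphere,
                "sentence_type": r.sentence_type, "anchor": r.anchor,
                "start_ms": int(round(ep.start_ms)),
                "end_ms": int(round(ep.end_ms)),
                "duration_ms": int(round(ep.duration_ms)),
                "sign": ep.sign,
            })
    return pd.DataFrame(rows, columns=["roi", "hemisphere", "sentence_type",
                                       "anchor", "start_ms", "end_ms",
                                       "duration_ms", "sign"])


def write_results(out_dir: str | Path, *, timecourses=None, significance=None,
                  slopes=None, contrasts=None, lmm_results=None,
                  behavior=None, config: RunConfig | None = None,
                  overwrite: bool = False) -> Path:
    """Write tidy TSV result tables plus a machine-readable run summary.

    Times in output tables are integer milliseconds relative to the named
    anchor (bin centers).
    """
    out = Path(out_dir)
    marker = out / "run_summary.json"
    if marker.exists() and not overwrite:
        raise FileExistsError(f"{out} already holds results; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    if timecourses:
        sig_by_key = {}
        if significance:
            sig_by_key = {(r.roi, r.hemisphere, r.sentence_type, r.anchor): r
                          for r in significance}
        rows = []
        for tc in timecourses:
            key = (tc.roi, tc.hemisphere, tc.sentence_type, tc.anchor)
            sig = sig_by_key.get(key)
            for i, t in enumerate(tc.times):
                row = {
                    "roi": tc.roi, "hemisphere": tc.hemisphere,
                    "sentence_type": tc.sentence_type, "anchor": tc.anchor,
                    "time_ms": int(round(t)),
                    "mean_pct": tc.mean[i], "se_pct": tc.se[i],
                    "n_electrodes": tc.n_electrodes,
                }
                if sig is not None:
                    row["p_raw"] = sig.p_raw[i]
                    row["p_fdr"] = sig.p_fdr[i]
                    row["in_epoch"] = int(any(
                        ep.start_ms <= t <= ep.end_ms for ep in sig.epochs))
                rows.append(row)
        pd.DataFrame(rows).to_csv(out / "roi_timecourses.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        summary["n_timecourses"] = len(timecourses)
    if significance:
        _epochs_frame(significance).to_csv(out / "significant_epochs.tsv",
                                           sep="\t", index=False)
        summary["n_epochs"] = int(sum(len(r.epochs) for r in significance))
    if slopes:
        rows = []
        for s in slopes:
            for i, t in enumerate(s.times):
                rows.append({
                    "roi": s.roi, "hemisphere": s.hemisphere,
                    "sentence_type": s.sentence_type, "anchor": s.anchor,
                    "time_ms": int(round(t)), "slope_pct_per_s": s.slope[i],
                    "ci_low": s.ci_low[i], "ci_high": s.ci_high[i],
                    "argmax_ms": int(round(s.argmax_time)),
                })
        pd.DataFrame(rows).to_csv(out / "slopes.tsv", sep="\t", index=False,
                                  float_format="%.6g")
    if contrasts:
        pd.DataFrame([{
            "roi": c.roi, "hemisphere": c.hemisphere, "window": c.window,
            "mean_diff_pct": c.mean_diff, "t": c.t_stat,
            "ci_low": c.ci95[0], "ci_high": c.ci95[1],
            "p_raw": c.p_raw, "p_fdr": c.p_fdr,
            "n_concrete": c.n_a, "n_wh": c.n_b,
        } for c in contrasts]).to_csv(out / "window_contrasts.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        summary["n_contrasts"] = len(contrasts)
    if lmm_results:
        rows = []
        for r in lmm_results:
            for term, coef in r.coefficients.iterrows():
                rows.append({
                    "roi": r.roi, "hemisphere": r.hemisphere,
                    "window": r.window, "term": term,
                    "estimate": coef["estimate"], "se": coef["se"],
                    "ci_low": coef["ci_low"], "ci_high": coef["ci_high"],
                    "p": coef["p"],
                    "p_fdr": r.p_fdr if term == "sentence_type" else np.nan,
                    "random_intercept_var": r.random_intercept_var,
                    "converged": int(r.converged),
                    "singular": int(r.singular),
                })
        pd.DataFrame(rows).to_csv(out / "lmm_coefficients.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        summary["n_lmm_fits"] = len(lmm_results)
    if behavior is not None:
        behavior.per_patient.to_csv(out / "behavior_per_patient.tsv", sep="\t",
                                    float_format="%.6g")
        summary["behavior_rt_p"] = behavior.rt_p
        summary["behavior_accuracy_p"] = behavior.accuracy_p
    if config is not None:
        config.to_yaml(out / "config_snapshot.yaml")
    marker.write_text(json.dumps(summary, indent=2, default=float))
    return out
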