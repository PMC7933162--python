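"""Forward model: raw multi-electrode voltage with known high-gamma effects.

Each electrode's signal is the sum of three components:

* an aperiodic 1/f background (power spectral density proportional to
  ``f ** -one_over_f_exponent``),
* mains (AC line) interference at 50 or 60 Hz, and
* a 65-95 Hz band-limited Gaussian carrier whose instantaneous envelope is
  ``hg_background_level * (1 + m(t))``, where ``m(t)`` is the sum of the
  requested event-locked effects (ramped boxcars per trial).

The modulation ``m(t)`` is returned alongside the voltage so that recovery
of effect size and timing can be checked against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hgmod.cohort import (
    Electrode,
    TrialSchedule,
    EVENT_NAMES,
    HEMISPHERES,
    ROI_LABELS,
    SENTENCE_TYPES,
    _as_rng,
)

HG_BAND = (65.0, 95.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Background-signal parameters (amplitudes in microvolts)."""

    one_over_f_exponent: float = 1.0
    background_rms: float = 15.0
    line_freq: float = 60.0
    line_amplitude: float = 10.0
    hg_background_level: float = 15.0

    def __post_init__(self) -> None:
        for name in ("background_rms", "line_amplitude", "hg_background_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if HG_BAND[0] <= self.line_freq <= HG_BAND[1]:
            raise ValueError("line frequency must lie outside the 65-95 Hz band")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth high-gamma modulation tied to a trial event.

    ``amplitude_change`` is a signed fraction (+0.10 = +10 % envelope
    augmentation, -0.053 = -5.3 % suppression).  The modulation is a boxcar
    from ``anchor + onset_lag`` to ``anchor + offset_lag`` with linear
    ramps of ``ramp_ms`` on either side.
    """

    roi: str
    hemisphere: str
    sentence_type: str  # concrete_first, wh_first, or both
    anchor: str
    onset_lag_ms: float
    offset_lag_ms: float
    amplitude_change: float
    ramp_ms: float = 100.0
    additive: bool = False

    def __post_init__(self) -> None:
        if self.roi not in ROI_LABELS:
            raise ValueError(f"unknown ROI {self.roi!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.sentence_type not in SENTENCE_TYPES + ("both",):
            raise ValueError(f"unknown sentence type {self.sentence_type!r}")
        if self.anchor not in EVENT_NAMES:
            raise ValueError(f"unknown anchor event {self.anchor!r}")
        if not self.onset_lag_ms < self.offset_lag_ms:
            raise ValueError("onset_lag_ms must be < offset_lag_ms")
        if self.amplitude_change <= -1.0:
            raise ValueError("amplitude_change must be > -1")
        if self.ramp_ms < 0:
            raise ValueError("ramp_ms must be non-negative")


@dataclass
class Recording:
    """Electrode x time voltage matrix at a fixed sampling rate."""

    data: np.ndarray  # (n_electrodes, n_samples), microvolts
    sfreq: float
    channels: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (electrodes x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel list does not match data rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sfreq


@dataclass
class GroundTruth:
    """True fractional envelope modulation m(t) per electrode sample."""

    modulation: np.ndarray  # (n_electrodes, n_samples)
    sfreq: float
    channels: list[str]

    def at_times(self, times_ms: np.ndarray) -> np.ndarray:
        """Sample m(t) at the given times (ms from recording start)."""
        idx = np.clip(np.round(np.asarray(times_ms) * self.sfreq / 1000.0).astype(int),
                      0, self.modulation.shape[1] - 1)
        return self.modulation[:, idx]


def _one_over_f_noise(rng: np.random.Generator, n_elec: int, n_samp: int,
                      sfreq: float, exponent: float, rms: float,
                      f_low: float = 0.5) -> np.ndarray:
    """Gaussian noise with PSD proportional to f**-exponent above f_low."""
    if rms == 0:
        return np.zeros((n_elec, n_samp))
    from scipy.fft import next_fast_len
    n_fft = next_fast_len(n_samp, real=True)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sfreq)
    shape = np.zeros_like(freqs)
    keep = freqs >= f_low
    shape[keep] = freqs[keep] ** (-exponent / 2.0)
    coef = (rng.standard_normal((n_elec, freqs.size))
            + 1j * rng.standard_normal((n_elec, freqs.size))) * shape
    x = np.fft.irfft(coef, n=n_fft, axis=1)[:, :n_samp]
    scale = rms / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x * scale


def _band_limited_noise(rng: np.random.Generator, n_elec: int, n_samp: int,
                        sfreq: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise strictly band-limited to ``band``."""
    from scipy.fft import next_fast_len
    n_fft = next_fast_len(n_samp, real=True)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sfreq)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    coef = (rng.standard_normal((n_elec, freqs.size))
            + 1j * rng.standard_normal((n_elec, freqs.size))) * mask
    x = np.fft.irfft(coef, n=n_fft, axis=1)[:, :n_samp]
    return x / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))


def _ramped_boxcar(times_ms: np.ndarray, start: float, stop: float,
                   ramp: float) -> np.ndarray:
    """Trapezoid: 0 before start, ramps to 1 over ``ramp``, back down after
    stop over ``ramp``."""
    if ramp <= 0:
        return ((times_ms >= start) & (times_ms < stop)).astype(float)
    up = np.clip((times_ms - start) / ramp, 0.0, 1.0)
    down = np.clip((stop - times_ms) / ramp + 1.0, 0.0, 1.0)
    return np.minimum(up, down)


def build_modulation(
    schedules: list[TrialSchedule],
    electrodes: list[Electrode],
    effect_specs: list[EffectSpec],
    n_samples: int,
    sfreq: float,
) -> np.ndarray:
    """Assemble m(t) per electrode; raises on contradictory overlaps.

    Two effects that touch the same electrode and overlap in time are an
    error unless at least one of them is declared ``additive``.
    """
    n_elec = len(electrodes)
    times_ms = np.arange(n_samples) * (1000.0 / sfreq)
    mod = np.zeros((n_elec, n_samples))
    support: list[np.ndarray | None] = [None] * n_elec

    for spec in effect_specs:
        hit = [i for i, e in enumerate(electrodes)
               if e.roi == spec.roi and e.hemisphere == spec.hemisphere
               and e.analyzable]
        if not hit:
            continue
        contrib = np.zeros(n_samples)
        for sched in schedules:
            if spec.sentence_type != "both" and sched.sentence_type != spec.sentence_type:
                continue
            anchor_t = sched.event_times[spec.anchor]
            contrib += _ramped_boxcar(
                times_ms,
                anchor_t + spec.onset_lag_ms,
                anchor_t + spec.offset_lag_ms,
                spec.ramp_ms,
            )
        contrib *= spec.amplitude_change
        nz = contrib != 0
        for i in hit:
            prev = support[i]
            if prev is not None and not spec.additive and np.any(prev & nz):
                raise ValueError(
                    f"overlapping effects on electrode "
                    f"{electrodes[i].electrode_id}; declare additive=True "
                    f"to stack them")
            mod[i] += contrib
            support[i] = nz if prev is None else (prev | nz)
    if np.any(mod <= -1.0):
        raise ValueError("combined effects drive the envelope below zero")
    return mod


def synthesize_recording(
    schedules: list[TrialSchedule],
    electrodes: list[Electrode],
    effect_specs: list[EffectSpec] | None = None,
    noise_spec: NoiseSpec | None = None,
    sampling_rate: float = 1000.0,
    rng_seed=None,
    *,
    duration_ms: float | None = None,
    tail_ms: float = 3000.0,
) -> tuple[Recording, GroundTruth]:
    """Synthesize one continuous recording for a set of electrodes.

    All schedules and electrodes should belong to a single patient (one
    recording session); the function does not enforce this so that small
    test rigs can mix freely.
    """
    noise = noise_spec if noise_spec is not None else NoiseSpec()
    effects = effect_specs or []
    if sampling_rate < 2.0 * (HG_BAND[1] + 10.0):
        raise ValueError("sampling rate too low for the 65-95 Hz band")
    rng = _as_rng(rng_seed)

    if duration_ms is None:
        if not schedules:
            raise ValueError("need schedules or an explicit duration_ms")
        duration_ms = max(s.event_times["response_onset"] for s in schedules) + tail_ms
    n_samp = int(round(duration_ms * sampling_rate / 1000.0))
    n_elec = len(electrodes)
    if n_elec == 0:
        raise ValueError("no electrodes")

    mod = build_modulation(schedules, electrodes, effects, n_samp, sampling_rate)

    data = _one_over_f_noise(rng, n_elec, n_samp, sampling_rate,
                             noise.one_over_f_exponent, noise.background_rms)
    if noise.line_amplitude > 0:
        t = np.arange(n_samp) / sampling_rate
        phases = rng.uniform(0, 2 * np.pi, size=(n_elec, 1))
        data += noise.line_amplitude * np.sin(
            2 * np.pi * noise.line_freq * t[None, :] + phases)
    if noise.hg_background_level > 0:
        carrier = _band_limited_noise(rng, n_elec, n_samp, sampling_rate, HG_BAND)
        data += noise.hg_background_level * (1.0 + mod) * carrier

    rec = Recording(
        data=data.astype(np.float32),
        sfreq=sampling_rate,
        channels=[e.electrode_id for e in electrodes],
    )
    truth = GroundTruth(modulation=mod.astype(np.float32), sfreq=sampling_rate,
                        channels=list(rec.channels))
    return rec, truth
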