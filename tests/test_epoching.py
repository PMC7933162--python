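import numpy as np
import pytest

from hgmod.cohort import Electrode, generate_patient_schedules
from hgmod.epoching import (align, filter_trials, percent_change,
                            roi_aggregate, trial_average)
from hgmod.timefreq import BandAmplitude


def flat_band(schedules, value=10.0, n_elec=2, duration_ms=None, step=10.0):
    if duration_ms is None:
        duration_ms = max(s.event_times["response_onset"] for s in schedules) + 3000
    n = int(duration_ms // step)
    times = np.arange(n) * step
    amp = np.full((n_elec, n), float(value))
    return BandAmplitude(amplitude=amp, band=(65.0, 95.0),
                         member_freqs=np.arange(65, 100, 5.0), times=times,
                         sfreq=1000.0,
                         channels=[f"E{i:02d}" for i in range(n_elec)])


@pytest.fixture
def schedules():
    rng = np.random.default_rng(0)
    return generate_patient_schedules("P01", rng, n_per_type=3)


class TestPercentChange:
    def test_constant_amplitude_gives_zero(self, schedules):
        tr = percent_change(flat_band(schedules), schedules)
        assert np.nanmax(np.abs(tr.data)) == 0.0

    def test_arithmetic(self, schedules):
        """Baseline 10 uV, bin value 12 uV -> +20%."""
        band = flat_band(schedules)
        s0 = schedules[0]
        i0 = int(round(s0.event_times["sentence_onset"] / 10)) + 50
        band.amplitude[0, i0] = 12.0
        tr = percent_change(band, schedules)
        assert tr.data[0, 0, np.searchsorted(tr.times, 500)] == pytest.approx(20.0)

    def test_baseline_self_consistency(self, mini_recording):
        """Mean percent change inside the baseline window, averaged over
        correct trials, is zero."""
        tr = percent_change(mini_recording["band"], mini_recording["schedules"])
        base = (tr.times >= -600) & (tr.times < -200)
        avg = np.nanmean(tr.data[tr.correct][:, :, base])
        assert abs(avg) < 1e-9

    def test_recovers_injected_effect(self, mini_recording):
        """Trial-averaged trace peaks near +10% where the generator
        injected a +10% augmentation."""
        sch = mini_recording["schedules"]
        tr = percent_change(mini_recording["band"], sch)
        tr = tr.select_trials(filter_trials(sch))
        anch = align(tr, "p1_offset", (-200, 700))
        avg = trial_average(anch, "concrete_first").mean(axis=0)
        sel = (anch.times >= 150) & (anch.times <= 450)
        assert np.nanmax(avg[sel]) == pytest.approx(10.0, abs=2.5)

    def test_degenerate_baseline_names_electrode(self, schedules):
        band = flat_band(schedules, value=0.0)
        with pytest.raises(ValueError, match="E00"):
            percent_change(band, schedules)


class TestAlign:
    def test_p1_onset_identity(self, schedules):
        tr = percent_change(flat_band(schedules), schedules)
        re = align(tr, "p1_onset", (tr.times[0], tr.times[-1]))
        np.testing.assert_array_equal(re.data, tr.data)

    def test_reindexing_collapses_offset_jitter(self, schedules):
        """Trials with different p1_offset times line up exactly after
        anchoring to p1_offset."""
        band = flat_band(schedules)
        step = 10
        for k, s in enumerate(schedules):
            i = int(round(s.event_times["p1_offset"] / step))
            band.amplitude[:, i:i + 10] = 15.0
        tr = percent_change(band, schedules)
        anch = align(tr, "p1_offset", (-100, 200))
        col = np.searchsorted(anch.times, 0)
        assert np.all(anch.data[:, :, col] == pytest.approx(50.0))

    def test_unknown_anchor(self, schedules):
        tr = percent_change(flat_band(schedules), schedules)
        with pytest.raises(ValueError, match="anchor"):
            align(tr, "p9_onset", (-100, 100))

    def test_anchor_invariance_with_identical_events(self):
        """When all trials share identical event times, anchorings are
        time-shifted copies of one another."""
        from hgmod.cohort import PHRASE_TIMING, generate_schedule
        params = {k: (m, 0.0) for k, (m, _) in PHRASE_TIMING["concrete_first"].items()}
        scheds = []
        for k in range(3):
            s = generate_schedule("concrete_first", params, rng_seed=0,
                                  trial_id=f"t{k}", sentence_onset_ms=4000 + 7000 * k,
                                  response_sigma=0.0)
            scheds.append(s)
        band = flat_band(scheds)
        rng = np.random.default_rng(5)
        band.amplitude += rng.random(band.amplitude.shape)
        tr = percent_change(band, scheds)
        a = align(tr, "p1_onset", (0, 500))
        off = scheds[0].event_times["p1_offset"] - scheds[0].event_times["p1_onset"]
        shift = int(round(off / 10)) * 10
        b = align(tr, "p1_offset", (0 - shift, 500 - shift))
        np.testing.assert_allclose(a.data, b.data)


class TestFilterTrials:
    def test_all_correct_identity(self, schedules):
        assert filter_trials(schedules).all()

    def test_incorrect_dropped_with_warning(self, schedules):
        for s in schedules:
            s.correct = False
        with pytest.warns(UserWarning, match="no correct trials"):
            mask = filter_trials(schedules)
        assert not mask.any()

    def test_expected_retention_rate(self):
        """At the default 97.9% accuracy roughly 94 of 96 trials are
        retained in expectation."""
        rng = np.random.default_rng(123)
        kept = [filter_trials(generate_patient_schedules(f"P{i}", rng,
                                                         n_per_type=48)).sum()
                for i in range(30)]
        assert abs(np.mean(kept) - 0.979 * 96) < 1.0


class TestRoiAggregate:
    def test_single_electrode_mean_and_zero_se(self, schedules):
        band = flat_band(schedules, n_elec=1)
        tr = percent_change(band, schedules)
        elecs = [Electrode("E00", "P01", "left", "posterior_MFG")]
        with pytest.warns(UserWarning, match="single electrode"):
            tcs = roi_aggregate(tr, elecs, rois=[("posterior_MFG", "left")])
        assert np.all(tcs[0].se == 0)
        np.testing.assert_array_equal(tcs[0].mean, trial_average(tr)[0])

    def test_identical_traces_zero_se(self, schedules):
        band = flat_band(schedules, n_elec=4)
        tr = percent_change(band, schedules)
        elecs = [Electrode(f"E{i:02d}", "P01", "left", "posterior_MFG")
                 for i in range(4)]
        tcs = roi_aggregate(tr, elecs, rois=[("posterior_MFG", "left")])
        assert np.nanmax(tcs[0].se) == 0.0

    def test_matches_bruteforce(self, mini_recording):
        """ROI mean/SE equal direct recomputation from the trial-average
        matrix."""
        sch = mini_recording["schedules"]
        tr = percent_change(mini_recording["band"], sch)
        tcs = roi_aggregate(tr, mini_recording["electrodes"],
                            sentence_type="concrete_first",
                            rois=[("posterior_MFG", "left")])
        tc = tcs[0]
        mat = trial_average(tr, "concrete_first")
        np.testing.assert_allclose(tc.mean, np.nanmean(mat, axis=0))
        np.testing.assert_allclose(
            tc.se, np.nanstd(mat, axis=0, ddof=1) / np.sqrt(mat.shape[0]))

    def test_excluded_electrodes_do_not_enter(self, schedules):
        band = flat_band(schedules, n_elec=2)
        elecs = [Electrode("E00", "P01", "left", "posterior_MFG"),
                 Electrode("E01", "P01", "left", "posterior_MFG",
                           status="excluded_soz")]
        tr = percent_change(band, schedules)
        with pytest.warns(UserWarning, match="single electrode"):
            tcs = roi_aggregate(tr, elecs, rois=[("posterior_MFG", "left")])
        assert tcs[0].n_electrodes == 1

    def test_composites(self, schedules):
        band = flat_band(schedules, n_elec=2)
        elecs = [Electrode("E00", "P01", "left", "posterior_MFG"),
                 Electrode("E01", "P01", "left", "posterior_IFG")]
        tr = percent_change(band, schedules)
        tcs = roi_aggregate(tr, elecs, rois=[("posterior_MFG", "left")],
                            include_composites=True)
        names = {(t.roi, t.hemisphere) for t in tcs}
        assert ("posterior_prefrontal", "left") in names
        pp = next(t for t in tcs if t.roi == "posterior_prefrontal")
        assert pp.n_electrodes == 2
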