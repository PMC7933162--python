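import numpy as np
import pytest

from hgmod.cohort import Electrode, generate_patient_schedules
from hgmod.simulate import EffectSpec, NoiseSpec, synthesize_recording
from hgmod.timefreq import high_gamma_amplitude


@pytest.fixture(scope="session")
def mini_recording():
    """A small single-patient session with one injected augmentation.

    8 electrodes in the left posterior MFG, 8 trials per sentence type,
    +10% high-gamma augmentation 150-450 ms after the 1st phrase offset in
    concrete-first trials.  Shared session-wide because synthesis plus
    demodulation is the expensive part of the suite.
    """
    rng = np.random.default_rng(1234)
    schedules = generate_patient_schedules("P01", rng, n_per_type=9)
    electrodes = [Electrode(f"P01_E{i:02d}", "P01", "left", "posterior_MFG")
                  for i in range(8)]
    effect = EffectSpec("posterior_MFG", "left", "concrete_first",
                        "p1_offset", 150.0, 450.0, 0.10, ramp_ms=50.0)
    rec, truth = synthesize_recording(schedules, electrodes, [effect],
                                      NoiseSpec(), rng_seed=rng)
    band = high_gamma_amplitude(rec.data, rec.sfreq, channels=rec.channels)
    return {"schedules": schedules, "electrodes": electrodes,
            "effect": effect, "recording": rec, "truth": truth, "band": band}
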