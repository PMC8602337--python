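import pytest

from sleeposc.io_preprocess import preprocess_recording
from sleeposc.spindles import BANDS, calibrate_relpower_threshold
from sleeposc.synthetic import CohortDesign, EffectSpec, generate_cohort


@pytest.fixture(scope="session")
def short_night():
    """One 2 h synthetic calibration night (2 channels) with ground truth."""
    design = CohortDesign(n_subjects=1, sessions_per_condition={"PRE": 1},
                          night_duration_min=120,
                          channel_labels=("C3-A2", "C4-A1"), seed=7)
    return generate_cohort(design, EffectSpec(), 7)[0]


@pytest.fixture(scope="session")
def processed_night(short_night):
    """The same night after EEG preprocessing (0.5-70 Hz, 128 Hz)."""
    rec = preprocess_recording(short_night.recording)
    return rec, short_night.hypnogram, short_night.truth


@pytest.fixture(scope="session")
def calibrated_thresholds(processed_night):
    rec, hyp, _ = processed_night
    return {name: {st: t.threshold for st, t in
                   calibrate_relpower_threshold(rec, hyp, band).items()}
            for name, band in BANDS.items()}
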