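"""Welch band powers per sleep stage.

Computes the four band powers of interest (slow waves 0.5-3.5 Hz, slow
spindles 9-12 Hz, fast spindles 12-15 Hz, overall spindles 9-15 Hz) per
stage: spindle bands averaged across channels, the slow-wave band from
C3-A2 in N3 only.
"""

from sleeposc import (
    CohortDesign,
    EffectSpec,
    generate_cohort,
    preprocess_recording,
    stage_band_powers,
)

design = CohortDesign(n_subjects=1, sessions_per_condition={"PRE": 1},
                      night_duration_min=120,
                      channel_labels=("C3-A2", "C4-A1"), seed=5)
night = generate_cohort(design, EffectSpec(), seed=5)[0]
rec = preprocess_recording(night.recording)

table = stage_band_powers(rec, night.hypnogram)
print(table.to_string(index=False))
# power is the trapezoidal integral of the Welch PSD (8 s Hann segments,
# 50% overlap) over each band, in uV^2; the sw row only exists for N3
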