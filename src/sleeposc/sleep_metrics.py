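"""Global sleep statistics derived from the hypnogram.

Definitions (epoch-resolution arithmetic, "asleep" = any of N1/N2/N3/REM):

* sleep onset — start of the first non-wake epoch;
* final awakening — end of the last non-wake epoch;
* SPT (sleep period time) — final awakening minus sleep onset;
* WASO (wake after sleep onset) — wake time inside the SPT window;
* TST (total sleep time) — SPT minus WASO.

With these definitions TST + WASO = SPT holds exactly and the per-stage
minutes inside the SPT window sum to TST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import NoSleepError
from .io_preprocess import Hypnogram, SLEEP_STAGES


@dataclass
class SleepStats:
    spt_min: float
    tst_min: float
    waso_min: float
    stage_minutes: dict[str, float] = field(default_factory=dict)
    sleep_onset_s: float = 0.0
    final_awakening_s: float = 0.0


def compute_sleep_stats(hypnogram: Hypnogram) -> SleepStats:
    """SPT, TST, WASO and per-stage minutes for one night.

    Raises :class:`NoSleepError` on an all-wake hypnogram.
    """
    stages = hypnogram.stages
    sleep_idx = [i for i, s in enumerate(stages) if s in SLEEP_STAGES]
    if not sleep_idx:
        raise NoSleepError("hypnogram contains no sleep epochs")
    first, last = sleep_idx[0], sleep_idx[-1]
    ep_min = hypnogram.epoch_length / 60.0
    window = stages[first:last + 1]
    spt = len(window) * ep_min
    waso = window.count("W") * ep_min
    stage_minutes = {s: window.count(s) * ep_min for s in SLEEP_STAGES}
    stage_minutes["WASO"] = waso
    return SleepStats(
        spt_min=spt, tst_min=spt - waso, waso_min=waso,
        stage_minutes=stage_minutes,
        sleep_onset_s=hypnogram.start_time + first * hypnogram.epoch_length,
        final_awakening_s=hypnogram.start_time + (last + 1) * hypnogram.epoch_length,
    )
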