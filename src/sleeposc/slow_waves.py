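"""Slow-wave detection in N3 on the left central channel (C3-A2).

The detector follows the classic amplitude/duration-criteria family
(Massimini-style).  The signal is band-passed to 0.5–3.5 Hz with a
linear-phase FIR (0.2 Hz transition band, group delay compensated), zero
crossings segment it into half-waves, and each negative half-wave is
paired with the immediately following positive half-wave.  A candidate
becomes a slow wave when all five bound pairs hold (strict inequalities):

* trough magnitude in (40, 300) µV,
* positive peak in (10, 200) µV,
* peak-to-peak amplitude in (75, 500) µV,
* down-state (negative half-wave) duration in (0.3, 1.5) s,
* up-state (positive half-wave) duration in (0.1, 1.0) s.

Detection is restricted to artifact-free N3 (stage membership decided by
the trough epoch); N2 is excluded to avoid counting K-complexes.  The
slope is the peak-to-peak amplitude divided by the trough-to-peak time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MontageError, ParameterError
from .io_preprocess import (
    Hypnogram,
    Recording,
    design_fir,
    fir_filter,
    stage_artifact_free_seconds,
)


@dataclass(frozen=True)
class SWParams:
    band: tuple[float, float] = (0.5, 3.5)
    fir_transition: float = 0.2            # Hz
    trough_bounds: tuple[float, float] = (40.0, 300.0)   # µV magnitude
    pos_peak_bounds: tuple[float, float] = (10.0, 200.0)  # µV
    p2p_bounds: tuple[float, float] = (75.0, 500.0)       # µV
    down_state_bounds: tuple[float, float] = (0.3, 1.5)   # s
    up_state_bounds: tuple[float, float] = (0.1, 1.0)     # s
    channel: str = "C3-A2"
    stage: str = "N3"
    slope_mode: str = "p2p_over_interval"  # or "max_derivative"

    def __post_init__(self) -> None:
        for lo, hi in (self.trough_bounds, self.pos_peak_bounds,
                       self.p2p_bounds, self.down_state_bounds,
                       self.up_state_bounds):
            if not lo < hi:
                raise ParameterError("bounds must be ordered low < high")


@dataclass
class SWCandidate:
    """A paired negative/positive half-wave before criteria are applied."""

    start: float            # s, negative-going zero crossing
    trough_time: float
    trough_amp: float       # µV, negative
    pos_peak_time: float
    pos_peak_amp: float     # µV
    down_state_dur: float
    up_state_dur: float

    @property
    def p2p_amplitude(self) -> float:
        return self.pos_peak_amp - self.trough_amp

    @property
    def duration(self) -> float:
        return self.down_state_dur + self.up_state_dur


@dataclass
class SWEvent:
    channel: str
    start: float
    trough_time: float
    trough_amp: float
    pos_peak_time: float
    pos_peak_amp: float
    p2p_amplitude: float
    down_state_dur: float
    up_state_dur: float
    duration: float
    slope: float            # µV/s
    stage: str = "N3"


def sw_bandpass(series: np.ndarray, rate: float,
                params: SWParams | None = None) -> np.ndarray:
    """Linear-phase 0.5–3.5 Hz band-pass with compensated group delay."""
    if params is None:
        params = SWParams()
    if rate < 32:
        raise ParameterError("sampling rate must be at least 32 Hz")
    taps = design_fir(params.band[0], params.band[1], rate,
                      transition=params.fir_transition)
    if series.size < 2:
        raise ParameterError("series shorter than the filter length")
    return fir_filter(np.asarray(series, dtype=float), taps)


def pair_waves(filtered: np.ndarray, rate: float) -> list[SWCandidate]:
    """Pair each negative half-wave with the following positive half-wave.

    Half-waves are delimited by zero crossings of the filtered signal; the
    down-state is the duration between the crossings bracketing the
    trough, the up-state likewise for the peak.
    """
    x = np.asarray(filtered, dtype=float)
    sign = np.zeros(x.size, dtype=np.int8)
    sign[x > 0] = 1
    sign[x < 0] = -1

    def _runs(value: int) -> list[tuple[int, int]]:
        sel = sign == value
        if not sel.any():
            return []
        idx = np.flatnonzero(sel)
        runs, start, prev = [], idx[0], idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                runs.append((start, prev + 1))
                start = i
            prev = i
        runs.append((start, prev + 1))
        return runs

    neg_runs = _runs(-1)
    pos_runs = _runs(1)
    if not neg_runs or not pos_runs:
        return []
    pos_starts = np.array([s for s, _ in pos_runs])
    candidates: list[SWCandidate] = []
    for ni, (a, b) in enumerate(neg_runs):
        k = int(np.searchsorted(pos_starts, b))
        if k >= len(pos_runs):
            break
        c, d = pos_runs[k]
        # the positive half-wave must immediately follow (no other negative
        # half-wave in between)
        if ni + 1 < len(neg_runs) and neg_runs[ni + 1][0] < c:
            continue
        i_trough = a + int(np.argmin(x[a:b]))
        i_peak = c + int(np.argmax(x[c:d]))
        candidates.append(SWCandidate(
            start=a / rate,
            trough_time=i_trough / rate,
            trough_amp=float(x[i_trough]),
            pos_peak_time=i_peak / rate,
            pos_peak_amp=float(x[i_peak]),
            down_state_dur=(b - a) / rate,
            up_state_dur=(d - c) / rate,
        ))
    return candidates


def _passes(c: SWCandidate, p: SWParams) -> bool:
    return (p.trough_bounds[0] < -c.trough_amp < p.trough_bounds[1]
            and p.pos_peak_bounds[0] < c.pos_peak_amp < p.pos_peak_bounds[1]
            and p.p2p_bounds[0] < c.p2p_amplitude < p.p2p_bounds[1]
            and p.down_state_bounds[0] < c.down_state_dur < p.down_state_bounds[1]
            and p.up_state_bounds[0] < c.up_state_dur < p.up_state_bounds[1])


def apply_sw_criteria(candidates: list[SWCandidate],
                      params: SWParams | None = None,
                      filtered: np.ndarray | None = None,
                      rate: float | None = None) -> list[SWEvent]:
    """Keep candidates satisfying all five bound pairs; compute slope.

    All bounds are strict; boundary-equal values are rejected.  The
    default slope is p2p / (trough-to-peak interval); ``slope_mode
    "max_derivative"`` instead takes the maximum first derivative of the
    filtered signal between trough and peak (requires ``filtered`` and
    ``rate``).
    """
    if params is None:
        params = SWParams()
    events: list[SWEvent] = []
    for c in candidates:
        if not _passes(c, params):
            continue
        interval = c.pos_peak_time - c.trough_time
        if params.slope_mode == "max_derivative":
            if filtered is None or rate is None:
                raise ParameterError("max_derivative slope needs the filtered series")
            i0 = int(round(c.trough_time * rate))
            i1 = int(round(c.pos_peak_time * rate))
            seg = np.diff(filtered[i0:i1 + 1]) * rate
            slope = float(np.max(seg)) if seg.size else float("nan")
        else:
            slope = c.p2p_amplitude / interval if interval > 0 else float("nan")
        events.append(SWEvent(
            channel=params.channel, start=c.start, trough_time=c.trough_time,
            trough_amp=c.trough_amp, pos_peak_time=c.pos_peak_time,
            pos_peak_amp=c.pos_peak_amp, p2p_amplitude=c.p2p_amplitude,
            down_state_dur=c.down_state_dur, up_state_dur=c.up_state_dur,
            duration=c.duration, slope=slope))
    return events


def detect_slow_waves(recording: Recording, hypnogram: Hypnogram,
                      params: SWParams | None = None
                      ) -> tuple[list[SWEvent], float]:
    """Detect slow waves in artifact-free N3 of channel C3-A2.

    Returns the event list and the density in events per artifact-free N3
    minute (NaN when there is no artifact-free N3).
    """
    if params is None:
        params = SWParams()
    if params.channel not in recording.channels:
        raise MontageError(f"channel {params.channel} not present in recording")
    rate = recording.sampling_rate
    x = recording.channels[params.channel]
    filtered = sw_bandpass(x, rate, params)
    candidates = pair_waves(filtered, rate)
    mask = recording.artifact_mask(params.channel)
    kept: list[SWCandidate] = []
    for c in candidates:
        if hypnogram.stage_at(c.trough_time) != params.stage:
            continue
        i = min(int(round(c.trough_time * rate)), mask.size - 1)
        if mask[i]:
            continue
        kept.append(c)
    events = apply_sw_criteria(kept, params, filtered, rate)
    free = stage_artifact_free_seconds(recording, hypnogram, params.channel)
    minutes = free.get(params.stage, 0.0) / 60.0
    density = len(events) / minutes if minutes > 0 else float("nan")
    return events, density
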