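"""Synthetic polysomnography cohorts with ground-truth oscillation events.

Spaceflight sleep-EEG recordings are rarely publicly available, so every
downstream stage of this package is validated against simulated nights: stage-structured 1/f
background EEG with sleep spindles and slow waves injected at known times,
frequencies and amplitudes.  The generator reproduces the study design it
emulates — four subjects recorded over preflight (PRE), inflight (IN) and
postflight (POST) sessions, four referenced EEG channels at 256 Hz, a
melatonin/placebo crossover on PRE and IN nights, and one PRE placebo
night per subject flagged for detector calibration — and injects condition
effects (fast-spindle density, slow-spindle frequency, slow-wave amplitude,
sleep curtailment) as shifts of the generating parameters, with subject
heterogeneity entering as Gaussian random intercepts.  That structure is
exactly the random-intercept linear mixed model assumed by the inference
layer, so recovery of the injected shifts is a meaningful end-to-end test.

All randomness flows from one seed; identical (design, effects, seed)
produce bit-identical cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .errors import DesignError, PlacementError
from .io_preprocess import Hypnogram, Recording, RecordingMeta, design_fir, fir_filter

SPINDLE_KINDS = ("slow_spindle", "fast_spindle")
SLOW_BAND = (9.0, 12.0)
FAST_BAND = (12.0, 15.0)

#: broadband RMS of the N2 background in microvolts (conventional value;
#: the study's recordings carry no published amplitude norms)
DEFAULT_N2_RMS = 15.0

#: per-stage RMS relative to N2 — deeper sleep carries more delta power
STAGE_RMS_SCALE = {"W": 0.6, "N1": 0.8, "N2": 1.0, "N3": 1.4, "REM": 0.7}


@dataclass(frozen=True)
class CohortDesign:
    """Structure of the simulated cohort (defaults emulate the study)."""

    n_subjects: int = 4
    sessions_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"PRE": 2, "IN": 4, "POST": 3})
    night_duration_min: float = 480.0
    channel_labels: tuple[str, ...] = ("C3-A2", "C4-A1", "O1-A2", "O2-A1")
    sampling_rate: float = 256.0
    seed: int = 0
    #: subjects (0-based indices) that never receive melatonin; by default
    #: one of the four subjects is melatonin-naive, matching the design
    melatonin_naive_subjects: tuple[int, ...] = (3,)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise DesignError("need at least one subject")
        if any(v < 1 for v in self.sessions_per_condition.values()):
            raise DesignError("session counts must be positive")
        if self.sessions_per_condition.get("PRE", 0) < 1:
            raise DesignError("need at least one PRE night for calibration")

    @property
    def nights_per_subject(self) -> int:
        return sum(self.sessions_per_condition.values())


@dataclass(frozen=True)
class EffectSpec:
    """Generating parameters and condition effects for the cohort.

    Baseline rates/morphologies are conventional sleep-EEG values; the
    inflight shifts default to the effect sizes the analysis is meant to
    resolve (fast-spindle density +1.757 /min, slow-spindle frequency
    +0.170 Hz, slow-wave amplitude −2.530 µV, sleep-period time
    −41.976 min).
    """

    # inflight condition shifts
    fast_density_shift_IN: float = 1.757     # spindles/min, N2 rate
    slow_freq_shift_IN: float = 0.170        # Hz
    sw_amplitude_shift_IN: float = -2.530    # µV on trough magnitude
    spt_shift_IN: float = -41.976            # min of sleep curtailed

    # baseline event rates (per artifact-free minute of the stage)
    fast_density_N2: float = 2.2
    fast_density_N3: float = 0.8
    slow_density_N2: float = 1.5
    slow_density_N3: float = 0.8
    sw_density_N3: float = 3.0

    # spindle morphology
    slow_freq_mean: float = 10.7             # Hz
    fast_freq_mean: float = 13.4             # Hz
    freq_sd: float = 0.25
    spindle_p2p_mean: float = 40.0           # µV
    spindle_p2p_sd: float = 8.0
    spindle_p2p_min: float = 20.0
    spindle_dur_mean: float = 0.9            # s
    spindle_dur_sd: float = 0.25

    # slow-wave morphology
    sw_trough_mean: float = 90.0             # µV magnitude
    sw_trough_sd: float = 20.0
    sw_peak_mean: float = 35.0               # µV
    sw_peak_sd: float = 8.0

    # background
    background_rms_N2: float = DEFAULT_N2_RMS
    background_alpha: float = 1.0

    # between-subject SDs of random intercepts, per generating parameter
    subject_sd: Mapping[str, float] = field(default_factory=lambda: {
        "fast_density": 0.3, "slow_density": 0.2, "slow_freq": 0.08,
        "fast_freq": 0.08, "sw_trough": 5.0, "sw_density": 0.3,
    })

    # optional melatonin shifts applied on active nights, keyed like the
    # condition shifts (e.g. {"slow_density": 0.3})
    melatonin_effects: Mapping[str, float] = field(default_factory=dict)


@dataclass
class TruthEvent:
    """Ground-truth injected oscillation."""

    kind: str                   # slow_spindle | fast_spindle | slow_wave
    channel: str
    start: float                # s
    end: float                  # s
    stage: str                  # stage at onset
    frequency: float | None = None       # Hz, spindles only
    p2p_amplitude: float = 0.0           # µV
    trough_amp: float | None = None      # µV (negative), slow waves only
    peak_amp: float | None = None        # µV, slow waves only

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SimulatedNight:
    recording: Recording
    hypnogram: Hypnogram
    truth: list[TruthEvent]


def _child_rng(seed: int, *names) -> np.random.Generator:
    """Deterministic per-stage generator forked from one seed by name."""
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def generate_hypnogram(night_duration_min: float, seed: int,
                       epoch_length: float = 30.0,
                       curtail_min: float = 0.0) -> Hypnogram:
    """Cyclic sleep-stage sequence with seeded jitter.

    Builds ~90 min NREM/REM cycles (N1→N2→N3→N2→REM), starts with at least
    one wake epoch, inserts at least one wake-after-sleep-onset bout, and
    guarantees ≥20 min N2 and ≥10 min N3 per 8 h.  ``curtail_min`` converts
    that much trailing sleep to wake, shortening the sleep period (used to
    emulate inflight sleep curtailment).
    """
    if night_duration_min < 90:
        raise DesignError("night must be at least 90 minutes")
    rng = _child_rng(seed, "hypnogram")
    n_epochs = int(round(night_duration_min * 60.0 / epoch_length))
    stages: list[str] = ["W"] * int(rng.integers(1, 4))
    cycle = 0
    while len(stages) < n_epochs:
        n1 = int(rng.integers(1, 3))
        n2a = int(rng.integers(14, 22))
        n3 = max(2, int(rng.integers(16, 24)) - 6 * cycle)
        n2b = int(rng.integers(6, 12))
        rem = min(2 + 3 * cycle + int(rng.integers(0, 3)), 20)
        stages += ["N1"] * n1 + ["N2"] * n2a + ["N3"] * n3 + ["N2"] * n2b + ["REM"] * rem
        if cycle == 0:
            stages += ["W"] * int(rng.integers(1, 3))  # WASO bout
        cycle += 1
    stages = stages[:n_epochs]

    # ensure a WASO bout survives truncation
    first_sleep = next((i for i, s in enumerate(stages) if s != "W"), None)
    if first_sleep is not None and "W" not in stages[first_sleep:]:
        mid = first_sleep + (len(stages) - first_sleep) // 2
        stages[mid] = "W"

    if curtail_min > 0:
        k = int(round(curtail_min * 60.0 / epoch_length))
        # walk back from the end converting sleep epochs to wake
        converted = 0
        for i in range(len(stages) - 1, -1, -1):
            if converted >= k:
                break
            if stages[i] != "W":
                stages[i] = "W"
                converted += 1
    return Hypnogram(stages=tuple(stages), epoch_length=epoch_length)


# ---------------------------------------------------------------------------
# background EEG
# ---------------------------------------------------------------------------

def generate_background(duration_s: float, rate: float,
                        hypnogram: Hypnogram | None, seed: int,
                        rms_n2: float = DEFAULT_N2_RMS,
                        alpha: float = 1.0) -> np.ndarray:
    """Gaussian 1/f^alpha noise with stage-dependent RMS scaling.

    The series is normalised so its overall RMS before stage scaling is
    ``rms_n2``; N2 samples keep that RMS, deeper stages are scaled up and
    wake/REM down (:data:`STAGE_RMS_SCALE`).
    """
    n = int(round(duration_s * rate))
    if n == 0:
        return np.zeros(0)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms_n2 / np.sqrt(np.mean(x ** 2))
    if hypnogram is not None:
        stages = hypnogram.sample_stages(rate, n)
        gain = np.ones(n)
        for stage, g in STAGE_RMS_SCALE.items():
            gain[stages == stage] = g
        x = x * gain
    return x


# ---------------------------------------------------------------------------
# event injection
# ---------------------------------------------------------------------------

def _overlap_fraction(a0: float, a1: float, b0: float, b1: float) -> float:
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    return inter / max(min(a1 - a0, b1 - b0), 1e-12)


def inject_spindle(series: np.ndarray, rate: float, t0: float, freq: float,
                   dur: float, p2p: float, channel: str = "C3-A2",
                   stage: str = "N2",
                   existing: Sequence[TruthEvent] = ()) -> tuple[np.ndarray, TruthEvent]:
    """Add a Hann-windowed spindle burst and return the truth record.

    The waveform is ``(p2p/2) * w(t) * sin(2π f (t−t0) + φ)`` with a Hann
    envelope ``w`` and phase chosen so the envelope centre coincides with a
    positive peak of the carrier.  Overlapping an existing same-kind event
    on the same channel by more than 50% raises :class:`PlacementError`.
    """
    if not 9.0 <= freq <= 15.0:
        raise PlacementError(f"spindle frequency {freq} outside [9, 15] Hz")
    if not 0.5 <= dur <= 2.0:
        raise PlacementError(f"spindle duration {dur} outside [0.5, 2] s")
    i0 = int(round(t0 * rate))
    i1 = int(round((t0 + dur) * rate))
    if i0 < 0 or i1 > len(series):
        raise PlacementError("spindle does not fit in the series")
    kind = "fast_spindle" if freq >= 12.0 else "slow_spindle"
    for ev in existing:
        if ev.kind == kind and ev.channel == channel:
            if _overlap_fraction(t0, t0 + dur, ev.start, ev.end) > 0.5:
                raise PlacementError("overlaps an existing same-kind event")
    n = i1 - i0
    t = np.arange(n) / rate
    envelope = np.hanning(n)
    phase = np.pi / 2.0 - 2.0 * np.pi * freq * (dur / 2.0)
    wave = (p2p / 2.0) * envelope * np.sin(2.0 * np.pi * freq * t + phase)
    out = series.copy()
    out[i0:i1] += wave
    truth = TruthEvent(kind=kind, channel=channel, start=t0, end=t0 + dur,
                       stage=stage, frequency=freq, p2p_amplitude=p2p)
    return out, truth


def inject_slow_wave(series: np.ndarray, rate: float, t0: float,
                     down_dur: float, up_dur: float, trough: float,
                     peak: float, channel: str = "C3-A2", stage: str = "N3",
                     existing: Sequence[TruthEvent] = ()) -> tuple[np.ndarray, TruthEvent]:
    """Add a biphasic slow wave (negative then positive half-sine).

    ``trough`` and ``peak`` are magnitudes in microvolts; the injected
    waveform reaches ``−trough`` then ``+peak``.
    """
    if not 0.3 < down_dur < 1.5:
        raise PlacementError(f"down-state duration {down_dur} outside (0.3, 1.5) s")
    if not 0.1 < up_dur < 1.0:
        raise PlacementError(f"up-state duration {up_dur} outside (0.1, 1.0) s")
    p2p = trough + peak
    if not 75.0 < p2p < 500.0:
        raise PlacementError(f"peak-to-peak {p2p} outside (75, 500) µV")
    i0 = int(round(t0 * rate))
    n_down = int(round(down_dur * rate))
    n_up = int(round(up_dur * rate))
    i1 = i0 + n_down + n_up
    if i0 < 0 or i1 > len(series):
        raise PlacementError("slow wave does not fit in the series")
    for ev in existing:
        if ev.kind == "slow_wave" and ev.channel == channel:
            if _overlap_fraction(t0, t0 + down_dur + up_dur, ev.start, ev.end) > 0.5:
                raise PlacementError("overlaps an existing slow wave")
    wave = np.concatenate([
        -trough * np.sin(np.pi * np.arange(n_down) / n_down),
        peak * np.sin(np.pi * np.arange(n_up) / n_up),
    ])
    out = series.copy()
    out[i0:i1] += wave
    truth = TruthEvent(kind="slow_wave", channel=channel, start=t0,
                       end=t0 + down_dur + up_dur, stage=stage,
                       p2p_amplitude=p2p, trough_amp=-trough, peak_amp=peak)
    return out, truth


@lru_cache(maxsize=256)
def _sw_inband_extrema(n_down: int, n_up: int, ratio: float,
                       rate: float) -> tuple[float, float]:
    """Extrema of the unit biphasic template after 0.5–3.5 Hz band-passing.

    The slow-wave detector measures amplitudes on the band-passed signal,
    which attenuates long biphasic transients; this factor lets the
    generator target in-band amplitudes.  ``ratio`` is peak/trough of the
    raw template.
    """
    wave = np.concatenate([
        -np.sin(np.pi * np.arange(n_down) / n_down),
        ratio * np.sin(np.pi * np.arange(n_up) / n_up),
    ])
    pad = int(6 * rate)
    padded = np.concatenate([np.zeros(pad), wave, np.zeros(pad)])
    # the detection chain high-passes twice (EEG preprocessing, then the
    # slow-wave band-pass); both are applied here for a faithful factor
    filt = fir_filter(padded, design_fir(0.5, 70.0, rate))
    filt = fir_filter(filt, design_fir(0.5, 3.5, rate, transition=0.2))
    return float(-np.min(filt)), float(np.max(filt))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def enumerate_sessions(design: CohortDesign) -> list[RecordingMeta]:
    """Session metadata for the whole cohort, in generation order.

    Melatonin alternates placebo/active across PRE and IN nights (starting
    with placebo, so the first PRE night of every subject is the placebo
    calibration night); POST nights and melatonin-naive subjects are all
    placebo.
    """
    metas: list[RecordingMeta] = []
    for s in range(design.n_subjects):
        subject = f"S{s + 1:02d}"
        naive = s in design.melatonin_naive_subjects
        crossover_idx = 0
        for condition in ("PRE", "IN", "POST"):
            for k in range(design.sessions_per_condition.get(condition, 0)):
                if condition in ("PRE", "IN") and not naive:
                    mel = "placebo" if crossover_idx % 2 == 0 else "active"
                    crossover_idx += 1
                else:
                    mel = "placebo"
                calib = condition == "PRE" and k == 0
                metas.append(RecordingMeta(
                    subject_id=subject, session_id=f"{condition}{k + 1}",
                    condition=condition, melatonin=mel,
                    is_calibration_night=calib))
    return metas


def _draw_events_for_stage(rng: np.random.Generator, hypnogram: Hypnogram,
                           stage: str, rate_per_min: float,
                           draw_event, channels: Sequence[str],
                           existing: list[TruthEvent],
                           margin: float = 2.5) -> list[tuple]:
    """Poisson placement of events inside contiguous runs of one stage.

    ``draw_event`` maps (rng, t0, channel) to event parameters; placement
    retries a few times on overlap conflicts.  Returns a list of draws
    (channel, t0, params).
    """
    runs = hypnogram.stage_runs(stage)
    total_min = sum(e - s for s, e in runs) / 60.0
    if total_min <= 0 or rate_per_min <= 0:
        return []
    n_events = rng.poisson(rate_per_min * total_min)
    lengths = np.array([e - s for s, e in runs])
    placements = []
    for _ in range(n_events):
        for _attempt in range(8):
            ri = rng.choice(len(runs), p=lengths / lengths.sum())
            s, e = runs[ri]
            if e - s <= margin:
                continue
            t0 = rng.uniform(s, e - margin)
            ch = channels[rng.integers(len(channels))]
            placements.append((ch, t0))
            break
    return placements


def generate_night(meta: RecordingMeta, design: CohortDesign,
                   effects: EffectSpec, subject_offsets: Mapping[str, float],
                   seed: int) -> SimulatedNight:
    """One simulated night: hypnogram, background, injected truth events."""
    rng = _child_rng(seed, meta.subject_id, meta.session_id, "events")
    is_in = meta.condition == "IN"
    curtail = -effects.spt_shift_IN if is_in else 0.0

    hyp = generate_hypnogram(
        design.night_duration_min,
        seed=int(_child_rng(seed, meta.subject_id, meta.session_id,
                            "hyp").integers(2 ** 31)),
        curtail_min=max(curtail, 0.0))

    duration_s = hyp.duration
    rate = design.sampling_rate
    channels: dict[str, np.ndarray] = {}
    for lab in design.channel_labels:
        ch_seed = int(_child_rng(seed, meta.subject_id, meta.session_id,
                                 lab, "bg").integers(2 ** 31))
        channels[lab] = generate_background(
            duration_s, rate, hyp, ch_seed,
            rms_n2=effects.background_rms_N2, alpha=effects.background_alpha)

    def mel(name: str) -> float:
        if meta.melatonin == "active":
            return effects.melatonin_effects.get(name, 0.0)
        return 0.0

    truth: list[TruthEvent] = []

    # --- spindles ---------------------------------------------------------
    spindle_specs = {
        "fast_spindle": {
            "N2": effects.fast_density_N2
                  + (effects.fast_density_shift_IN if is_in else 0.0)
                  + subject_offsets.get("fast_density", 0.0) + mel("fast_density"),
            "N3": effects.fast_density_N3,
            "freq_mean": effects.fast_freq_mean + subject_offsets.get("fast_freq", 0.0),
            "band": FAST_BAND,
        },
        "slow_spindle": {
            "N2": effects.slow_density_N2 + subject_offsets.get("slow_density", 0.0)
                  + mel("slow_density"),
            "N3": effects.slow_density_N3,
            "freq_mean": effects.slow_freq_mean
                         + (effects.slow_freq_shift_IN if is_in else 0.0)
                         + subject_offsets.get("slow_freq", 0.0) + mel("slow_freq"),
            "band": SLOW_BAND,
        },
    }
    for kind, spec in spindle_specs.items():
        for stage in ("N2", "N3"):
            rate_min = max(spec[stage], 0.0)
            if rate_min * (effects.spindle_dur_mean / 60.0) > 0.5:
                raise DesignError("spindle rate would exceed 50% time coverage")
            for focal, t0 in _draw_events_for_stage(
                    rng, hyp, stage, rate_min, None, design.channel_labels, truth):
                lo, hi = spec["band"]
                f = float(np.clip(rng.normal(spec["freq_mean"], effects.freq_sd),
                                  lo + 0.05, hi - 0.05))
                dur = float(np.clip(rng.normal(effects.spindle_dur_mean,
                                               effects.spindle_dur_sd), 0.5, 2.0))
                p2p = float(max(rng.normal(effects.spindle_p2p_mean,
                                           effects.spindle_p2p_sd),
                                effects.spindle_p2p_min))
                if any(_overlap_fraction(t0, t0 + dur, t.start, t.end) > 0.5
                       for t in truth if t.kind == kind):
                    continue
                # one brain event is visible on every electrode: full
                # amplitude on the focal channel, attenuated elsewhere
                try:
                    channels[focal], ev = inject_spindle(
                        channels[focal], rate, t0, f, dur, p2p, channel=focal,
                        stage=stage, existing=())
                except PlacementError:
                    continue
                for other in design.channel_labels:
                    if other == focal:
                        continue
                    gain = float(rng.uniform(0.55, 0.9))
                    channels[other], _ = inject_spindle(
                        channels[other], rate, t0, f, dur, p2p * gain,
                        channel=other, stage=stage, existing=())
                truth.append(ev)

    # --- slow waves (C3-A2 only, N3 only) ---------------------------------
    sw_rate = max(effects.sw_density_N3 + subject_offsets.get("sw_density", 0.0)
                  + mel("sw_density"), 0.0)
    if sw_rate * (1.2 / 60.0) > 0.5:
        raise DesignError("slow-wave rate would exceed 50% time coverage")
    sw_channel = design.channel_labels[0]
    for ch, t0 in _draw_events_for_stage(
            rng, hyp, "N3", sw_rate, None, [sw_channel], truth):
        trough_mag = effects.sw_trough_mean \
            + (effects.sw_amplitude_shift_IN if is_in else 0.0) \
            + subject_offsets.get("sw_trough", 0.0) + mel("sw_trough")
        # targets are in-band amplitudes (what the detector measures on the
        # 0.5-3.5 Hz filtered signal); the raw waveform is scaled up to
        # compensate the band-pass attenuation of long biphasic transients
        trough_t = float(np.clip(rng.normal(trough_mag, effects.sw_trough_sd),
                                 50.0, 290.0))
        peak_t = float(np.clip(rng.normal(effects.sw_peak_mean, effects.sw_peak_sd),
                               12.0, 195.0))
        down = float(rng.uniform(0.4, 1.2))
        up = float(rng.uniform(0.2, 0.8))
        n_down, n_up = int(round(down * rate)), int(round(up * rate))
        ratio = round(peak_t / trough_t, 2)
        ft, fp = _sw_inband_extrema(n_down, n_up, ratio, rate)
        scale = trough_t / ft
        raw_trough = scale
        raw_peak = scale * ratio
        inband_peak = fp * scale
        inband_p2p = trough_t + inband_peak
        if not (76.0 < inband_p2p < 495.0 and 12.0 < inband_peak < 195.0):
            continue
        if not 75.0 < raw_trough + raw_peak < 500.0:
            continue
        if any(_overlap_fraction(t0, t0 + down + up, t.start, t.end) > 0.5
               for t in truth if t.kind == "slow_wave"):
            continue
        try:
            channels[ch], ev = inject_slow_wave(
                channels[ch], rate, t0, down, up, raw_trough, raw_peak,
                channel=ch, stage="N3", existing=())
        except PlacementError:
            continue
        ev.trough_amp = -trough_t
        ev.peak_amp = inband_peak
        ev.p2p_amplitude = inband_p2p
        truth.append(ev)

    truth.sort(key=lambda ev: ev.start)
    rec = Recording(channels=channels, sampling_rate=rate, meta=meta)
    return SimulatedNight(recording=rec, hypnogram=hyp, truth=truth)


def generate_cohort(design: CohortDesign,
                    effects: EffectSpec | None = None,
                    seed: int | None = None) -> list[SimulatedNight]:
    """Simulate the whole cohort; see module docstring for the model."""
    if effects is None:
        effects = EffectSpec()
    if seed is None:
        seed = design.seed
    metas = enumerate_sessions(design)
    nights: list[SimulatedNight] = []
    offsets_by_subject: dict[str, dict[str, float]] = {}
    for meta in metas:
        if meta.subject_id not in offsets_by_subject:
            srng = _child_rng(seed, meta.subject_id, "intercepts")
            offsets_by_subject[meta.subject_id] = {
                name: float(srng.normal(0.0, sd))
                for name, sd in effects.subject_sd.items()}
        nights.append(generate_night(meta, design, effects,
                                     offsets_by_subject[meta.subject_id], seed))
    return nights
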