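"""Recording containers, filtering/resampling, artifact masking and file I/O.

The in-memory model mirrors a referenced polysomnography montage: a
:class:`Recording` holds per-channel amplitude series in microvolts at one
sampling rate, together with artifact intervals and study metadata, and a
:class:`Hypnogram` holds the per-epoch AASM stage sequence (W/N1/N2/N3/REM,
30 s epochs by default).

Filtering follows the modality presets used for sleep EEG analysis:

========  =========  =========  ============  ==============
modality  high-pass  low-pass   target rate   extra
========  =========  =========  ============  ==============
EEG       0.5 Hz     70 Hz      128 Hz        --
EOG       0.16 Hz    35 Hz      64 Hz         moving average
EMG       10.61 Hz   100 Hz     128 Hz        --
========  =========  =========  ============  ==============

Filters are linear-phase windowed-sinc FIRs applied with centred
convolution, so the group delay is fully compensated and event timestamps
downstream are unshifted.  Downsampling uses anti-aliased polyphase
resampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .errors import (
    FormatError,
    InvalidSignalError,
    OutOfRangeError,
    UnitError,
    UnsupportedUpsamplingError,
)

STAGES = ("W", "N1", "N2", "N3", "REM")
SLEEP_STAGES = ("N1", "N2", "N3", "REM")
CONDITIONS = ("PRE", "IN", "POST")
MELATONIN = ("active", "placebo")

#: sentinel channel label for artifact intervals that apply to all channels
ALL_CHANNELS = "ALL"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingMeta:
    """Study metadata attached to one night's recording."""

    subject_id: str
    session_id: str
    condition: str = "PRE"
    melatonin: str = "placebo"
    is_calibration_night: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.melatonin not in MELATONIN:
            raise ValueError(f"melatonin must be one of {MELATONIN}")


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage sequence aligned to a recording.

    Parameters
    ----------
    stages
        Sequence of stage tokens drawn from ``{"W","N1","N2","N3","REM"}``.
    epoch_length
        Epoch duration in seconds (30 s under AASM scoring).
    start_time
        Offset of the first epoch from recording start, in seconds.
    """

    stages: tuple[str, ...]
    epoch_length: float = 30.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage tokens: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        """Span in seconds from start_time to end of last epoch."""
        return self.n_epochs * self.epoch_length

    def stage_at(self, t: float) -> str | None:
        """Stage of the epoch containing time ``t`` (seconds), or None."""
        idx = int(math.floor((t - self.start_time) / self.epoch_length))
        if 0 <= idx < self.n_epochs:
            return self.stages[idx]
        return None

    def stage_seconds(self, stage: str) -> float:
        return self.stages.count(stage) * self.epoch_length

    def sample_stages(self, rate: float, n_samples: int) -> np.ndarray:
        """Stage token per sample for a series at ``rate`` Hz.

        Samples outside the hypnogram span get the empty token ``""``.
        """
        t = self.start_time
        idx = np.floor((np.arange(n_samples) / rate - t) / self.epoch_length)
        idx = idx.astype(np.int64)
        out = np.full(n_samples, "", dtype="U3")
        ok = (idx >= 0) & (idx < self.n_epochs)
        stages_arr = np.asarray(self.stages, dtype="U3")
        out[ok] = stages_arr[idx[ok]]
        return out

    def stage_runs(self, stage: str) -> list[tuple[float, float]]:
        """Maximal contiguous runs of ``stage`` as (start_s, end_s) pairs."""
        runs: list[tuple[float, float]] = []
        start = None
        for i, s in enumerate(self.stages):
            if s == stage and start is None:
                start = i
            elif s != stage and start is not None:
                runs.append((self.start_time + start * self.epoch_length,
                             self.start_time + i * self.epoch_length))
                start = None
        if start is not None:
            runs.append((self.start_time + start * self.epoch_length,
                         self.start_time + self.n_epochs * self.epoch_length))
        return runs


@dataclass
class Recording:
    """Multi-channel signal in microvolts with artifacts and metadata.

    ``channels`` maps referenced-pair labels (e.g. ``"C3-A2"``) to 1-D
    float arrays; all channels share one sampling rate and length.
    ``artifact_intervals`` holds half-open ``(channel_or_ALL, start_s,
    end_s)`` triples in seconds from recording start.
    """

    channels: dict[str, np.ndarray]
    sampling_rate: float
    meta: RecordingMeta
    start_time: float = 0.0
    artifact_intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must share one length")
        for label, x in self.channels.items():
            x = np.asarray(x, dtype=float)
            if not np.all(np.isfinite(x)):
                raise InvalidSignalError(f"channel {label} has non-finite samples")
            self.channels[label] = x
        dur = self.duration
        for ch, s, e in self.artifact_intervals:
            if not (0 <= s < e <= dur + 1e-9):
                raise OutOfRangeError(
                    f"artifact interval ({ch}, {s}, {e}) outside [0, {dur})")
            if ch != ALL_CHANNELS and ch not in self.channels:
                raise OutOfRangeError(f"artifact interval names unknown channel {ch}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def channel_labels(self) -> list[str]:
        return list(self.channels)

    def artifact_mask(self, channel: str) -> np.ndarray:
        """Boolean per-sample mask for one channel; True = excluded."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for ch, s, e in self.artifact_intervals:
            if ch in (channel, ALL_CHANNELS):
                i0 = int(round(s * self.sampling_rate))
                i1 = int(round(e * self.sampling_rate))
                mask[i0:min(i1, self.n_samples)] = True
        return mask

    def union_artifact_mask(self) -> np.ndarray:
        """Per-sample mask excluded on *any* channel (used for pooled stats)."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for label in self.channels:
            mask |= self.artifact_mask(label)
        return mask


@dataclass(frozen=True)
class FilterSpec:
    """Band limits and target rate for one modality."""

    low_cut: float | None
    high_cut: float | None
    target_rate: float
    moving_average: bool = False

    def __post_init__(self) -> None:
        if self.low_cut is not None and self.high_cut is not None:
            if not self.low_cut < self.high_cut:
                raise ValueError("low_cut must be below high_cut")
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")


def preset_specs() -> dict[str, FilterSpec]:
    """Per-modality filtering presets (EEG, EOG, EMG)."""
    return {
        "EEG": FilterSpec(low_cut=0.5, high_cut=70.0, target_rate=128.0),
        "EOG": FilterSpec(low_cut=0.16, high_cut=35.0, target_rate=64.0,
                          moving_average=True),
        "EMG": FilterSpec(low_cut=10.61, high_cut=100.0, target_rate=128.0),
    }


# ---------------------------------------------------------------------------
# filtering / resampling
# ---------------------------------------------------------------------------

def design_fir(low_cut: float | None, high_cut: float | None, rate: float,
               transition: float | None = None) -> np.ndarray:
    """Windowed-sinc linear-phase FIR taps for the given band edges.

    The transition width defaults to half the lower cutoff (or a quarter of
    the upper cutoff for a pure low-pass), which puts the >20 dB stopband
    within one octave of each edge.
    """
    if low_cut is None and high_cut is None:
        raise ValueError("at least one cutoff required")
    if transition is None:
        if low_cut is not None:
            transition = low_cut / 2.0
        else:
            transition = high_cut / 4.0
    numtaps = int(math.ceil(3.3 * rate / transition))
    numtaps += (numtaps + 1) % 2  # odd length -> integer group delay
    if low_cut is not None and high_cut is not None:
        return signal.firwin(numtaps, [low_cut, high_cut], pass_zero=False, fs=rate)
    if low_cut is not None:
        return signal.firwin(numtaps, low_cut, pass_zero=False, fs=rate)
    return signal.firwin(numtaps, high_cut, pass_zero=True, fs=rate)


def fir_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with centred (zero-delay) convolution."""
    return signal.fftconvolve(x, taps, mode="same")


def preprocess_signal(samples: np.ndarray, source_rate: float,
                      spec: FilterSpec) -> np.ndarray:
    """Band-limit and resample one channel according to ``spec``.

    Returns the series at ``spec.target_rate``.  Raises
    :class:`InvalidSignalError` on non-finite input and
    :class:`UnsupportedUpsamplingError` if the target rate exceeds the
    source rate.
    """
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidSignalError("input contains non-finite samples")
    if spec.target_rate > source_rate:
        raise UnsupportedUpsamplingError(
            f"target rate {spec.target_rate} exceeds source rate {source_rate}")
    if x.size == 0:
        return x
    taps = design_fir(spec.low_cut, spec.high_cut, source_rate)
    y = fir_filter(x, taps)
    if spec.moving_average:
        # 5-sample boxcar; inert for the analyses in this package (EOG only)
        y = np.convolve(y, np.ones(5) / 5.0, mode="same")
    if spec.target_rate != source_rate:
        frac = Fraction(spec.target_rate / source_rate).limit_denominator(1000)
        y = signal.resample_poly(y, frac.numerator, frac.denominator)
    return y


def preprocess_recording(recording: Recording,
                         spec: FilterSpec | None = None) -> Recording:
    """Apply the EEG preset (or ``spec``) to every channel of a recording."""
    if spec is None:
        spec = preset_specs()["EEG"]
    channels = {lab: preprocess_signal(x, recording.sampling_rate, spec)
                for lab, x in recording.channels.items()}
    return Recording(channels=channels, sampling_rate=spec.target_rate,
                     meta=recording.meta, start_time=recording.start_time,
                     artifact_intervals=list(recording.artifact_intervals))


# ---------------------------------------------------------------------------
# artifact masking
# ---------------------------------------------------------------------------

def _union_intervals(intervals: Iterable[tuple[float, float]]
                     ) -> list[tuple[float, float]]:
    ivs = sorted(intervals)
    out: list[tuple[float, float]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def mask_artifacts(recording: Recording, hypnogram: Hypnogram
                   ) -> tuple[Recording, dict[str, float]]:
    """Flag artifact samples and return per-stage artifact-free durations.

    The recording is returned unchanged apart from the masks being
    computable (the time base is preserved; nothing is deleted).  The
    second return value maps each stage to its artifact-free time in
    seconds, using the union of all channels' masks.
    """
    dur = recording.duration
    for ch, s, e in recording.artifact_intervals:
        if not (0 <= s < e <= dur + 1e-9):
            raise OutOfRangeError(f"artifact interval ({ch}, {s}, {e}) out of range")
    mask = recording.union_artifact_mask()
    stages = hypnogram.sample_stages(recording.sampling_rate, recording.n_samples)
    free: dict[str, float] = {}
    for stage in STAGES:
        sel = stages == stage
        free[stage] = float(np.sum(sel & ~mask)) / recording.sampling_rate
    return recording, free


def stage_artifact_free_seconds(recording: Recording, hypnogram: Hypnogram,
                                channel: str | None = None) -> dict[str, float]:
    """Artifact-free seconds per stage, for one channel or the union mask."""
    if channel is None:
        mask = recording.union_artifact_mask()
    else:
        mask = recording.artifact_mask(channel)
    stages = hypnogram.sample_stages(recording.sampling_rate, recording.n_samples)
    return {stage: float(np.sum((stages == stage) & ~mask)) / recording.sampling_rate
            for stage in STAGES}


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------
#
# Signals are exchanged as EDF.  Reading goes through MNE; writing uses a
# compact EDF writer below (16-bit, one-second data records), which MNE and
# any polysomnography viewer can read back.

_ACCEPTED_UNITS = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6}


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, recording: Recording,
              physical_dimension: str = "uV") -> None:
    """Write a Recording as EDF (16-bit, 1 s data records).

    The last partial second, if any, is zero-padded.  ``physical_dimension``
    labels the stored values; samples are converted from microvolts into
    that unit before quantization.
    """
    if physical_dimension not in _ACCEPTED_UNITS:
        raise UnitError(f"unsupported physical dimension {physical_dimension!r}")
    scale_to_unit = 1.0 / _ACCEPTED_UNITS[physical_dimension]
    rate = recording.sampling_rate
    if abs(rate - round(rate)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))
    labels = recording.channel_labels
    ns = len(labels)
    n = recording.n_samples
    n_records = int(math.ceil(n / rate)) if n else 0

    data = np.zeros((ns, n_records * rate))
    phys_min, phys_max = [], []
    digital = np.zeros_like(data, dtype=np.int16)
    for i, lab in enumerate(labels):
        x = recording.channels[lab] * scale_to_unit
        data[i, :n] = x
        lo, hi = float(np.min(data[i])), float(np.max(data[i]))
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        gain = (hi - lo) / (32767 - (-32768))
        digital[i] = np.round((data[i] - lo) / gain - 32768).astype(np.int16)

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field(recording.meta.subject_id, 80)
    header += _edf_field(recording.meta.session_id, 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(str(256 + ns * 256), 8)
    header += _edf_field("", 44)
    header += _edf_field(str(n_records), 8)
    header += _edf_field("1", 8)
    header += _edf_field(str(ns), 4)
    for lab in labels:
        header += _edf_field(lab, 16)
    for _ in labels:
        header += _edf_field("", 80)
    for _ in labels:
        header += _edf_field(physical_dimension, 8)
    for v in phys_min:
        header += _edf_field(f"{v:.8g}"[:8], 8)
    for v in phys_max:
        header += _edf_field(f"{v:.8g}"[:8], 8)
    for _ in labels:
        header += _edf_field("-32768", 8)
    for _ in labels:
        header += _edf_field("32767", 8)
    for _ in labels:
        header += _edf_field("", 80)
    for _ in labels:
        header += _edf_field(str(rate), 8)
    for _ in labels:
        header += _edf_field("", 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for i in range(ns):
                fh.write(digital[i, rec * rate:(rec + 1) * rate].tobytes())


def read_recording(path: str | Path, fmt: str = "edf",
                   meta: RecordingMeta | None = None,
                   expected_labels: Sequence[str] | None = None) -> Recording:
    """Read a signal file into a Recording (values in microvolts).

    EDF reading is delegated to MNE; original physical dimensions are
    checked and converted to microvolts.  ``expected_labels``, when given,
    must match the montage exactly.
    """
    if fmt.lower() != "edf":
        raise FormatError(f"unsupported format {fmt!r}")
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    orig_units = getattr(raw, "_orig_units", {}) or {}
    for ch, unit in orig_units.items():
        if unit not in _ACCEPTED_UNITS and unit not in ("n/a", ""):
            raise UnitError(f"channel {ch} has unknown unit {unit!r}")
    labels = list(raw.ch_names)
    if expected_labels is not None and list(expected_labels) != labels:
        raise FormatError(
            f"montage mismatch: expected {list(expected_labels)}, found {labels}")
    data = raw.get_data() * 1e6  # MNE works in volts internally
    if meta is None:
        sidecar = Path(path).with_suffix(".json")
        if sidecar.exists():
            meta = read_meta(sidecar)
        else:
            meta = RecordingMeta(subject_id="unknown", session_id=Path(path).stem)
    return Recording(channels={lab: data[i] for i, lab in enumerate(labels)},
                     sampling_rate=float(raw.info["sfreq"]), meta=meta)


def write_hypnogram(path: str | Path, hypnogram: Hypnogram) -> None:
    with open(path, "w") as fh:
        fh.write(f"epoch_length,{hypnogram.epoch_length}\n")
        for s in hypnogram.stages:
            fh.write(s + "\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a stage-per-row CSV whose header line declares the epoch length."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].lower().startswith("epoch_length"):
        raise FormatError("hypnogram file must start with an epoch_length header")
    epoch_length = float(lines[0].split(",")[1])
    stages = tuple(lines[1:])
    return Hypnogram(stages=stages, epoch_length=epoch_length)


def write_artifacts(path: str | Path,
                    intervals: Sequence[tuple[str, float, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("channel,start_s,end_s\n")
        for ch, s, e in intervals:
            fh.write(f"{ch},{s},{e}\n")


def read_artifacts(path: str | Path) -> list[tuple[str, float, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("channel"):
            raise FormatError("artifact file must have a channel,start_s,end_s header")
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            ch, s, e = ln.split(",")
            out.append((ch, float(s), float(e)))
    return out


def write_meta(path: str | Path, meta: RecordingMeta) -> None:
    with open(path, "w") as fh:
        json.dump({
            "subject_id": meta.subject_id,
            "session_id": meta.session_id,
            "condition": meta.condition,
            "melatonin": meta.melatonin,
            "is_calibration_night": meta.is_calibration_night,
        }, fh, indent=2)


def read_meta(path: str | Path) -> RecordingMeta:
    with open(path) as fh:
        d = json.load(fh)
    return RecordingMeta(**d)


def write_events(path: str | Path, events: Sequence) -> None:
    """Write a sequence of event dataclasses as CSV (one row per event)."""
    import dataclasses

    import pandas as pd

    rows = [dataclasses.asdict(ev) for ev in events]
    pd.DataFrame(rows).to_csv(path, index=False)
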