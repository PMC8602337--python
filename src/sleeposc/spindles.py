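"""Sleep spindle detection in the sigma band (9–15 Hz).

The detector follows the moving-RMS / moving-correlation / relative-power
family of sigma-index algorithms (Lacourse-style).  For each channel, the
signal is filtered into the requested spindle band — slow (9–12 Hz), fast
(12–15 Hz) or overall (9–15 Hz) — and three criteria are evaluated on a
100 ms decision grid:

1. the moving RMS (300 ms window, 100 ms step) of the band-filtered signal
   exceeds its night-level mean + 1.5 SD (computed per channel and per
   stage over that stage's artifact-free bins);
2. the moving Pearson correlation (same window/step) between the broadband
   signal (0.5–40 Hz) and the band-filtered signal exceeds 0.65;
3. the relative sigma power — band power over total 0.5–40 Hz power per
   2 s Hann STFT frame computed every 200 ms — exceeds a per-subject,
   per-stage threshold calibrated on a designated placebo night.

A bin is spindle-positive when at least two of the three criteria hold
simultaneously.  Runs of positive bins become candidates; within-channel
candidates separated by less than 0.3 s are merged; candidates shorter
than 0.5 s or longer than 2 s are discarded; events whose onset epoch is
not N2/N3 are dropped.  Events detected on different channels with onsets
within 500 ms are treated as one spindle, keeping the one with the highest
mean relative power.  Densities are event counts per artifact-free minute
of each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, CalibrationError
from .io_preprocess import (
    Hypnogram,
    Recording,
    design_fir,
    fir_filter,
    stage_artifact_free_seconds,
)

BANDS = {"slow": (9.0, 12.0), "fast": (12.0, 15.0), "overall": (9.0, 15.0)}


@dataclass(frozen=True)
class SpindleParams:
    """All detector constants (defaults are the canonical values)."""

    band: tuple[float, float] = (12.0, 15.0)
    rms_window: float = 0.3          # s
    rms_step: float = 0.1            # s
    rms_k: float = 1.5               # threshold = mean + k*SD
    corr_threshold: float = 0.65
    corr_window: float = 0.3         # s
    corr_step: float = 0.1           # s
    broadband: tuple[float, float] = (0.5, 40.0)
    stft_window: float = 2.0         # s
    stft_step: float = 0.2           # s between successive frame starts
    min_dur: float = 0.5             # s
    max_dur: float = 2.0             # s
    merge_gap: float = 0.3           # s, within-channel candidate merging
    cross_channel_window: float = 0.5  # s

    def __post_init__(self) -> None:
        if not self.min_dur < self.max_dur:
            raise ValueError("min_dur must be below max_dur")
        lo, hi = self.band
        blo, bhi = self.broadband
        if not (blo <= lo < hi <= bhi):
            raise ValueError("spindle band must lie within the broadband range")


@dataclass(frozen=True)
class RelPowerThreshold:
    subject_id: str
    stage: str
    band: tuple[float, float]
    threshold: float

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("relative-power threshold must lie in (0, 1)")


@dataclass
class SpindleEvent:
    channel: str
    start: float
    end: float
    duration: float
    p2p_amplitude: float
    frequency: float
    mean_relative_power: float
    stage: str
    band: str


# ---------------------------------------------------------------------------
# moving statistics
# ---------------------------------------------------------------------------

def _grid(n: int, rate: float, window: float, step: float) -> np.ndarray:
    """Window start times such that the full window fits in the series."""
    last = n / rate - window
    if last < -1e-12:
        return np.zeros(0)
    n_bins = int(np.floor(last / step + 1e-9)) + 1
    return np.arange(n_bins) * step


def _window_bounds(times: np.ndarray, rate: float, window: float,
                   n: int) -> tuple[np.ndarray, np.ndarray]:
    i0 = np.round(times * rate).astype(np.int64)
    i1 = np.minimum(i0 + int(round(window * rate)), n)
    return i0, i1


def moving_rms(series: np.ndarray, rate: float, window: float = 0.3,
               step: float = 0.1, mask: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Moving RMS on a fixed grid; returns (window start times, values).

    Bins with more than half their samples masked are NaN; otherwise the
    RMS is taken over the unmasked samples only.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    times = _grid(n, rate, window, step)
    if times.size == 0:
        return times, np.zeros(0)
    i0, i1 = _window_bounds(times, rate, window, n)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    good = (~mask).astype(float)
    csum_sq = np.concatenate([[0.0], np.cumsum(x * x * good)])
    csum_n = np.concatenate([[0.0], np.cumsum(good)])
    tot = (i1 - i0).astype(float)
    n_good = csum_n[i1] - csum_n[i0]
    ssq = csum_sq[i1] - csum_sq[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.sqrt(ssq / n_good)
    vals[n_good < 0.5 * tot] = np.nan
    vals[n_good == 0] = np.nan
    return times, vals


def moving_correlation(broadband: np.ndarray, band_filtered: np.ndarray,
                       rate: float, window: float = 0.3, step: float = 0.1,
                       mask: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Moving Pearson correlation on the same grid as :func:`moving_rms`.

    Zero-variance windows yield NaN (excluded from the decision logic).
    """
    a = np.asarray(broadband, dtype=float)
    b = np.asarray(band_filtered, dtype=float)
    if a.size != b.size:
        raise AlignmentError("series lengths differ")
    n = a.size
    times = _grid(n, rate, window, step)
    if times.size == 0:
        return times, np.zeros(0)
    i0, i1 = _window_bounds(times, rate, window, n)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    good = (~mask).astype(float)

    def csum(v):
        return np.concatenate([[0.0], np.cumsum(v)])

    ca, cb = csum(a * good), csum(b * good)
    caa, cbb, cab = csum(a * a * good), csum(b * b * good), csum(a * b * good)
    cn = csum(good)
    m = cn[i1] - cn[i0]
    tot = (i1 - i0).astype(float)
    sa = ca[i1] - ca[i0]
    sb = cb[i1] - cb[i0]
    saa = caa[i1] - caa[i0]
    sbb = cbb[i1] - cbb[i0]
    sab = cab[i1] - cab[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sab - sa * sb / m
        va = saa - sa * sa / m
        vb = sbb - sb * sb / m
        r = cov / np.sqrt(va * vb)
    bad = (m < 0.5 * tot) | (m < 2) | ~np.isfinite(r)
    r = np.where(bad, np.nan, r)
    return times, r


def relative_power_series(series: np.ndarray, rate: float,
                          band: tuple[float, float],
                          params: SpindleParams | None = None,
                          mask: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Relative band power per STFT frame (Hann, 2 s window, 200 ms step).

    Each frame's value is the integrated power in ``band`` divided by the
    integrated power in the broadband range; frames that are all-zero or
    more than half masked are NaN.  Timestamps are frame starts.
    """
    if params is None:
        params = SpindleParams(band=band)
    x = np.asarray(series, dtype=float)
    n = x.size
    win = int(round(params.stft_window * rate))
    times = _grid(n, rate, params.stft_window, params.stft_step)
    if times.size == 0:
        return times, np.zeros(0)
    i0, _ = _window_bounds(times, rate, params.stft_window, n)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    window = np.hanning(win)
    freqs = np.fft.rfftfreq(win, 1.0 / rate)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    blo, bhi = params.broadband
    in_total = (freqs >= blo) & (freqs <= bhi)
    vals = np.full(times.size, np.nan)
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[i0]
    mask_frames = np.lib.stride_tricks.sliding_window_view(mask, win)[i0]
    spec = np.abs(np.fft.rfft(frames * window, axis=1)) ** 2
    band_p = spec[:, in_band].sum(axis=1)
    total_p = spec[:, in_total].sum(axis=1)
    ok = (mask_frames.mean(axis=1) <= 0.5) & (total_p > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = band_p / total_p
    vals[ok] = ratio[ok]
    return times, vals


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_relpower_threshold(recording: Recording, hypnogram: Hypnogram,
                                 band: tuple[float, float],
                                 params: SpindleParams | None = None,
                                 min_stage_minutes: float = 5.0
                                 ) -> dict[str, RelPowerThreshold]:
    """Per-stage relative-power thresholds from a designated placebo night.

    The threshold for a stage is the mean relative power over that stage's
    artifact-free STFT frames, averaged across channels.  Raises
    :class:`CalibrationError` if the recording is not flagged as a
    calibration night or a stage has under ``min_stage_minutes`` of
    artifact-free data.
    """
    if params is None:
        params = SpindleParams(band=band)
    if not recording.meta.is_calibration_night:
        raise CalibrationError(
            "recording is not a calibration night; supply explicit "
            "relative-power thresholds instead")
    free = stage_artifact_free_seconds(recording, hypnogram)
    out: dict[str, RelPowerThreshold] = {}
    for stage in ("N2", "N3"):
        if free[stage] < min_stage_minutes * 60.0:
            raise CalibrationError(
                f"stage {stage} has only {free[stage] / 60:.1f} artifact-free "
                f"minutes (< {min_stage_minutes})")
        channel_means = []
        for lab in recording.channel_labels:
            mask = recording.artifact_mask(lab)
            t, v = relative_power_series(recording.channels[lab],
                                         recording.sampling_rate, band,
                                         params, mask)
            frame_stage = np.array([hypnogram.stage_at(tt) for tt in t])
            sel = (frame_stage == stage) & np.isfinite(v)
            if sel.any():
                channel_means.append(float(np.mean(v[sel])))
        if not channel_means:
            raise CalibrationError(f"no usable frames in stage {stage}")
        out[stage] = RelPowerThreshold(
            subject_id=recording.meta.subject_id, stage=stage, band=band,
            threshold=float(np.mean(channel_means)))
    return out


# ---------------------------------------------------------------------------
# decision logic
# ---------------------------------------------------------------------------

def hold_previous(grid_times: np.ndarray, frame_times: np.ndarray,
                  frame_values: np.ndarray) -> np.ndarray:
    """Previous-value hold of a coarse series onto a finer grid.

    Grid points before the first frame are NaN.
    """
    out = np.full(grid_times.size, np.nan)
    if frame_times.size == 0:
        return out
    idx = np.searchsorted(frame_times, grid_times + 1e-9, side="right") - 1
    ok = idx >= 0
    out[ok] = frame_values[idx[ok]]
    return out


def decide_candidates(rms_times: np.ndarray, rms_values: np.ndarray,
                      corr_values: np.ndarray,
                      relpower_held: np.ndarray,
                      rms_threshold: np.ndarray | float,
                      relpower_thresholds: np.ndarray | float,
                      params: SpindleParams,
                      allowed: np.ndarray | None = None
                      ) -> list[tuple[float, float]]:
    """Two-of-three voting on the 100 ms decision grid.

    ``rms_threshold`` and ``relpower_thresholds`` may each be a scalar or
    a per-bin array (the thresholds depend on the stage of each bin).  ``allowed`` restricts
    detection to bins whose window start lies in N2/N3.  NaN criteria
    count as not met.  Maximal runs of positive bins become candidate
    intervals ``[first bin start, last bin start + step)``.
    """
    step = params.rms_step
    with np.errstate(invalid="ignore"):
        c1 = rms_values > rms_threshold
        c2 = corr_values > params.corr_threshold
        c3 = relpower_held > relpower_thresholds
    votes = c1.astype(int) + c2.astype(int) + c3.astype(int)
    positive = votes >= 2
    if allowed is not None:
        positive &= allowed
    candidates: list[tuple[float, float]] = []
    in_run = False
    start = 0.0
    for i, p in enumerate(positive):
        if p and not in_run:
            in_run, start = True, rms_times[i]
        elif not p and in_run:
            in_run = False
            candidates.append((start, rms_times[i - 1] + step))
    if in_run:
        candidates.append((start, rms_times[-1] + step))
    return candidates


def merge_candidates(candidates: list[tuple[float, float]],
                     gap: float) -> list[tuple[float, float]]:
    """Merge same-channel candidates separated by less than ``gap`` seconds."""
    if not candidates:
        return []
    merged = [candidates[0]]
    for s, e in candidates[1:]:
        if s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def finalize_events(candidates: list[tuple[float, float]],
                    band_filtered: np.ndarray, rate: float,
                    relpower_grid_times: np.ndarray,
                    relpower_held: np.ndarray,
                    params: SpindleParams, hypnogram: Hypnogram,
                    channel: str, band_name: str) -> list[SpindleEvent]:
    """Gap-merge, duration-gate and characterise candidates.

    Frequency is estimated from the zero-crossing count of the
    band-filtered segment; amplitude is its peak-to-peak range.
    """
    merged = merge_candidates(sorted(candidates), params.merge_gap)
    events: list[SpindleEvent] = []
    for s, e in merged:
        dur = e - s
        if not params.min_dur <= dur <= params.max_dur:
            continue
        stage = hypnogram.stage_at(s)
        if stage not in ("N2", "N3"):
            continue
        i0 = int(round(s * rate))
        i1 = min(int(round(e * rate)), band_filtered.size)
        seg = band_filtered[i0:i1]
        if seg.size < 2:
            continue
        p2p = float(np.max(seg) - np.min(seg))
        crossings = int(np.sum(np.abs(np.diff(np.signbit(seg)))))
        freq = crossings / (2.0 * dur)
        sel = (relpower_grid_times >= s) & (relpower_grid_times < e)
        rp = relpower_held[sel]
        rp = rp[np.isfinite(rp)]
        mean_rp = float(np.mean(rp)) if rp.size else float("nan")
        events.append(SpindleEvent(channel=channel, start=s, end=e,
                                   duration=dur, p2p_amplitude=p2p,
                                   frequency=freq, mean_relative_power=mean_rp,
                                   stage=stage, band=band_name))
    return events


def deduplicate_across_channels(events: list[SpindleEvent],
                                window: float = 0.5) -> list[SpindleEvent]:
    """Collapse near-simultaneous events on different channels.

    Events on different channels with onsets within ``window`` seconds form
    one group (transitive closure); the member with the highest mean
    relative power survives, ties broken by earliest onset.
    """
    evs = sorted(events, key=lambda ev: (ev.start, ev.channel))
    n = len(evs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if evs[j].start - evs[i].start >= window:
                break
            if evs[j].channel != evs[i].channel:
                union(i, j)
    groups: dict[int, list[SpindleEvent]] = {}
    for i, ev in enumerate(evs):
        groups.setdefault(find(i), []).append(ev)
    survivors = []
    for members in groups.values():
        def key(ev):
            rp = ev.mean_relative_power
            return (-(rp if np.isfinite(rp) else -np.inf), ev.start)
        survivors.append(min(members, key=key))
    return sorted(survivors, key=lambda ev: ev.start)


def spindle_density(events: list[SpindleEvent], hypnogram: Hypnogram,
                    stage_free_seconds: dict[str, float]) -> pd.DataFrame:
    """Events per artifact-free minute, per (stage, channel) and pooled.

    Cells whose stage has zero artifact-free time are reported as missing
    (NaN), not zero.
    """
    rows = []
    channels = sorted({ev.channel for ev in events}) or []
    for stage in ("N2", "N3"):
        minutes = stage_free_seconds.get(stage, 0.0) / 60.0
        for ch in channels:
            count = sum(1 for ev in events if ev.stage == stage and ev.channel == ch)
            rows.append({"stage": stage, "channel": ch,
                         "density": count / minutes if minutes > 0 else np.nan})
        pooled = sum(1 for ev in events if ev.stage == stage)
        rows.append({"stage": stage, "channel": "pooled",
                     "density": pooled / minutes if minutes > 0 else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def detect_spindles(recording: Recording, hypnogram: Hypnogram,
                    band: tuple[float, float],
                    thresholds: dict[str, float],
                    params: SpindleParams | None = None,
                    band_name: str | None = None
                    ) -> tuple[list[SpindleEvent], pd.DataFrame]:
    """Detect spindles in one band across all channels of a recording.

    ``thresholds`` maps stage ("N2"/"N3") to the calibrated relative-power
    threshold.  Returns the cross-channel-deduplicated event list and a
    density table (per-channel densities use pre-deduplication events; the
    pooled rows use post-deduplication counts).
    """
    if params is None:
        params = SpindleParams(band=band)
    if band_name is None:
        band_name = next((k for k, v in BANDS.items() if v == tuple(band)), "custom")
    rate = recording.sampling_rate
    band_taps = design_fir(band[0], band[1], rate, transition=1.0)
    broad_taps = design_fir(params.broadband[0], params.broadband[1], rate)

    all_events: list[SpindleEvent] = []
    for lab in recording.channel_labels:
        x = recording.channels[lab]
        mask = recording.artifact_mask(lab)
        xb = fir_filter(x, band_taps)
        xw = fir_filter(x, broad_taps)
        t_rms, v_rms = moving_rms(xb, rate, params.rms_window, params.rms_step, mask)
        _, v_corr = moving_correlation(xw, xb, rate, params.corr_window,
                                       params.corr_step, mask)
        t_rel, v_rel = relative_power_series(x, rate, band, params, mask)
        held = hold_previous(t_rms, t_rel, v_rel)

        bin_stage = np.array([hypnogram.stage_at(t) or "" for t in t_rms])
        allowed = (bin_stage == "N2") | (bin_stage == "N3")
        rel_thr = np.full(t_rms.size, np.inf)
        for stage, thr in thresholds.items():
            rel_thr[bin_stage == stage] = thr

        # RMS statistics are computed per stage: the background amplitude
        # differs between N2 and N3, and a pooled threshold would trade
        # N3 false positives against N2 sensitivity
        rms_thr = np.full(t_rms.size, np.inf)
        for stage in ("N2", "N3"):
            sel = (bin_stage == stage) & np.isfinite(v_rms)
            if sel.sum() >= 2:
                rms_thr[bin_stage == stage] = (
                    np.nanmean(v_rms[sel])
                    + params.rms_k * np.nanstd(v_rms[sel]))
        cands = decide_candidates(t_rms, v_rms, v_corr, held, rms_thr,
                                  rel_thr, params, allowed)
        all_events.extend(finalize_events(cands, xb, rate, t_rms, held,
                                          params, hypnogram, lab, band_name))

    per_channel = list(all_events)
    deduped = deduplicate_across_channels(all_events, params.cross_channel_window)
    free = stage_artifact_free_seconds(recording, hypnogram)
    density = spindle_density(deduped, hypnogram, free)
    # per-channel rows from pre-dedup events, pooled rows from post-dedup
    per_ch_density = spindle_density(per_channel, hypnogram, free)
    density = pd.concat([
        per_ch_density[per_ch_density["channel"] != "pooled"],
        density[density["channel"] == "pooled"],
    ], ignore_index=True)
    return deduped, density


def detect_all_bands(recording: Recording, hypnogram: Hypnogram,
                     thresholds: dict[str, dict[str, float]],
                     params_by_band: dict[str, SpindleParams] | None = None
                     ) -> dict[str, tuple[list[SpindleEvent], pd.DataFrame]]:
    """Run the detector for the slow, fast and overall bands.

    ``thresholds`` maps band name to its per-stage relative-power
    thresholds.
    """
    out = {}
    for name, band in BANDS.items():
        params = (params_by_band or {}).get(name) or SpindleParams(band=band)
        out[name] = detect_spindles(recording, hypnogram, band,
                                    thresholds[name], params, band_name=name)
    return out
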