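"""Welch power-spectral-density estimation and band-power integration.

PSDs use Welch's method with 8 s Hann-windowed segments at 50% overlap,
density scaling (µV²/Hz) so that the integral over all frequencies equals
the signal variance (Parseval).  Band powers are trapezoidal integrals
over the four bands of interest: slow waves 0.5–3.5 Hz, slow spindles
9–12 Hz, fast spindles 12–15 Hz, overall spindles 9–15 Hz.  Segments
never span artifact-masked samples or sleep-stage boundaries; unmasked
runs shorter than one segment are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import InsufficientDataError, ParameterError
from .io_preprocess import Hypnogram, Recording

POWER_BANDS = {
    "sw": (0.5, 3.5),
    "slow": (9.0, 12.0),
    "fast": (12.0, 15.0),
    "overall": (9.0, 15.0),
}


@dataclass
class PSDEstimate:
    frequencies: np.ndarray       # Hz
    power: np.ndarray             # µV²/Hz
    segment_length: float = 8.0   # s
    overlap: float = 0.5          # fraction
    window: str = "hann"
    n_segments: int = 0


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal unmasked runs as (start, end) index pairs."""
    good = ~mask
    if not good.any():
        return []
    runs = []
    idx = np.flatnonzero(good)
    splits = np.flatnonzero(np.diff(idx) > 1)
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    return runs


def welch_psd(series: np.ndarray, rate: float,
              mask: np.ndarray | None = None,
              segment_length: float = 8.0, overlap: float = 0.5
              ) -> PSDEstimate:
    """Welch PSD over the valid (unmasked) runs of a series.

    Each run contributes ``1 + floor((len - nperseg)/hop)`` segments; the
    returned PSD is the segment-count-weighted mean across runs.  Raises
    :class:`InsufficientDataError` when no run holds one full segment.
    """
    x = np.asarray(series, dtype=float)
    nperseg = int(round(segment_length * rate))
    noverlap = int(round(nperseg * overlap))
    hop = nperseg - noverlap
    if mask is None:
        runs = [(0, x.size)] if x.size else []
    else:
        runs = _runs_from_mask(np.asarray(mask, dtype=bool))
    acc = None
    total_segments = 0
    freqs = None
    for s, e in runs:
        if e - s < nperseg:
            continue
        f, p = sp_signal.welch(x[s:e], fs=rate, window="hann",
                               nperseg=nperseg, noverlap=noverlap,
                               detrend="constant", scaling="density")
        nseg = 1 + (e - s - nperseg) // hop
        acc = p * nseg if acc is None else acc + p * nseg
        total_segments += nseg
        freqs = f
    if total_segments == 0:
        raise InsufficientDataError(
            f"no unmasked run holds one full {segment_length} s segment")
    return PSDEstimate(frequencies=freqs, power=acc / total_segments,
                       segment_length=segment_length, overlap=overlap,
                       n_segments=total_segments)


def band_power(psd: PSDEstimate, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over ``band`` (µV²)."""
    lo, hi = band
    if not lo < hi:
        raise ParameterError(f"inverted band ({lo}, {hi})")
    f = psd.frequencies
    if lo < f[0] - 1e-9 or hi > f[-1] + 1e-9:
        raise ParameterError("band outside the frequency grid")
    sel = (f >= lo - 1e-12) & (f <= hi + 1e-12)
    return float(np.trapezoid(psd.power[sel], f[sel]))


def stage_band_powers(recording: Recording, hypnogram: Hypnogram,
                      bands: dict[str, tuple[float, float]] | None = None,
                      sw_channel: str = "C3-A2") -> pd.DataFrame:
    """Band-power table per (stage, band).

    Spindle-band powers are computed per channel over the valid runs of
    each stage (N2 and N3 separately) and averaged across channels; the
    slow-wave band uses only ``sw_channel`` in N3.  Cells with
    insufficient data are absent from the table.
    """
    if bands is None:
        bands = POWER_BANDS
    rate = recording.sampling_rate
    stages = hypnogram.sample_stages(rate, recording.n_samples)
    rows = []
    for stage in ("N2", "N3"):
        stage_mask = stages != stage  # True = excluded
        psds: dict[str, PSDEstimate] = {}
        for lab in recording.channel_labels:
            mask = stage_mask | recording.artifact_mask(lab)
            try:
                psds[lab] = welch_psd(recording.channels[lab], rate, mask)
            except InsufficientDataError:
                continue
        for name, band in bands.items():
            if name == "sw":
                if stage != "N3" or sw_channel not in psds:
                    continue
                power = band_power(psds[sw_channel], band)
            else:
                vals = [band_power(p, band) for p in psds.values()]
                if not vals:
                    continue
                power = float(np.mean(vals))
            rows.append({"stage": stage, "band": name, "power": power})
    return pd.DataFrame(rows)
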