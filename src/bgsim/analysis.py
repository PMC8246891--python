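"""Rate, variability and spectral summaries of spike records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from . import params as P
from .simulate import SpikeRecord

#: frequency bands (Hz) whose power maxima are extracted from spectra
BANDS = {"delta": (2.0, 4.0), "alpha": (8.0, 12.0),
         "beta": (12.0, 35.0), "gamma": (35.0, 128.0)}


def population_rate(record: SpikeRecord, nucleus: str,
                    channel: int | None = None,
                    window: tuple | None = None) -> float:
    """Mean firing rate in Hz: total spikes / (neurons x window length).

    The default window is the post-warm-up analysis window of the record.
    """
    members = record.population_ids(nucleus, channel)
    if members.size == 0:
        raise ValueError(f"no neurons in population {nucleus} channel {channel}")
    if window is None:
        window = (record.warmup_ms, record.duration_ms)
    t0, t1 = window
    if not record.warmup_ms <= t0 < t1 <= record.duration_ms + 1e-9:
        if not 0 <= t0 < t1 <= record.duration_ms + 1e-9:
            raise ValueError("window outside the recorded interval")
    mask = np.isin(record.ids, members) & (record.times >= t0) & (record.times < t1)
    n_spikes = int(np.count_nonzero(mask))
    return n_spikes / (members.size * (t1 - t0) / 1000.0)


def per_neuron_rates(record: SpikeRecord, nucleus: str,
                     channel: int | None = None) -> np.ndarray:
    members = record.population_ids(nucleus, channel)
    ids, _ = record.spikes_of(nucleus, channel)
    counts = np.bincount(ids, minlength=record.nucleus_of.size)[members]
    return counts / (record.window_ms / 1000.0)


def cv_isi(times: np.ndarray) -> float:
    """Coefficient of variation of the inter-spike intervals (>= 3 spikes)."""
    if times.size < 3:
        return np.nan
    isi = np.diff(np.sort(times))
    mean = isi.mean()
    return float(isi.std() / mean) if mean > 0 else np.nan


def cv_distribution(record: SpikeRecord, nucleus: str,
                    channel: int | None = None) -> pd.DataFrame:
    """Per-neuron ISI CV; neurons with 2 spikes or fewer are flagged excluded."""
    members = record.population_ids(nucleus, channel)
    ids, times = record.spikes_of(nucleus, channel)
    rows = []
    for m in members:
        t = times[ids == m]
        rows.append({
            "neuron_id": int(m),
            "n_spikes": int(t.size),
            "cv": cv_isi(t),
            "excluded": t.size <= 2,
        })
    return pd.DataFrame(rows)


@dataclass
class SpectrumSummary:
    """Power spectrum of the summed population spike-count series."""

    frequency: np.ndarray   # Hz
    power: np.ndarray
    band_peaks: dict = field(default_factory=dict)  # band -> (freq, power)

    def to_csv(self, path) -> None:
        pd.DataFrame({"frequency_hz": self.frequency,
                      "power": self.power}).to_csv(path, index=False)


def power_spectrum(record: SpikeRecord, nucleus: str,
                   channel: int | None = None,
                   bin_ms: float = 1.0, duration_ms: float = 10000.0) -> SpectrumSummary:
    """FFT power spectrum of the binned population spiking activity.

    Counts are summed over the population in ``bin_ms`` bins over the first
    ``duration_ms`` of the analysis window, mean-subtracted, and transformed
    with a single plain FFT window (no tapering).  The per-band peak is the
    maximum power sample strictly inside each closed band interval, with ties
    resolved toward the lowest frequency.
    """
    if record.window_ms + 1e-9 < duration_ms:
        raise ValueError("record shorter than the requested spectrum duration")
    t0 = record.warmup_ms
    _, times = record.spikes_of(nucleus, channel)
    times = times[times < t0 + duration_ms]
    n_bins = int(round(duration_ms / bin_ms))
    counts, _ = np.histogram(times, bins=n_bins, range=(t0, t0 + duration_ms))

    fs = 1000.0 / bin_ms
    freq, power = periodogram(counts.astype(float), fs=fs, window="boxcar",
                              detrend="constant")
    peaks = {}
    for band, (lo, hi) in BANDS.items():
        mask = (freq >= lo) & (freq <= hi)
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        best = idx[np.argmax(power[idx])]  # argmax returns the first maximum
        peaks[band] = (float(freq[best]), float(power[best]))
    return SpectrumSummary(frequency=freq, power=power, band_peaks=peaks)


def rate_table(record: SpikeRecord, by_channel: bool = False) -> pd.DataFrame:
    """Mean rate per nucleus (optionally per channel) in the analysis window."""
    rows = []
    channels = range(int(record.channel_of.max()) + 1) if by_channel else [None]
    for nucleus in P.NUCLEI:
        for ch in channels:
            rows.append({
                "nucleus": nucleus,
                "channel": ch if ch is not None else "all",
                "rate_hz": population_rate(record, nucleus, ch),
            })
    return pd.DataFrame(rows)
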