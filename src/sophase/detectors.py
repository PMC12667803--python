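"""Spindle and slow-wave event detection on masked N2/N3 EEG.

Two spindle detectors share a wavelet-power pathway (complex Morlet power
averaged over 11-16 Hz, smoothed with a 100 ms moving average):

* the primary detector z-scores the smoothed power over usable samples and
  keeps maximal runs with z > 2 lasting >= 300 ms whose within-run maximum
  exceeds 3;
* the alternative detector applies a fixed amplitude criterion instead — a
  configurable multiple (default 4.5x) of the mean smoothed power over usable
  samples — with the same 300 ms duration rule and no z-scoring, making it
  the more stringent of the two on typical signals.

Slow waves are negative half-waves of the zero-phase 0.5-4 Hz filtered
signal bounded by consecutive down-going and up-going zero crossings 0.25-1 s
apart whose Hilbert-envelope peak exceeds the 75th percentile of the
absolute filtered signal over all usable samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

from .errors import DegenerateSignalError
from .types import Recording, SPINDLE_COLUMNS, SW_COLUMNS, empty_events

logger = logging.getLogger(__name__)

SPINDLE_BAND = (11.0, 16.0)
SW_FILTER_BAND = (0.5, 4.0)


def spindle_band_power(x: np.ndarray, fs: float,
                       band: tuple[float, float] = SPINDLE_BAND,
                       freq_step: float = 0.5, n_cycles: float = 4.0,
                       smooth_ms: float = 100.0) -> np.ndarray:
    """Smoothed Morlet wavelet power of one channel in the spindle band.

    Power is averaged over center frequencies ``band[0]:freq_step:band[1]``
    and smoothed with a ``smooth_ms`` moving average. The default 4-cycle
    wavelet keeps the temporal FWHM (~0.12 s at 13 Hz) well below the 300 ms
    duration criterion, so measured event durations reflect the burst, not
    the wavelet's own support; wider wavelets smear strong sub-criterion
    bursts into qualifying runs.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.arange(band[0], band[1] + freq_step / 2, freq_step)
    power = tfr_array_morlet(x[None, None, :], float(fs), freqs,
                             n_cycles=n_cycles, output="power",
                             verbose="error")[0, 0]
    mean_power = power.mean(axis=0)
    win = max(1, int(round(smooth_ms / 1000.0 * fs)))
    return uniform_filter1d(mean_power, size=win, mode="nearest")


def _runs_above(above: np.ndarray):
    padded = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    return zip(np.flatnonzero(padded == 1), np.flatnonzero(padded == -1))


def _merge_runs(runs, max_gap: int):
    """Merge supra-threshold runs separated by less than ``max_gap`` samples."""
    merged = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < max_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return merged


def _detect_band_events(rec: Recording, usable: np.ndarray | None, *,
                        score_fn, min_dur: float, max_dur: float,
                        merge_gap_ms: float, detector_id: str) -> pd.DataFrame:
    """Shared run-finding machinery for both spindle detectors."""
    fs = rec.fs
    # closed-interval span: end_s - start_s = (stop-1-start)/fs must reach min_dur
    min_samp = int(np.ceil(min_dur * fs)) + 1
    max_samp = int(round(max_dur * fs))
    gap = int(round(merge_gap_ms / 1000.0 * fs))
    rows = []
    for ci, ch in enumerate(rec.channel_labels):
        ok = np.ones(rec.n_samples, dtype=bool) if usable is None else usable[ci]
        if not ok.any():
            continue
        score, threshold, peak_floor = score_fn(rec.data[ci], fs, ok)
        runs = _merge_runs(_runs_above(score > threshold), gap)
        for start, stop in runs:
            if stop - start < min_samp:
                continue
            if stop - start > max_samp:
                logger.info("%s: %s event at %.1fs exceeds %.1fs cap; dropped",
                            detector_id, ch, start / fs, max_dur)
                continue
            seg = score[start:stop]
            if peak_floor is not None and seg.max() <= peak_floor:
                continue
            if not ok[start:stop].all():
                continue
            peak = start + int(np.argmax(seg))
            rows.append((ch, start / fs, (stop - 1) / fs, peak / fs,
                         float(seg.max()), detector_id))
    if not rows:
        return empty_events(SPINDLE_COLUMNS)
    return pd.DataFrame(rows, columns=SPINDLE_COLUMNS)


def detect_spindles(rec: Recording, usable: np.ndarray | None = None, *,
                    band: tuple[float, float] = SPINDLE_BAND,
                    z_threshold: float = 2.0, z_peak: float = 3.0,
                    min_dur: float = 0.3, max_dur: float = 3.0,
                    merge_gap_ms: float = 100.0) -> pd.DataFrame:
    """Primary z-score spindle detector.

    The smoothed spindle-band power is z-scored over usable samples; events
    are runs with z > ``z_threshold`` lasting >= ``min_dur`` whose maximum z
    exceeds ``z_peak``. Events touching any unusable sample are discarded,
    and ``peak_s`` is the time of maximum smoothed z within the event.
    """
    def score_fn(x, fs, ok):
        power = spindle_band_power(x, fs, band)
        mu, sd = power[ok].mean(), power[ok].std()
        if sd == 0:
            raise DegenerateSignalError("zero-variance usable signal; z undefined")
        return (power - mu) / sd, z_threshold, z_peak

    return _detect_band_events(rec, usable, score_fn=score_fn,
                               min_dur=min_dur, max_dur=max_dur,
                               merge_gap_ms=merge_gap_ms, detector_id="zscore")


def detect_spindles_alt(rec: Recording, usable: np.ndarray | None = None, *,
                        band: tuple[float, float] = SPINDLE_BAND,
                        threshold_multiple: float = 4.5,
                        min_dur: float = 0.3, max_dur: float = 3.0,
                        merge_gap_ms: float = 100.0) -> pd.DataFrame:
    """Alternative fixed-amplitude spindle detector (no z-scoring).

    Threshold = ``threshold_multiple`` times the mean smoothed spindle-band
    power over usable samples.
    """
    def score_fn(x, fs, ok):
        power = spindle_band_power(x, fs, band)
        mean = power[ok].mean()
        if mean == 0:
            raise DegenerateSignalError("zero usable spindle-band power")
        return power, threshold_multiple * mean, None

    return _detect_band_events(rec, usable, score_fn=score_fn,
                               min_dur=min_dur, max_dur=max_dur,
                               merge_gap_ms=merge_gap_ms, detector_id="alt")


def detect_slow_waves(rec: Recording, usable: np.ndarray | None = None, *,
                      filter_band: tuple[float, float] = SW_FILTER_BAND,
                      min_half_wave: float = 0.25, max_half_wave: float = 1.0,
                      envelope_percentile: float = 75.0) -> pd.DataFrame:
    """Detect discrete slow-wave events as qualifying negative half-waves.

    On each channel's zero-phase 0.5-4 Hz filtered signal, a candidate is
    the span between a down-going zero crossing and the next up-going one
    (half-wave duration 0.25-1.0 s, i.e. a 0.5-2 Hz wave). Candidates are
    kept when the Hilbert-envelope maximum inside the half-wave exceeds the
    75th percentile of the absolute filtered signal over all usable samples
    of that channel (an amplitude percentile: the envelope is compared
    against a magnitude, so the signed signal values are rectified first).
    Candidates touching unusable samples are discarded.
    """
    fs = rec.fs
    sos = butter(4, filter_band, btype="bandpass", fs=fs, output="sos")
    rows = []
    for ci, ch in enumerate(rec.channel_labels):
        ok = np.ones(rec.n_samples, dtype=bool) if usable is None else usable[ci]
        if not ok.any():
            continue
        filt = sosfiltfilt(sos, rec.data[ci])
        env = np.abs(hilbert(filt))
        thresh = np.percentile(np.abs(filt[ok]), envelope_percentile)
        sign = np.sign(filt)
        # down-going: + -> non-positive; up-going: - -> non-negative
        down = np.flatnonzero((sign[:-1] > 0) & (sign[1:] <= 0)) + 1
        up = np.flatnonzero((sign[:-1] < 0) & (sign[1:] >= 0)) + 1
        ui = 0
        for d in down:
            while ui < up.size and up[ui] <= d:
                ui += 1
            if ui >= up.size:
                break
            u = up[ui]
            dur = (u - d) / fs
            if not (min_half_wave <= dur <= max_half_wave):
                continue
            if not ok[d:u + 1].all():
                continue
            seg_env = env[d:u]
            if not seg_env.max() > thresh:
                continue
            trough = d + int(np.argmin(filt[d:u]))
            rows.append((ch, d / fs, u / fs, trough / fs, float(seg_env.max())))
    if not rows:
        if usable is not None and not usable.any():
            logger.warning("no usable samples; empty slow-wave list")
        return empty_events(SW_COLUMNS)
    return pd.DataFrame(rows, columns=SW_COLUMNS)
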