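"""Slow-oscillation phase at spindle peaks, and per-channel circular statistics.

The SO is treated as a continuous signal: each channel is zero-phase
bandpass filtered in the SO band (0.5-2 Hz) and the instantaneous phase is
the argument of its analytic (Hilbert) signal. Phase 0 therefore falls at
positive peaks of the filtered SO, pi at troughs, and -pi/2 at up-going zero
crossings. When a per-sample usability mask is supplied the analytic signal
is computed on each contiguous usable segment independently — no
interpolation across artifacts or wake — and samples within ``edge_s``
seconds of a segment edge are flagged unreliable (Hilbert edge effects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .errors import UndefinedStatisticError
from .precession import DEFAULT_POSITION_MAP
from .types import PHASE_COLUMNS, Recording, wrap_phase

logger = logging.getLogger(__name__)

SO_BAND = (0.5, 2.0)


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    return butter(order, band, btype="bandpass", fs=fs, output="sos")


def _usable_segments(usable: np.ndarray):
    """Start/stop index pairs of contiguous True runs."""
    padded = np.diff(np.concatenate(([0], usable.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return zip(starts, stops)


def so_phase_series(rec: Recording, band: tuple[float, float] = SO_BAND,
                    usable: np.ndarray | None = None,
                    edge_s: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous SO phase per channel.

    Parameters
    ----------
    rec : Recording
        Standardized recording.
    band : (low, high)
        SO band in Hz; zero-phase 4th-order Butterworth.
    usable : bool ndarray (n_channels, n_samples), optional
        True where the sample may be analyzed; the analytic signal is
        computed per contiguous usable segment.
    edge_s : float
        Samples within this margin of a segment (or recording) edge are
        marked unreliable.

    Returns
    -------
    phase : ndarray (n_channels, n_samples)
        Phase in (-pi, pi]; NaN outside usable segments.
    valid : bool ndarray (n_channels, n_samples)
        True where the phase is reliable (usable and away from edges).
    """
    sos = _bandpass_sos(band, rec.fs)
    edge = int(round(edge_s * rec.fs))
    min_len = max(2 * edge + 1, int(round(2 * rec.fs / band[0])))

    phase = np.full(rec.data.shape, np.nan)
    valid = np.zeros(rec.data.shape, dtype=bool)
    for ci in range(rec.n_channels):
        if usable is None:
            segments = [(0, rec.n_samples)]
        else:
            segments = list(_usable_segments(usable[ci]))
        for start, stop in segments:
            if stop - start < min_len:
                continue
            filt = sosfiltfilt(sos, rec.data[ci, start:stop])
            phase[ci, start:stop] = np.angle(hilbert(filt))
            valid[ci, start + edge: stop - edge] = True
    return phase, valid


def phases_at_spindles(phase: np.ndarray, valid: np.ndarray, fs: float,
                       spindles: pd.DataFrame, channel_labels: list[str],
                       subject_id: str = "S", *,
                       sw_events: pd.DataFrame | None = None,
                       sw_margin_half_waves: float = 1.0,
                       pos_map: Mapping[str, float] | None = None) -> pd.DataFrame:
    """One phase sample per spindle, read at the spindle peak.

    If ``sw_events`` is given (sensitivity mode) only spindles co-occurring
    with a detected slow wave on the same channel are kept and tagged
    ``source="SW_event"``; otherwise every spindle with a reliable phase
    contributes with ``source="continuous_SO"``.

    Co-occurrence means the spindle peak lies within the SW's negative
    half-wave extended by ``sw_margin_half_waves`` half-wave durations on
    each side. The default margin of 1 spans the full slow-wave cycle around
    the detected trough, including the adjacent positive peaks where
    spindles preferentially occur; a margin of 0 restricts to the negative
    half-wave itself, which amputates the phase distribution to the
    trough-facing arc and systematically distorts phase-position fits.
    """
    pos_map = DEFAULT_POSITION_MAP if pos_map is None else pos_map
    rows = []
    n_samples = phase.shape[1]
    for _, ev in spindles.iterrows():
        ch = ev["channel"]
        ci = channel_labels.index(ch)
        idx = int(round(ev["peak_s"] * fs))
        if not 0 <= idx < n_samples:
            logger.info("spindle peak %.2fs outside recording; skipped", ev["peak_s"])
            continue
        if not valid[ci, idx]:
            continue
        source = "continuous_SO"
        if sw_events is not None:
            on_ch = sw_events[sw_events["channel"] == ch]
            margin = sw_margin_half_waves * (on_ch["up_zc_s"] - on_ch["down_zc_s"])
            inside = ((on_ch["down_zc_s"] - margin <= ev["peak_s"])
                      & (ev["peak_s"] <= on_ch["up_zc_s"] + margin)).any()
            if not inside:
                continue
            source = "SW_event"
        from .precession import position_for_label
        try:
            pos = position_for_label(ch, pos_map)
        except KeyError:
            pos = np.nan
        rows.append((subject_id, ch, pos, wrap_phase(float(phase[ci, idx])),
                     float(ev["peak_s"]), source))
    return pd.DataFrame(rows, columns=PHASE_COLUMNS)


def rayleigh_test(phases: np.ndarray, *, method: str = "approx",
                  n_sim: int = 10000, rng: np.random.Generator | None = None
                  ) -> float:
    """Rayleigh test of circular uniformity; returns the p-value.

    ``method="approx"`` uses the standard small-sample series around
    exp(-Z), Z = n R^2:

        p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    ``method="montecarlo"`` simulates the null resultant length instead.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        raise UndefinedStatisticError("Rayleigh test on empty sample")
    R = np.abs(np.exp(1j * phases).mean())
    Z = n * R * R
    if method == "approx":
        p = np.exp(-Z) * (1 + (2 * Z - Z**2) / (4 * n)
                          - (24 * Z - 132 * Z**2 + 76 * Z**3 - 9 * Z**4) / (288 * n**2))
        return float(np.clip(p, np.finfo(float).tiny, 1.0))
    if method == "montecarlo":
        rng = np.random.default_rng(0) if rng is None else rng
        null = np.abs(np.exp(1j * rng.uniform(-np.pi, np.pi, (n_sim, n))).mean(axis=1))
        return float((np.sum(null >= R) + 1) / (n_sim + 1))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ChannelPhaseStats:
    """Circular summary of one channel's spindle SO phases."""

    channel: str
    n: int
    mean_phase: float      # NaN when the resultant vanishes (mean undefined)
    resultant_R: float
    rayleigh_p: float

    @property
    def significant(self) -> bool:
        return bool(self.rayleigh_p < 0.05)


def channel_phase_stats(phases: np.ndarray, channel: str = "",
                        rayleigh_method: str = "approx") -> ChannelPhaseStats:
    """Mean phase, resultant length and Rayleigh p for one channel's phases."""
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        raise UndefinedStatisticError("no phases for channel stats")
    vec = np.exp(1j * phases).mean()
    R = float(np.abs(vec))
    mean_phase = float(np.angle(vec)) if R > 1e-12 else float("nan")
    p = rayleigh_test(phases, method=rayleigh_method)
    return ChannelPhaseStats(channel, int(n), mean_phase, R, p)


def channel_stats_table(samples: pd.DataFrame,
                        rayleigh_method: str = "approx") -> pd.DataFrame:
    """Per (subject, channel) circular stats table for the group-level fit.

    Columns: subject_id, channel, position, n, mean_phase, resultant_R,
    rayleigh_p.
    """
    rows = []
    for (sid, ch), grp in samples.groupby(["subject_id", "channel"], sort=True):
        st = channel_phase_stats(grp["phase"].to_numpy(), channel=ch,
                                 rayleigh_method=rayleigh_method)
        rows.append((sid, ch, float(grp["position"].iloc[0]), st.n,
                     st.mean_phase, st.resultant_R, st.rayleigh_p))
    return pd.DataFrame(rows, columns=["subject_id", "channel", "position", "n",
                                       "mean_phase", "resultant_R", "rayleigh_p"])
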