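"""Synthetic NREM-sleep EEG with imposed spindle-SO phase precession.

Two generators with a shared statistical model:

* :func:`generate_phase_dataset` draws spindle SO phases directly — one von
  Mises sample per event around a channel-specific preferred phase
  ``phase0 + slope_true * position`` — exercising the circular-statistics and
  regression stages in isolation.
* :func:`generate_recording` synthesizes the multichannel signal itself:
  a slow oscillation (cosine, phase 0 at the positive peak), 1/f (pink)
  background noise, Hann-windowed spindle bursts whose centers fall at von
  Mises-drawn SO phases around each channel's preferred phase, plus optional
  artifact segments — and returns the injected ground truth so the whole
  pipeline is testable by parameter recovery.

Neither generator attempts realistic sleep macroarchitecture (cycles, REM,
arousals); the hypnogram simply marks the generated span as N2/N3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError
from .precession import DEFAULT_POSITION_MAP, position_for_label
from .types import (Hypnogram, PHASE_COLUMNS, PARASAGITTAL_CHANNELS, Recording,
                    wrap_phase)

#: sentinel concentration meaning "noiseless": phases exactly at the mean
KAPPA_NOISELESS = np.inf


def _von_mises(rng: np.random.Generator, mu: float, kappa: float,
               size: int) -> np.ndarray:
    if np.isinf(kappa):
        return np.full(size, wrap_phase(mu))
    return wrap_phase(rng.vonmises(mu, kappa, size))


@dataclass
class PhaseGenConfig:
    """Phase-level generator settings.

    slope_true : radians of preferred-phase advance per position unit
    phase0     : mean phase at position 0 (radians)
    kappa      : von Mises concentration (>= 0; ``numpy.inf`` = noiseless)
    n_per_channel : events per channel
    positions  : channel label -> anterior-posterior position unit
    """

    slope_true: float = -0.9
    phase0: float = 2.7
    kappa: float = 2.0
    n_per_channel: int = 150
    positions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POSITION_MAP))
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_channel < 1:
            raise ConfigError("n_per_channel must be >= 1")
        if not self.positions:
            raise ConfigError("positions mapping is empty")
        if len(set(self.positions.values())) < 2:
            raise ConfigError("need >= 2 distinct positions")
        if not (self.kappa >= 0):
            raise ConfigError("kappa must be >= 0 (numpy.inf for noiseless)")


def generate_phase_dataset(cfg: PhaseGenConfig,
                           subject_id: str = "sim") -> pd.DataFrame:
    """Draw spindle SO phases with an imposed linear phase-position relation.

    For a channel at position x, phases are i.i.d. von Mises with mean
    ``phase0 + slope_true * x`` and concentration ``kappa``, wrapped to
    (-pi, pi]. Bit-reproducible for a given seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for ch in sorted(cfg.positions):
        x = float(cfg.positions[ch])
        mu = cfg.phase0 + cfg.slope_true * x
        phases = _von_mises(rng, mu, cfg.kappa, cfg.n_per_channel)
        for k, phi in enumerate(phases):
            rows.append((subject_id, ch, x, float(phi), float(k), "continuous_SO"))
    return pd.DataFrame(rows, columns=PHASE_COLUMNS)


@dataclass
class SignalGenConfig:
    """Signal-level generator settings (amplitudes in µV, durations in s)."""

    channel_labels: Sequence[str] = PARASAGITTAL_CHANNELS
    fs: float = 128.0
    duration: float = 2700.0          # 45 min
    so_freq: float = 0.8              # within the 0.5-2 Hz SO band
    so_amp: float = 75.0
    spindle_freq: float = 13.0        # within the 11-16 Hz sigma band
    spindle_amp: float = 25.0
    spindle_dur: float = 1.0          # >= 0.3 s so the detector can qualify it
    events_per_min: float = 4.0
    coupling_slope: float = -0.9      # rad per position unit
    coupling_phase0: float = 2.7      # preferred phase at position 0
    coupling_kappa: float = 2.0       # numpy.inf = noiseless coupling
    noise_amp: float = 15.0           # std of the pink background
    white_noise: bool = False         # white instead of 1/f background
    so_random_phase: bool = True      # random SO phase offset per channel
    so_freq_jitter: float = 0.03      # fractional SO frequency jitter per channel
    artifact_spec: Sequence[tuple[str, float, float]] = ()
    reference_channel: str | None = None   # extra non-cortical channel (e.g. Cs2)
    reference_mix: float = 0.5             # posterior-SO fraction it carries
    edge_margin: float = 4.0          # keep events away from recording edges
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 100:
            raise ConfigError("fs must be >= 100 Hz")
        if self.spindle_dur * self.fs < 1:
            raise ConfigError("spindle_dur shorter than one sample")
        if not (0.5 <= self.so_freq <= 2.0):
            raise ConfigError("so_freq must lie in the 0.5-2 Hz SO band")
        if not (11.0 <= self.spindle_freq <= 16.0):
            raise ConfigError("spindle_freq must lie in the 11-16 Hz band")
        if self.spindle_dur < 0.3:
            raise ConfigError("spindle_dur must be >= 0.3 s")
        for amp in (self.so_amp, self.spindle_amp, self.noise_amp):
            if amp < 0:
                raise ConfigError("amplitudes must be >= 0")
        for kind, _, _ in self.artifact_spec:
            if kind not in ("high_voltage", "flat", "myogenic"):
                raise ConfigError(f"unknown artifact kind {kind!r}")


@dataclass
class GroundTruth:
    """Injected events and imposed parameters of one synthetic recording."""

    spindles: pd.DataFrame          # channel, start_s, end_s, center_s, phase
    preferred_phase: dict[str, float]
    coupling_slope: float
    hypnogram: Hypnogram

    def to_dict(self) -> dict:
        return {
            "spindles": self.spindles.to_dict(orient="list"),
            "preferred_phase": self.preferred_phase,
            "coupling_slope": self.coupling_slope,
            "hypnogram": list(self.hypnogram.stages),
        }


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    with np.errstate(divide="ignore"):
        shaping = np.where(freqs > 0, 1.0 / np.sqrt(freqs), 0.0)
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std()


def _place_events(rng: np.random.Generator, targets: np.ndarray,
                  cfg: SignalGenConfig, f: float, delta: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Center times realizing the target SO phases, non-overlapping.

    The channel's SO is cos(2*pi*f*t + delta), so its instantaneous phase is
    2*pi*f*t + delta (mod 2*pi) and the target phase phi is met once per
    cycle at t = ((phi - delta)/2pi + k)/f. Cycles are sampled without
    replacement and events closer than one spindle duration are rejected.
    """
    lo, hi = cfg.edge_margin, cfg.duration - cfg.edge_margin
    n_cycles = int(np.floor(hi * f)) - int(np.ceil(lo * f))
    n_events = targets.size
    if n_events > 0.5 * n_cycles:
        raise GenerationError(
            f"events_per_min={cfg.events_per_min} needs {n_events} events but only "
            f"{n_cycles} SO cycles are available; halve the rate or extend duration")
    first = int(np.ceil(lo * f))
    cycles = first + rng.choice(n_cycles, size=n_events, replace=False)
    times = (wrap_phase(targets - delta) / (2 * np.pi) + cycles) / f
    order = np.argsort(times)
    times, keep_phase = times[order], targets[order]
    keep = np.ones(n_events, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if t - last < cfg.spindle_dur * 1.05 or not (lo <= t <= hi):
            keep[i] = False
        else:
            last = t
    return times[keep], keep_phase[keep]


def generate_recording(cfg: SignalGenConfig
                       ) -> tuple[Recording, Hypnogram, GroundTruth]:
    """Synthesize a multichannel recording with coupled spindle bursts.

    Every channel carries the same slow oscillation ``so_amp*cos(2*pi*f*t)``
    plus independent background noise; spindle bursts (Hann-windowed
    ``spindle_freq`` sinusoids) are centered at times where the SO phase
    equals a von Mises draw around the channel's preferred phase
    ``coupling_phase0 + coupling_slope * position``. Artifact segments are
    injected on all channels per ``artifact_spec``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    labels = [str(c) for c in cfg.channel_labels]
    n_events = int(round(cfg.events_per_min * cfg.duration / 60.0))
    burst_n = int(round(cfg.spindle_dur * cfg.fs))
    window = np.hanning(burst_n)

    # Per-channel SO desynchronization: scalp SO is only partially coherent
    # across channels, and a perfectly identical SO would vanish under the
    # common-average montage and cancel in bipolar derivations. Ground-truth
    # coupling is always defined against the channel's own local SO phase.
    deltas = (rng.uniform(-np.pi, np.pi, len(labels)) if cfg.so_random_phase
              else np.zeros(len(labels)))
    f_chs = cfg.so_freq * (1 + cfg.so_freq_jitter
                           * rng.uniform(-1, 1, len(labels)))

    data = np.empty((len(labels), n))
    preferred: dict[str, float] = {}
    gt_rows = []
    posterior_idx = []
    for ci, ch in enumerate(labels):
        noise = (rng.normal(size=n) if cfg.white_noise
                 else _pink_noise(rng, n, cfg.fs)) * cfg.noise_amp
        so = cfg.so_amp * np.cos(2 * np.pi * f_chs[ci] * t + deltas[ci])
        sig = so + noise
        try:
            pos = position_for_label(ch)
        except KeyError:
            pos = None
        if pos is not None:
            mu = wrap_phase(cfg.coupling_phase0 + cfg.coupling_slope * pos)
            preferred[ch] = float(mu)
            if pos >= 4:
                posterior_idx.append(ci)
            targets = _von_mises(rng, mu, cfg.coupling_kappa, n_events)
            centers, phases = _place_events(rng, targets, cfg, f_chs[ci],
                                            deltas[ci])
            for c, phi in zip(centers, phases):
                i0 = int(round(c * cfg.fs)) - burst_n // 2
                burst = cfg.spindle_amp * window * np.cos(
                    2 * np.pi * cfg.spindle_freq * (np.arange(burst_n) + i0) / cfg.fs)
                sig[i0: i0 + burst_n] += burst
                gt_rows.append((ch, i0 / cfg.fs, (i0 + burst_n - 1) / cfg.fs,
                                float(c), float(wrap_phase(phi))))
        data[ci] = sig

    if cfg.reference_channel is not None:
        # a neck-style reference: a fraction of the posterior SO plus noise
        src = (data[posterior_idx].mean(axis=0) if posterior_idx
               else cfg.so_amp * np.cos(2 * np.pi * cfg.so_freq * t))
        ref = cfg.reference_mix * src + cfg.noise_amp * _pink_noise(rng, n, cfg.fs)
        data = np.vstack([data, ref[None, :]])
        labels = labels + [cfg.reference_channel]

    for kind, start, dur in cfg.artifact_spec:
        i0, i1 = int(round(start * cfg.fs)), int(round((start + dur) * cfg.fs))
        i1 = min(i1, n)
        if kind == "high_voltage":
            data[:, i0:i1] += 500.0 * np.sign(
                np.sin(2 * np.pi * 2.0 * t[i0:i1] + 1e-9))
        elif kind == "flat":
            data[:, i0:i1] = 0.0
        elif kind == "myogenic":
            seg = rng.normal(size=(data.shape[0], i1 - i0))
            from scipy.signal import butter, sosfiltfilt
            sos = butter(4, (30, min(50, cfg.fs / 2 * 0.95)), btype="bandpass",
                         fs=cfg.fs, output="sos")
            data[:, i0:i1] += 60.0 * sosfiltfilt(sos, seg, axis=1)

    n_epochs = int(n / cfg.fs // 30)
    stages = ["N2" if e < n_epochs // 2 else "N3" for e in range(n_epochs)]
    hyp = Hypnogram(stages)
    rec = Recording(data, cfg.fs, labels, "as_recorded")
    gt = GroundTruth(
        spindles=pd.DataFrame(
            gt_rows, columns=["channel", "start_s", "end_s", "center_s", "phase"]),
        preferred_phase=preferred,
        coupling_slope=cfg.coupling_slope,
        hypnogram=hyp,
    )
    return rec, hyp, gt


def config_to_dict(cfg) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, float) and np.isinf(v):
            d[k] = "inf"
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
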