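"""Core in-memory containers for the spindle–SO phase-precession pipeline.

Signals live in a :class:`Recording` (channels × samples, microvolts);
detected events and extracted phase samples are plain :class:`pandas.DataFrame`
tables with documented column schemas so they serialize to CSV/TSV trivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: canonical spelling of the 13 parasagittal 10-20 channels, anterior to posterior
PARASAGITTAL_CHANNELS = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "O2",
)

#: 10-20 labels we know how to spell canonically (parasagittal + common extras)
_CANONICAL = {
    c.lower(): c
    for c in PARASAGITTAL_CHANNELS
    + ("F7", "F8", "T3", "T4", "T5", "T6", "A1", "A2", "Fpz", "Oz", "Cs2")
}


def canonical_label(label: str) -> str:
    """Normalize a 10-20 channel label to its canonical capitalization.

    Unknown labels are returned stripped but otherwise untouched.
    """
    key = label.strip().lower()
    return _CANONICAL.get(key, label.strip())


@dataclass
class Recording:
    """Multichannel scalp EEG.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Canonical 10-20 labels, unique.
    reference : str
        One of ``as_recorded``, ``common_average``, ``referential:<label>``,
        ``longitudinal_bipolar``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    reference: str = "as_recorded"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(canonical_label(label))
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy(self, **changes) -> "Recording":
        rec = replace(self, **changes)
        if "data" not in changes:
            rec.data = self.data.copy()
        return rec


NREM_STAGES = frozenset({"N2", "N3"})
STAGES = ("W", "N1", "N2", "N3", "REM")


@dataclass
class Hypnogram:
    """Sleep stages in consecutive fixed-length epochs (30 s by convention)."""

    stages: list[str]
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages: {sorted(bad)}")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")

    def __len__(self) -> int:
        return len(self.stages)

    def sample_mask(self, n_samples: int, fs: float,
                    keep: frozenset[str] = NREM_STAGES) -> np.ndarray:
        """Boolean per-sample mask: True where the sample's epoch is in `keep`.

        Samples beyond the last scored epoch are False.
        """
        mask = np.zeros(n_samples, dtype=bool)
        spe = int(round(self.epoch_len * fs))
        for i, stage in enumerate(self.stages):
            if stage in keep:
                mask[i * spe: min((i + 1) * spe, n_samples)] = True
        return mask


@dataclass
class ArtifactMask:
    """Per-channel boolean over a fixed 5-s window grid (True = rejected)."""

    flags: np.ndarray  # (n_channels, n_windows)
    window_len: float = 5.0
    channel_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ValueError("flags must be 2-D (channels x windows)")

    @property
    def n_windows(self) -> int:
        return self.flags.shape[1]

    def sample_mask(self, n_samples: int, fs: float) -> np.ndarray:
        """Expand to per-channel per-sample rejection mask (True = rejected).

        Samples past the last full window inherit its trailing-window flag;
        if no window covers them they are rejected (conservative).
        """
        spw = int(round(self.window_len * fs))
        out = np.ones((self.flags.shape[0], n_samples), dtype=bool)
        for w in range(self.n_windows):
            sl = slice(w * spw, min((w + 1) * spw, n_samples))
            out[:, sl] = self.flags[:, w][:, None]
        return out


SPINDLE_COLUMNS = ["channel", "start_s", "end_s", "peak_s", "peak_score", "detector_id"]
SW_COLUMNS = ["channel", "down_zc_s", "up_zc_s", "trough_s", "envelope_peak"]
PHASE_COLUMNS = ["subject_id", "channel", "position", "phase", "event_time_s", "source"]


def empty_events(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float if c != "channel" else object)
                         for c in columns})


@dataclass
class PrecessionFit:
    """Circular-linear regression of spindle SO-phase on electrode position.

    ``slope_a`` is in radians per position unit; ``corr_R`` is the
    circular-linear correlation coefficient (non-negative by construction —
    the sign of the relationship is carried by ``slope_a``).
    """

    slope_a: float
    phase_offset_phi0: float
    corr_R: float
    p_value: float
    n: int
    level: str  # "group_mean_phases" | "subject_raw_phases"

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05 and self.slope_a != 0.0)

    def to_dict(self) -> dict:
        return {
            "slope_a": float(self.slope_a),
            "phase_offset_phi0": float(self.phase_offset_phi0),
            "corr_R": float(self.corr_R),
            "p_value": float(self.p_value),
            "n": int(self.n),
            "level": self.level,
            "significant": self.significant,
        }


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the half-open interval (-pi, pi]."""
    out = -np.mod(-np.asarray(phi, dtype=float) + np.pi, 2 * np.pi) + np.pi
    return float(out) if np.isscalar(phi) else out
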