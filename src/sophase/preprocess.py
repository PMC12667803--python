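"""Recording I/O, standardization, montage re-referencing and masking.

The analysis operates on 128 Hz, 0.1-50 Hz bandpassed EEG restricted to
artifact-free N2/N3 sleep. Artifact rejection screens non-overlapping 5-s
windows per channel against three criteria: excessive voltage (> 400 µV),
flat signal (std < 0.01 µV), and excessive myogenic activity (std of the
window's 30-50 Hz bandpassed signal more than 3x the std of the whole
recording's 30-50 Hz bandpassed signal).
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .errors import ChannelMissingError, ResamplingDirectionError
from .types import ArtifactMask, Hypnogram, NREM_STAGES, Recording, canonical_label

logger = logging.getLogger(__name__)

TARGET_FS = 128.0
BROAD_BAND = (0.1, 50.0)
MYO_BAND = (30.0, 50.0)

#: standard longitudinal bipolar chains over the parasagittal electrodes
BIPOLAR_CHAINS = (
    ("Fp1", "F3", "C3", "P3", "O1"),
    ("Fp2", "F4", "C4", "P4", "O2"),
    ("Fz", "Cz", "Pz"),
)


def load_recording(path: str | Path,
                   montage_channels: Sequence[str] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (µV, labels canonicalized).

    ``montage_channels`` selects and orders channels (case-insensitive);
    absent channels raise :class:`ChannelMissingError` naming them. The
    sampling rate is preserved as recorded — no implicit resampling.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [canonical_label(ch.removeprefix("EEG ").strip())
              for ch in raw.ch_names]
    data_uv = raw.get_data() * 1e6  # MNE loads EEG in volts
    rec = Recording(data_uv, float(raw.info["sfreq"]), labels, "as_recorded")
    if montage_channels is not None:
        wanted = [canonical_label(c) for c in montage_channels]
        missing = [c for c in wanted if c not in labels]
        if missing:
            raise ChannelMissingError(missing)
        idx = [labels.index(c) for c in wanted]
        rec = Recording(rec.data[idx], rec.fs, wanted, rec.reference)
    return rec


def standardize(rec: Recording, target_fs: float = TARGET_FS,
                band: tuple[float, float] = BROAD_BAND) -> Recording:
    """Down-sample to 128 Hz (anti-aliased) and bandpass 0.1-50 Hz, zero-phase.

    Recordings already at the target rate are only filtered. Up-sampling is
    refused: the detectors assume the acquisition rate was >= 128 Hz.
    """
    if rec.fs < target_fs:
        raise ResamplingDirectionError(
            f"recording at {rec.fs} Hz is below the {target_fs} Hz analysis rate")
    data = rec.data
    if rec.fs != target_fs:
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = resample_poly(data, frac.numerator, frac.denominator, axis=1)
    sos = butter(4, band, btype="bandpass", fs=target_fs, output="sos")
    data = sosfiltfilt(sos, data, axis=1)
    return Recording(data, target_fs, list(rec.channel_labels), rec.reference)


def rereference(rec: Recording, mode: str,
                include: Sequence[str] | None = None) -> Recording:
    """Re-reference into one of the three analysis montages.

    ``common_average``
        Subtract, at every sample, the mean over ``include`` (default: all
        channels) from each included channel; non-included channels are
        dropped.
    ``referential:<label>``
        Subtract the named channel (e.g. the neck electrode Cs2) from every
        other channel; the reference channel itself is dropped.
    ``longitudinal_bipolar``
        Derive anterior-minus-posterior neighbor pairs along the standard
        chains (Fp1-F3, F3-C3, ... and homologs, plus Fz-Cz, Cz-Pz).
    """
    if mode == "as_recorded":
        return rec.copy()
    if mode == "common_average":
        labels = list(rec.channel_labels) if include is None else [
            canonical_label(c) for c in include]
        missing = [c for c in labels if c not in rec.channel_labels]
        if missing:
            raise ChannelMissingError(missing)
        idx = [rec.channel_index(c) for c in labels]
        sub = rec.data[idx]
        return Recording(sub - sub.mean(axis=0, keepdims=True), rec.fs,
                         labels, "common_average")
    if mode.startswith("referential:"):
        ref = canonical_label(mode.split(":", 1)[1])
        if ref not in rec.channel_labels:
            raise ChannelMissingError([ref])
        ref_sig = rec.data[rec.channel_index(ref)]
        labels = [c for c in rec.channel_labels if c != ref]
        idx = [rec.channel_index(c) for c in labels]
        return Recording(rec.data[idx] - ref_sig, rec.fs, labels,
                         f"referential:{ref}")
    if mode == "longitudinal_bipolar":
        pairs = []
        for chain in BIPOLAR_CHAINS:
            for a, b in zip(chain, chain[1:]):
                if a in rec.channel_labels and b in rec.channel_labels:
                    pairs.append((a, b))
        if not pairs:
            raise ChannelMissingError(["no constructible bipolar pairs"])
        data = np.stack([rec.data[rec.channel_index(a)] - rec.data[rec.channel_index(b)]
                         for a, b in pairs])
        return Recording(data, rec.fs, [f"{a}-{b}" for a, b in pairs],
                         "longitudinal_bipolar")
    raise ValueError(f"unknown reference mode {mode!r}")


def artifact_mask(rec: Recording, *, window_len: float = 5.0,
                  hv_threshold: float = 400.0, flat_std: float = 0.01,
                  myo_ratio: float = 3.0,
                  myo_band: tuple[float, float] = MYO_BAND) -> ArtifactMask:
    """Flag 5-s windows with high voltage, flat signal or myogenic artifact.

    Criteria are evaluated per channel; a window is rejected if ANY holds:

    1. any sample with |v| > 400 µV;
    2. window standard deviation < 0.01 µV;
    3. std of the window's 30-50 Hz bandpassed signal > ``myo_ratio`` times
       the std of the whole recording's 30-50 Hz bandpassed signal (per
       channel, computed over the full standardized recording).

    A trailing partial window is flagged (conservative).
    """
    spw = int(round(window_len * rec.fs))
    if rec.n_samples < spw:
        warnings.warn("recording shorter than one artifact window; empty mask",
                      RuntimeWarning, stacklevel=2)
        return ArtifactMask(np.zeros((rec.n_channels, 0), dtype=bool),
                            window_len, list(rec.channel_labels))
    n_full = rec.n_samples // spw
    has_partial = rec.n_samples % spw != 0
    n_win = n_full + int(has_partial)

    sos = butter(4, myo_band, btype="bandpass", fs=rec.fs, output="sos")
    myo = sosfiltfilt(sos, rec.data, axis=1)
    global_myo_std = myo.std(axis=1)

    trimmed = rec.data[:, : n_full * spw].reshape(rec.n_channels, n_full, spw)
    myo_w = myo[:, : n_full * spw].reshape(rec.n_channels, n_full, spw)
    flags = np.zeros((rec.n_channels, n_win), dtype=bool)
    flags[:, :n_full] = (
        (np.abs(trimmed).max(axis=2) > hv_threshold)
        | (trimmed.std(axis=2) < flat_std)
        | (myo_w.std(axis=2) > myo_ratio * global_myo_std[:, None])
    )
    if has_partial:
        flags[:, -1] = True
    return ArtifactMask(flags, window_len, list(rec.channel_labels))


def analysis_mask(rec: Recording, hyp: Hypnogram, amask: ArtifactMask,
                  stages: frozenset[str] = NREM_STAGES) -> np.ndarray:
    """Per-channel per-sample usability: N2/N3 epoch AND artifact-free window."""
    stage_ok = hyp.sample_mask(rec.n_samples, rec.fs, keep=stages)
    artifact = amask.sample_mask(rec.n_samples, rec.fs)
    return stage_ok[None, :] & ~artifact
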