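"""File-format plumbing: EDF output, hypnogram CSV, event/phase tables.

EDF *reading* is delegated to MNE (:func:`sophase.preprocess.load_recording`).
Writing uses the small 16-bit EDF encoder below, since no EDF writer is
available as a library dependency; the encoder emits plain EDF (not EDF+)
with one-second data records, which MNE reads back losslessly up to the
16-bit quantization of the stated physical range.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Hypnogram, Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad_ascii(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, rec: Recording, *,
              patient_id: str = "X", recording_id: str = "sophase synthetic") -> Path:
    """Write a :class:`Recording` to an EDF file (µV, 16-bit).

    The sampling rate must be a positive integer (samples are stored in
    one-second records). The final partial record, if any, is zero-padded.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_sig = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))

    data = np.zeros((n_sig, n_rec * fs))
    data[:, : rec.n_samples] = rec.data
    # per-channel physical range, symmetric, with headroom against clipping
    phys_max = np.maximum(np.abs(data).max(axis=1) * 1.01, 1.0)
    phys_min = -phys_max
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.clip(
        np.rint((data - phys_min[:, None]) * scale[:, None] + _DIG_MIN),
        _DIG_MIN, _DIG_MAX,
    ).astype("<i2")

    header_bytes = 256 * (1 + n_sig)
    with open(path, "wb") as fh:
        fh.write(_pad_ascii("0", 8))
        fh.write(_pad_ascii(patient_id, 80))
        fh.write(_pad_ascii(recording_id, 80))
        fh.write(_pad_ascii("01.01.00", 8))
        fh.write(_pad_ascii("00.00.00", 8))
        fh.write(_pad_ascii(str(header_bytes), 8))
        fh.write(_pad_ascii("", 44))
        fh.write(_pad_ascii(str(n_rec), 8))
        fh.write(_pad_ascii("1", 8))
        fh.write(_pad_ascii(str(n_sig), 4))
        for lab in rec.channel_labels:
            fh.write(_pad_ascii(f"EEG {lab}", 16))
        for _ in range(n_sig):
            fh.write(_pad_ascii("", 80))
        for _ in range(n_sig):
            fh.write(_pad_ascii("uV", 8))
        for v in phys_min:
            fh.write(_pad_ascii(f"{v:.2f}"[:8], 8))
        for v in phys_max:
            fh.write(_pad_ascii(f"{v:.2f}"[:8], 8))
        for _ in range(n_sig):
            fh.write(_pad_ascii(str(_DIG_MIN), 8))
        for _ in range(n_sig):
            fh.write(_pad_ascii(str(_DIG_MAX), 8))
        for _ in range(n_sig):
            fh.write(_pad_ascii("", 80))
        for _ in range(n_sig):
            fh.write(_pad_ascii(str(fs), 8))
        for _ in range(n_sig):
            fh.write(_pad_ascii("", 32))
        # data records: all samples of signal 0, then signal 1, ... per record
        for r in range(n_rec):
            block = digital[:, r * fs: (r + 1) * fs]
            fh.write(block.tobytes())
    return path


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> Path:
    path = Path(path)
    pd.DataFrame({"epoch_index": np.arange(len(hyp)), "stage": hyp.stages}
                 ).to_csv(path, index=False)
    return path


def read_hypnogram(path: str | Path, epoch_len: float = 30.0) -> Hypnogram:
    df = pd.read_csv(path)
    if not {"epoch_index", "stage"} <= set(df.columns):
        raise ValueError("hypnogram CSV needs columns epoch_index,stage")
    df = df.sort_values("epoch_index")
    return Hypnogram(stages=[str(s) for s in df["stage"]], epoch_len=epoch_len)


def write_events(path: str | Path, events: pd.DataFrame) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phase_samples(path: str | Path, samples: pd.DataFrame) -> Path:
    path = Path(path)
    samples.to_csv(path, index=False)
    return path


def read_phase_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
    return path


def write_mask_intervals(path: str | Path, mask, *,
                         reason: str = "artifact") -> Path:
    """Export an :class:`ArtifactMask` as BED-like text for audit:
    channel <tab> start_s <tab> end_s <tab> reason."""
    path = Path(path)
    rows = []
    for ci, lab in enumerate(mask.channel_labels):
        for w in np.flatnonzero(mask.flags[ci]):
            rows.append((lab, w * mask.window_len, (w + 1) * mask.window_len, reason))
    pd.DataFrame(rows, columns=["channel", "start_s", "end_s", "reason"]
                 ).to_csv(path, sep="\t", index=False, header=False)
    return path
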