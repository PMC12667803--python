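"""End-to-end orchestration: simulate/load -> preprocess -> detect -> couple -> fit.

A single :class:`RunConfig` (YAML-serializable) drives both single-subject
runs and the sensitivity matrix over montage x detector x phase source. All
artifacts written by a run carry the hash of the exact configuration that
produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling, detectors, io, precession, preprocess, synthgen
from .errors import SophaseError
from .precession import DEFAULT_POSITION_MAP
from .types import Hypnogram, Recording

logger = logging.getLogger(__name__)

MONTAGES = ("as_recorded", "common_average", "longitudinal_bipolar")  # + referential:<label>
DETECTORS = ("zscore", "alt")
PHASE_SOURCES = ("continuous_SO", "SW_event")


@dataclass
class RunConfig:
    """One subject's analysis configuration.

    Exactly one input source: either ``edf_path`` (+ ``hypnogram_path``) or
    ``synth`` (keyword arguments for :class:`sophase.synthgen.SignalGenConfig`).
    """

    subject_id: str = "S01"
    edf_path: str | None = None
    hypnogram_path: str | None = None
    synth: dict | None = None
    montage: str = "common_average"
    detector: str = "zscore"
    phase_source: str = "continuous_SO"
    so_band: tuple[float, float] = (0.5, 2.0)
    slope_range: tuple[float, float] = (-float(np.pi), float(np.pi))
    min_subject_n: int = 10
    assume_polarity_ok: bool = True
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if (self.edf_path is None) == (self.synth is None):
            raise SophaseError("exactly one input source: edf_path or synth")
        if self.detector not in DETECTORS:
            raise SophaseError(f"detector must be one of {DETECTORS}")
        if self.phase_source not in PHASE_SOURCES:
            raise SophaseError(f"phase_source must be one of {PHASE_SOURCES}")
        if not (self.montage in MONTAGES or self.montage.startswith("referential:")):
            raise SophaseError(f"unknown montage {self.montage!r}")
        if not self.assume_polarity_ok:
            raise SophaseError(
                "polarity not confirmed: set assume_polarity_ok once recording "
                "polarity has been verified upstream")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["so_band"] = list(self.so_band)
        d["slope_range"] = list(self.slope_range)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SophaseError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.so_band, list):
            cfg.so_band = tuple(cfg.so_band)
        if isinstance(cfg.slope_range, list):
            cfg.slope_range = tuple(cfg.slope_range)
        return cfg


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage's name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, SophaseError):
                raise SophaseError(f"stage {name!r} failed: {exc}") from exc
            if isinstance(exc, SophaseError) and not getattr(exc, "_staged", False):
                exc._staged = True
                exc.args = (f"stage {name!r}: {exc.args[0]}",) + exc.args[1:]
            return False
    return _Ctx()


def _load_input(cfg: RunConfig) -> tuple[Recording, Hypnogram]:
    if cfg.synth is not None:
        synth_kwargs = dict(cfg.synth)
        synth_kwargs.setdefault("seed", cfg.seed)
        gen_cfg = synthgen.SignalGenConfig(**synth_kwargs)
        rec, hyp, _ = synthgen.generate_recording(gen_cfg)
        return rec, hyp
    rec = preprocess.load_recording(cfg.edf_path)
    if cfg.hypnogram_path is None:
        raise SophaseError("hypnogram_path required with edf_path")
    hyp = io.read_hypnogram(cfg.hypnogram_path)
    return rec, hyp


def run_subject(cfg: RunConfig, write: bool = True) -> dict:
    """Run the full pipeline for one subject.

    Returns a dict with the recording-level intermediates and the
    subject-level :class:`~sophase.types.PrecessionFit`. With ``write=True``
    and an ``output_dir``, events, phase samples, channel stats and the fit
    (with a full parameter manifest) are written as TSV/CSV/JSON.
    """
    cfg.validate()
    with _stage("input"):
        rec, hyp = _load_input(cfg)
    with _stage("standardize"):
        rec = preprocess.standardize(rec)
    with _stage("rereference"):
        if cfg.montage == "common_average":
            include = [c for c in rec.channel_labels if c in DEFAULT_POSITION_MAP]
            rec_ref = preprocess.rereference(rec, cfg.montage, include=include)
        else:
            rec_ref = preprocess.rereference(rec, cfg.montage)
    with _stage("artifact_mask"):
        amask = preprocess.artifact_mask(rec_ref)
        usable = preprocess.analysis_mask(rec_ref, hyp, amask)
    with _stage("detect"):
        if cfg.detector == "zscore":
            spindles = detectors.detect_spindles(rec_ref, usable)
        else:
            spindles = detectors.detect_spindles_alt(rec_ref, usable)
        sw = (detectors.detect_slow_waves(rec_ref, usable)
              if cfg.phase_source == "SW_event" else None)
    with _stage("couple"):
        phase, valid = coupling.so_phase_series(rec_ref, band=cfg.so_band,
                                                usable=usable)
        samples = coupling.phases_at_spindles(
            phase, valid, rec_ref.fs, spindles, rec_ref.channel_labels,
            subject_id=cfg.subject_id, sw_events=sw)
        samples = samples[samples["position"].notna()]
        stats = coupling.channel_stats_table(samples) if len(samples) else None
    with _stage("fit"):
        fit = precession.fit_subject(samples, min_n=cfg.min_subject_n,
                                     slope_range=cfg.slope_range)

    result = {
        "config": cfg, "config_hash": config_hash(cfg),
        "recording": rec_ref, "hypnogram": hyp, "artifact_mask": amask,
        "spindles": spindles, "sw_events": sw, "phase_samples": samples,
        "channel_stats": stats, "fit": fit,
    }
    if write and cfg.output_dir is not None:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = f"{cfg.subject_id}"
        io.write_events(outdir / f"{tag}_spindles.tsv", spindles)
        if sw is not None:
            io.write_events(outdir / f"{tag}_slow_waves.tsv", sw)
        io.write_phase_samples(outdir / f"{tag}_phases.csv", samples)
        if stats is not None:
            stats.to_csv(outdir / f"{tag}_channel_stats.csv", index=False)
        manifest = {"config": cfg.to_dict(), "config_hash": config_hash(cfg),
                    "detector_id": cfg.detector, "n_spindles": int(len(spindles))}
        io.write_json(outdir / f"{tag}_fit.json",
                      {"fit": fit.to_dict(), "manifest": manifest})
    return result


def run_sensitivity_matrix(cfg: RunConfig,
                           variants: dict[str, list[str]] | None = None
                           ) -> pd.DataFrame:
    """Run every combination of the requested methodology axes on one input.

    ``variants`` maps any of ``montage``, ``detector``, ``phase_source`` to
    the values to sweep; omitted axes stay at the base configuration. An
    empty/None mapping yields the single default run.
    """
    cfg.validate()
    variants = variants or {}
    axes = {"montage": [cfg.montage], "detector": [cfg.detector],
            "phase_source": [cfg.phase_source]}
    for key, values in variants.items():
        if key not in axes:
            raise SophaseError(f"unknown sensitivity axis {key!r}")
        axes[key] = list(values)
    rows = []
    for montage, det, src in itertools.product(
            axes["montage"], axes["detector"], axes["phase_source"]):
        sub = dataclasses.replace(cfg, montage=montage, detector=det,
                                  phase_source=src)
        res = run_subject(sub, write=False)
        fit = res["fit"]
        rows.append({"montage": montage, "detector": det, "phase_source": src,
                     **fit.to_dict(), "config_hash": res["config_hash"]})
    return pd.DataFrame(rows)


def simulate_to_files(synth_kwargs: dict, outdir: str | Path,
                      subject_id: str = "S01") -> dict[str, Path]:
    """Generate a synthetic recording and write EDF + hypnogram CSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen_cfg = synthgen.SignalGenConfig(**synth_kwargs)
    rec, hyp, gt = synthgen.generate_recording(gen_cfg)
    paths = {
        "edf": io.write_edf(outdir / f"{subject_id}.edf", rec),
        "hypnogram": io.write_hypnogram(outdir / f"{subject_id}_hypnogram.csv", hyp),
        "ground_truth": io.write_json(outdir / f"{subject_id}_truth.json",
                                      gt.to_dict()),
        "params": io.write_json(outdir / f"{subject_id}_params.json",
                                synthgen.config_to_dict(gen_cfg)),
    }
    logger.info("simulated %s: %d channels, %.0f s, seed %d", subject_id,
                rec.n_channels, rec.duration, gen_cfg.seed)
    return paths
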