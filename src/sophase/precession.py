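"""Anterior-posterior position mapping and circular-linear phase-precession fits.

The quantity of interest is the systematic advance of the preferred
slow-oscillation phase of sleep spindles along the scalp's anterior-posterior
axis. Electrode rows of the 10-20 system (frontopolar, frontal, central,
parietal, occipital) are equidistant along the nasion-inion line, so each row
is one position unit. Phase-on-position is fit with the circular-linear
regression of Kempter et al.: the slope â maximizes the mean resultant length
of the phase residuals

    R(a) = (1/n) | sum_j exp(i (phi_j - a x_j)) |,

equivalently minimizing the summed circular distances between the data and
the line phi = phi0 + a x. Strength and significance come from the
circular-linear correlation of Berens et al. (non-negative R; the sign of the
relationship is carried by the slope).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, UnidentifiableSlopeError
from .types import PrecessionFit, wrap_phase

#: anterior-posterior position unit for each parasagittal 10-20 electrode
DEFAULT_POSITION_MAP: dict[str, int] = {
    "Fp1": 1, "Fp2": 1,
    "F3": 2, "Fz": 2, "F4": 2,
    "C3": 3, "Cz": 3, "C4": 3,
    "P3": 4, "Pz": 4, "P4": 4,
    "O1": 5, "O2": 5,
}

#: successive 10-20 spacings along the nasion-inion line, percent of that distance
TEN_TWENTY_SPACINGS_PCT = (10.0, 20.0, 20.0, 20.0, 20.0, 10.0)


def electrode_row_fractions() -> np.ndarray:
    """Nasion-inion fractions of the five parasagittal rows (Fp, F, C, P, O).

    Derived from the standard 10-20 spacing percentages: rows sit at the
    cumulative 10-20-20-20-20(-10) marks.
    """
    marks = np.cumsum(TEN_TWENTY_SPACINGS_PCT[:-1]) / 100.0
    return marks


def unit_spacing_fraction() -> float:
    """Nasion-inion fraction spanned by one position unit (adjacent rows)."""
    spacings = np.diff(electrode_row_fractions())
    assert np.allclose(spacings, spacings[0])
    return float(spacings[0])


def slope_to_degrees(slope_rad: float) -> float:
    """Express a precession slope in degrees of phase per position unit."""
    return float(np.degrees(slope_rad))


def position_for_label(label: str, pos_map: Mapping[str, float] | None = None) -> float:
    """Position of a channel label; bipolar labels 'A-B' map to the midpoint."""
    pos_map = DEFAULT_POSITION_MAP if pos_map is None else pos_map
    if label in pos_map:
        return float(pos_map[label])
    if "-" in label:
        a, b = label.split("-", 1)
        if a in pos_map and b in pos_map:
            return (float(pos_map[a]) + float(pos_map[b])) / 2.0
    raise KeyError(f"channel {label!r} has no anterior-posterior position")


def assign_positions(samples: pd.DataFrame,
                     pos_map: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Attach the anterior-posterior position to each phase sample.

    Raises
    ------
    KeyError
        If any channel label has no position (e.g. temporal chain channels).
    """
    out = samples.copy()
    out["position"] = [position_for_label(ch, pos_map) for ch in out["channel"]]
    return out


def _resultant_length(phases: np.ndarray, positions: np.ndarray,
                      slopes: np.ndarray) -> np.ndarray:
    """R(a) for each candidate slope a (vectorized over slopes)."""
    resid = phases[None, :] - np.asarray(slopes)[:, None] * positions[None, :]
    return np.abs(np.exp(1j * resid).mean(axis=1))


def kempter_fit(phases: Sequence[float], positions: Sequence[float], *,
                slope_range: tuple[float, float] = (-np.pi, np.pi),
                coarse_step: float = 1e-2,
                refine: bool = True) -> tuple[float, float]:
    """Fit phi = phi0 + a x by maximizing the residual mean resultant length.

    A coarse grid over ``slope_range`` locates the basin; a bounded scalar
    optimization refines within one grid step. Ties on the grid break toward
    the smallest |a| (favoring the null of no precession). Returns
    ``(slope_a, phi0)`` with phi0 wrapped to (-pi, pi].
    """
    phases = np.asarray(phases, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if phases.shape != positions.shape or phases.ndim != 1:
        raise ValueError("phases and positions must be 1-D and equal length")
    n = phases.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 samples for a slope fit, got {n}")
    if np.unique(positions).size < 2:
        raise UnidentifiableSlopeError("all positions identical")

    lo, hi = slope_range
    grid = np.arange(lo, hi + coarse_step / 2, coarse_step)
    R = _resultant_length(phases, positions, grid)
    best_R = R.max()
    ties = np.flatnonzero(R >= best_R - 1e-12)
    a_hat = grid[ties[np.argmin(np.abs(grid[ties]))]]

    if refine:
        lo_r = max(lo, a_hat - coarse_step)
        hi_r = min(hi, a_hat + coarse_step)
        res = optimize.minimize_scalar(
            lambda a: -_resultant_length(phases, positions, np.array([a]))[0],
            bounds=(lo_r, hi_r), method="bounded",
            options={"xatol": 1e-7},
        )
        if -res.fun >= best_R:
            a_hat = float(res.x)

    if min(a_hat - lo, hi - a_hat) < coarse_step:
        warnings.warn(
            f"fitted slope {a_hat:.3f} lies at the search boundary {slope_range}; "
            "consider widening slope_range", RuntimeWarning, stacklevel=2)

    phi0 = float(np.angle(np.exp(1j * (phases - a_hat * positions)).sum()))
    return float(a_hat), wrap_phase(phi0)


def circ_linear_corr(phases: Sequence[float],
                     positions: Sequence[float]) -> tuple[float, float]:
    """Circular-linear correlation (Berens) between angles and a linear variable.

    With r_cx = corr(cos phi, x), r_sx = corr(sin phi, x) and
    r_cs = corr(cos phi, sin phi):

        R = sqrt((r_cx^2 + r_sx^2 - 2 r_cx r_sx r_cs) / (1 - r_cs^2)),

    and the p-value refers n R^2 to a chi-square with 2 degrees of freedom.
    """
    phases = np.asarray(phases, dtype=float)
    x = np.asarray(positions, dtype=float)
    n = phases.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 samples for the correlation, got {n}")
    c, s = np.cos(phases), np.sin(phases)
    if min(np.var(x), np.var(c), np.var(s)) <= 0:
        raise UnidentifiableSlopeError(
            "degenerate variance in positions or phase components")
    r_cx = np.corrcoef(c, x)[0, 1]
    r_sx = np.corrcoef(s, x)[0, 1]
    r_cs = np.corrcoef(c, s)[0, 1]
    R2 = (r_cx**2 + r_sx**2 - 2 * r_cx * r_sx * r_cs) / (1 - r_cs**2)
    R = float(np.sqrt(np.clip(R2, 0.0, 1.0)))
    p = float(stats.chi2.sf(n * R * R, df=2))
    return R, max(p, np.finfo(float).tiny)


def fit_subject(samples: pd.DataFrame, *, min_n: int = 10,
                slope_range: tuple[float, float] = (-np.pi, np.pi),
                level: str = "subject_raw_phases") -> PrecessionFit:
    """Subject-level fit on the raw phase of every coupling event.

    No Rayleigh gating: every spindle's SO phase enters, preserving the raw
    data even at electrodes without a significant phase preference.
    """
    if len(samples) < min_n:
        raise InsufficientDataError(
            f"subject fit needs >= {min_n} phase samples, got {len(samples)}")
    phases = samples["phase"].to_numpy(dtype=float)
    x = samples["position"].to_numpy(dtype=float)
    a, phi0 = kempter_fit(phases, x, slope_range=slope_range)
    R, p = circ_linear_corr(phases, x)
    return PrecessionFit(a, phi0, R, p, len(samples), level)


def fit_group(channel_stats: pd.DataFrame, *, alpha: float = 0.05,
              slope_range: tuple[float, float] = (-np.pi, np.pi)) -> PrecessionFit:
    """Group-level fit on Rayleigh-significant per-subject channel mean phases.

    `channel_stats` holds one row per (subject, channel) with columns
    ``subject_id, channel, position, mean_phase, rayleigh_p``. Only rows with
    a significant non-uniform phase distribution (Rayleigh p < alpha)
    contribute, each as a single (position, mean phase) point; pooling is
    unweighted.
    """
    if channel_stats["subject_id"].nunique() < 2:
        raise InsufficientDataError("group fit needs >= 2 subjects")
    kept = channel_stats[channel_stats["rayleigh_p"] < alpha]
    if len(kept) < 3:
        raise InsufficientDataError(
            f"only {len(kept)} Rayleigh-significant subject-channels; need >= 3")
    phases = kept["mean_phase"].to_numpy(dtype=float)
    x = kept["position"].to_numpy(dtype=float)
    a, phi0 = kempter_fit(phases, x, slope_range=slope_range)
    R, p = circ_linear_corr(phases, x)
    return PrecessionFit(a, phi0, R, p, len(kept), "group_mean_phases")


def phase_position_table(fit: PrecessionFit, samples: pd.DataFrame,
                         line_x: Sequence[float] | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables: doubled phase points and the fitted line.

    Circular values near the wrap look scattered on a linear axis, so every
    point is emitted twice, at phi and phi + 2*pi. The line is
    phi0 + a x, also doubled.
    """
    x = samples["position"].to_numpy(dtype=float)
    phi = samples["phase"].to_numpy(dtype=float)
    points = pd.DataFrame({
        "x": np.concatenate([x, x]),
        "phase": np.concatenate([phi, phi + 2 * np.pi]),
        "copy": np.repeat([0, 1], x.size),
    })
    if line_x is None:
        line_x = np.linspace(0.0, float(x.max()) + 0.5, 50) if x.size else np.array([0.0, 1.0])
    line_x = np.asarray(line_x, dtype=float)
    line_phi = fit.phase_offset_phi0 + fit.slope_a * line_x
    line = pd.DataFrame({
        "x": np.concatenate([line_x, line_x]),
        "phase": np.concatenate([line_phi, line_phi + 2 * np.pi]),
        "copy": np.repeat([0, 1], line_x.size),
    })
    return points, line
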