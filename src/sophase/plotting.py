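"""Phase-position plot: doubled phases against electrode position."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .precession import phase_position_table
from .types import PrecessionFit


def phase_position_plot(fit: PrecessionFit, samples: pd.DataFrame,
                        path: str | Path | None = None, ax=None):
    """Scatter the (position, phase) samples twice (phi and phi + 2*pi) with
    the fitted line overlaid, the conventional view of circular-linear data."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    points, line = phase_position_table(fit, samples)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(points["x"], points["phase"], s=8, alpha=0.35, color="tab:blue")
    for _, grp in line.groupby("copy"):
        ax.plot(grp["x"], grp["phase"], color="black")
    ax.set_xlabel("anterior-posterior position (units)")
    ax.set_ylabel("SO phase of spindle (rad)")
    ax.set_title(f"slope={fit.slope_a:.2f} rad/unit, R={fit.corr_R:.2f}, "
                 f"p={fit.p_value:.2g}, n={fit.n}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
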