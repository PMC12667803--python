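"""Cohort-level statistics: demographics vs phase-precession metrics.

Per-subject precession metrics (slope, circular-linear R, significance flag)
are joined to age, sex and recording group, then analyzed with ordinary
least squares adjusting for the total number of phase samples behind each
subject's fit and for the recording group. Because subjects differ widely in
spindle-SO coupling event counts, the count covariate guards against density
driving apparent strength differences. Significance proportions across age
quartiles are compared with a 2x2 Pearson chi-square (no continuity
correction).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency

from .errors import CollinearityError, InsufficientDataError

COHORT_COLUMNS = ["subject_id", "age", "sex", "group", "total_count",
                  "slope", "corr_R", "significant"]

METRICS = ("corr_R", "slope")
PREDICTORS = ("age", "sex")


def validate_cohort(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if (records["total_count"] < 1).any():
        raise ValueError("total_count must be >= 1")
    if (records["age"] <= 0).any():
        raise ValueError("age must be positive")
    return records


def _design(records: pd.DataFrame, predictor: str) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    if predictor == "age":
        cols.append(records["age"].to_numpy(dtype=float))
        names.append("age")
    elif predictor == "sex":
        cols.append((records["sex"] == "M").to_numpy(dtype=float))  # reference F
        names.append("sex[M]")
    else:
        raise ValueError(f"predictor must be one of {PREDICTORS}")
    cols.append(records["total_count"].to_numpy(dtype=float))
    names.append("total_count")
    if records["group"].nunique() > 1:
        cols.append((records["group"] == "AMB").to_numpy(dtype=float))  # ref EMU
        names.append("group[AMB]")
    X = np.column_stack(cols)
    return X, names


def regress_metric(records: pd.DataFrame, metric: str, predictor: str
                   ) -> dict[str, float]:
    """OLS of a precession metric on age or sex, adjusted for count and group.

    When the metric is the slope, only subjects with a significant precession
    fit enter (a non-significant fit's slope is not interpretable). Returns
    the overall model F, the predictor coefficient b, the multiple
    correlation R of the adjusted model, and the predictor's p-value.
    """
    records = validate_cohort(records)
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if metric == "slope":
        records = records[records["significant"].astype(bool)]
    if len(records) < 10:
        raise InsufficientDataError(
            f"need >= 10 records for the regression, got {len(records)}")
    X, names = _design(records, predictor)
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise CollinearityError(f"rank-deficient design with columns {names}")
    fit = sm.OLS(records[metric].to_numpy(dtype=float), exog).fit()
    return {
        "F": float(fit.fvalue),
        "b": float(fit.params[1]),
        "R_model": float(np.sqrt(max(fit.rsquared, 0.0))),
        "p": float(fit.pvalues[1]),
        "n": int(len(records)),
        "predictor": names[0],
        "metric": metric,
    }


def quartile_significance_test(records: pd.DataFrame) -> dict[str, float]:
    """Compare significant-precession proportions in the youngest vs oldest
    age quartile with a 2x2 Pearson chi-square (no continuity correction).

    Quartile bounds are sample quantiles with linear interpolation; subjects
    at or below Q1 are "young", at or above Q3 "old".
    """
    records = validate_cohort(records)
    if len(records) < 8:
        raise InsufficientDataError("need >= 8 records for quartile comparison")
    q1, q3 = np.quantile(records["age"].to_numpy(dtype=float), [0.25, 0.75])
    young = records[records["age"] <= q1]
    old = records[records["age"] >= q3]
    if len(young) == 0 or len(old) == 0:
        raise InsufficientDataError("empty age quartile")
    sig_y = int(young["significant"].astype(bool).sum())
    sig_o = int(old["significant"].astype(bool).sum())
    table = np.array([[sig_y, len(young) - sig_y],
                      [sig_o, len(old) - sig_o]])
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return {
        "prop_young": sig_y / len(young),
        "prop_old": sig_o / len(old),
        "chi2": float(chi2),
        "p": float(p),
        "n_young": len(young),
        "n_old": len(old),
        "age_q1": float(q1),
        "age_q3": float(q3),
    }


def pearson_chi2(table: Iterable[Iterable[int]]) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) of a contingency table."""
    chi2, p, _, _ = chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def cohort_summary(records: pd.DataFrame) -> dict:
    """Proportion significant; mean +/- sd slope among significant fits;
    counts by group and sex."""
    records = validate_cohort(records)
    if len(records) == 0:
        raise InsufficientDataError("empty cohort")
    sig = records[records["significant"].astype(bool)]
    slopes = sig["slope"].to_numpy(dtype=float)
    return {
        "n": int(len(records)),
        "prop_significant": float(len(sig) / len(records)),
        "slope_mean": float(slopes.mean()) if slopes.size else None,
        "slope_sd": float(slopes.std(ddof=1)) if slopes.size > 1 else (
            0.0 if slopes.size == 1 else None),
        "counts_by_group": records["group"].value_counts().to_dict(),
        "counts_by_sex": records["sex"].value_counts().to_dict(),
    }
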