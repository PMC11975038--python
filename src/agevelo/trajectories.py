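"""Aging velocities and years-aged from clock predictions.

The aging *velocity* of a donor is the slope of an ordinary least-squares
regression of predicted biological age on chronological time: 1x means the
clock tracks calendar time, 8.5x means 8.5 biological years per calendar
year.  For cultured samples the chronological axis is the donor's baseline
age plus time in culture converted from months to decimal years (month m at
baseline 55 gives 55, 55.083, 55.167, ...).  *Years aged* over an interval is
the plain difference of predicted ages between two timepoints of one donor.

The cohort-level "average velocity" is the unweighted mean of per-donor
slopes, not the slope of the pooled scatter — pooling would conflate donor
baseline offsets with the time trend.  A pooled (``group_by="cohort"``) mode
remains available and is what a cross-sectional in-vivo cohort uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .errors import AgeVeloError, DomainError

MONTHS_PER_YEAR = 12.0


def _time_axis(sheet: pd.DataFrame) -> pd.Series:
    """Chronological age in years for every sheet row."""
    base = sheet["chronological_age_at_baseline"].astype(float)
    culture = sheet["time_in_culture"].astype(float) / MONTHS_PER_YEAR
    return base + culture


def _merged(predictions: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    preds = predictions.reset_index() if predictions.index.name == "sample_id" \
        else predictions.copy()
    if "sample_id" not in preds.columns:
        raise AgeVeloError("predictions need a 'sample_id' index or column")
    merged = preds.merge(sheet, on="sample_id", how="inner")
    if merged.empty:
        raise AgeVeloError("no overlap between predictions and sample sheet")
    merged["time_years"] = _time_axis(merged)
    return merged


def fit_velocity(predictions: pd.DataFrame, sheet: pd.DataFrame,
                 group_by: str = "donor") -> pd.DataFrame:
    """OLS slope of predicted age on chronological time, per donor or pooled.

    Returns one row per group with slope (the velocity), intercept,
    r_squared, two-sided p-value for the slope (t distribution on n-2 df),
    and the number of points.
    """
    if group_by not in ("donor", "cohort"):
        raise AgeVeloError(f"group_by must be 'donor' or 'cohort', got {group_by!r}")
    merged = _merged(predictions, sheet)

    groups = ([("cohort", merged)] if group_by == "cohort"
              else list(merged.groupby("donor_id")))
    rows = []
    for gid, sub in groups:
        t = sub["time_years"].to_numpy(dtype=float)
        y = sub["predicted_age"].to_numpy(dtype=float)
        if len(t) < 2:
            raise DomainError(f"group {gid!r}: need >= 2 time points, got {len(t)}")
        if np.ptp(t) == 0:
            raise DomainError(f"group {gid!r}: zero variance in chronological time")
        fit = scipy.stats.linregress(t, y)
        assays = sorted(sub["assay"].unique())
        rows.append({
            "donor_id": gid,
            "assay": assays[0] if len(assays) == 1 else "mixed",
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.rvalue ** 2,
            "p_value": fit.pvalue,
            "n_points": len(t),
        })
    return pd.DataFrame(rows)


def average_velocity(fits: pd.DataFrame) -> dict:
    """Unweighted mean +/- SD of per-donor slopes."""
    if len(fits) == 0:
        raise AgeVeloError("average_velocity: empty fit table")
    slopes = fits["slope"].to_numpy(dtype=float)
    single = len(slopes) < 2
    return {
        "mean": float(np.mean(slopes)),
        "sd": 0.0 if single else float(np.std(slopes, ddof=1)),
        "sd_defined": not single,
        "n": len(slopes),
    }


def years_aged(predictions: pd.DataFrame, sheet: pd.DataFrame,
               t0: float, t1: float) -> pd.DataFrame:
    """Predicted-age difference between two culture timepoints per donor."""
    if t1 == t0:
        raise DomainError("years_aged: interval must be nonzero")
    merged = _merged(predictions, sheet)
    rows = []
    for donor, sub in merged.groupby("donor_id"):
        picks = {}
        for t in (t0, t1):
            match = sub[np.isclose(sub["time_in_culture"].astype(float), t)]
            if match.empty:
                raise AgeVeloError(
                    f"donor {donor!r}: no sample at time_in_culture={t}")
            picks[t] = match["predicted_age"].mean()
        assays = sorted(sub["assay"].unique())
        rows.append({
            "donor_id": donor,
            "assay": assays[0] if len(assays) == 1 else "mixed",
            "delta": picks[t1] - picks[t0],
            "interval": abs(t1 - t0),
        })
    return pd.DataFrame(rows)


def prediction_error_summary(predictions: pd.DataFrame,
                             sheet: pd.DataFrame) -> dict:
    """Mean +/- SD of (predicted - chronological) age across samples."""
    merged = _merged(predictions, sheet)
    offsets = (merged["predicted_age"] - merged["time_years"]).to_numpy(float)
    return {
        "mean_offset": float(np.mean(offsets)),
        "sd_offset": float(np.std(offsets, ddof=1)) if len(offsets) > 1 else 0.0,
        "n": len(offsets),
    }
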