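"""Adherence filtering and weekly feature assembly.

Daily tracker records become one fixed-length observation per patient-week
by "unmelting": each of the 15 feature columns splits into 7 day columns,
giving a 105-slot vector x_t aligned with the week's PRO survey.  Weeks
with at least 3 missing days for any feature are dropped; patients with 3
or more dropped weeks (i.e. more than 2) are excluded; remaining gaps are
imputed from the same patient's previous-week feature mean.

Slot ordering is feature-major and fixed — ``f_d1 .. f_d7`` for feature
``f`` in the canonical feature order — so per-feature aggregation of model
importances is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PreprocessConfig
from .synthetic import FEATURE_NAMES, HR_FEATURES, TABLE1_FEATURES

__all__ = [
    "WeeklyObservations",
    "slot_columns",
    "aggregate_day",
    "unmelt_weekly",
    "flag_dropped_weeks",
    "exclude_patients",
    "impute_missing",
    "remelt_daily",
    "preprocess_daily",
]

KEY_COLS = ["patient_id", "week_index"]


def slot_columns(features: Sequence[str]) -> list[str]:
    """Feature-major 105-slot column names: f1_d1..f1_d7, f2_d1, ..."""
    return [f"{f}_d{d}" for f in features for d in range(1, 8)]


def feature_of_slot(slot: str) -> str:
    return slot.rsplit("_d", 1)[0]


@dataclass
class WeeklyObservations:
    """Per-patient-week observations after unmelting.

    ``data`` holds the keys, the slot columns and a ``dropped`` flag;
    ``imputed`` is a boolean frame over the same index/slots recording
    which values were filled by imputation.
    """

    data: pd.DataFrame
    features: list[str]
    imputed: pd.DataFrame | None = None

    @property
    def slots(self) -> list[str]:
        return slot_columns(self.features)

    def copy(self) -> "WeeklyObservations":
        return WeeklyObservations(
            self.data.copy(),
            list(self.features),
            None if self.imputed is None else self.imputed.copy(),
        )

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        if self.imputed is not None:
            filled = self.imputed.to_numpy()
            names = np.array(self.slots)
            out["imputed_slots"] = [
                ";".join(names[row]) for row in filled
            ]
        out.to_csv(path, index=False)


def aggregate_day(
    minute_records: pd.DataFrame,
    boundary_hour: float = 20.0,
) -> pd.DataFrame:
    """Aggregate a timestamped minute-level stream into daily feature rows.

    A "day" is the 24-hour interval from ``boundary_hour`` (default 8 PM)
    to the same time next day, labelled by the calendar date containing the
    interval's *end*.  Duration/count features are summed, with records
    spanning the boundary split proportionally; heart-rate features take
    the min (``hr_min``) or max (``hr_max``) of the samples in the
    interval.

    ``minute_records`` columns: ``patient_id``, ``timestamp`` (datetime),
    ``feature``, ``value`` and optional ``duration_mins`` (0 for point
    samples).
    """
    df = minute_records.copy()
    if df.empty:
        return pd.DataFrame(columns=["patient_id", "day", "feature", "value"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if "duration_mins" not in df.columns:
        df["duration_mins"] = 0.0
    shift = pd.Timedelta(hours=24.0 - boundary_hour)

    pieces = []
    for _, row in df.iterrows():
        start = row["timestamp"]
        dur = float(row["duration_mins"])
        feat = row["feature"]
        if feat in HR_FEATURES or dur <= 0:
            day = (start + shift).normalize()
            pieces.append((row["patient_id"], day, feat, float(row["value"]), 1.0))
            continue
        # split the [start, start+dur) span at day boundaries, pro rata
        end = start + pd.Timedelta(minutes=dur)
        cur = start
        while cur < end:
            day = (cur + shift).normalize()
            # the day's real-time window is [day - shift, day - shift + 24h)
            interval_end = day - shift + pd.Timedelta(hours=24)
            seg_end = min(end, interval_end)
            frac = (seg_end - cur) / (end - start)
            pieces.append(
                (row["patient_id"], day, feat, float(row["value"]) * frac, frac)
            )
            cur = seg_end

    long = pd.DataFrame(
        pieces, columns=["patient_id", "day", "feature", "value", "w"]
    )

    def _agg(g: pd.DataFrame) -> float:
        feat = g.name[2]
        if feat == "hr_min":
            return float(g["value"].min())
        if feat == "hr_max":
            return float(g["value"].max())
        return float(g["value"].sum())

    agg = (
        long.groupby(["patient_id", "day", "feature"])
        .apply(_agg, include_groups=False)
        .rename("value")
        .reset_index()
    )
    return agg


def unmelt_weekly(
    daily: pd.DataFrame, features: Sequence[str] | None = None
) -> WeeklyObservations:
    """Pivot daily rows into one 105-slot row per patient-week.

    Absent patient-days become missing (NaN) slots; values are never
    altered.  Duplicate (patient, week, day) keys are a hard error.
    """
    if features is None:
        features = [c for c in FEATURE_NAMES if c in daily.columns]
    features = list(features)
    keys = ["patient_id", "week_index", "day_of_week"]
    dup = daily.duplicated(subset=keys)
    if dup.any():
        bad = daily.loc[dup, keys].iloc[0].tolist()
        raise ValueError(f"duplicate daily record for (patient, week, day) = {bad}")

    df = daily.copy()
    # days masked as unworn carry NaNs already; respect an explicit worn flag
    if "worn" in df.columns:
        df.loc[~df["worn"].astype(bool), features] = np.nan

    wide = df.pivot(index=KEY_COLS, columns="day_of_week", values=features)
    # wide columns: (feature, day); reorder feature-major
    cols = {}
    for f in features:
        for d in range(1, 8):
            col = f"{f}_d{d}"
            cols[col] = wide[(f, d)] if (f, d) in wide.columns else np.nan
    out = pd.DataFrame(cols, index=wide.index).reset_index()
    out["dropped"] = False
    return WeeklyObservations(out, features)


def flag_dropped_weeks(
    weekly: WeeklyObservations, missing_day_threshold: int = 3
) -> WeeklyObservations:
    """Drop a week when any feature misses at least ``missing_day_threshold``
    of its 7 day-slots.  Assessed on raw (pre-imputation) missingness."""
    wk = weekly.copy()
    dropped = np.zeros(len(wk.data), dtype=bool)
    for f in wk.features:
        cols = [f"{f}_d{d}" for d in range(1, 8)]
        n_missing = wk.data[cols].isna().sum(axis=1).to_numpy()
        dropped |= n_missing >= missing_day_threshold
    wk.data["dropped"] = dropped
    return wk


def exclude_patients(
    weekly: WeeklyObservations, dropped_week_threshold: int = 3
) -> WeeklyObservations:
    """Remove every week of patients with >= ``dropped_week_threshold``
    dropped weeks; retained patients keep their dropped weeks flagged."""
    wk = weekly.copy()
    n_dropped = wk.data.groupby("patient_id")["dropped"].sum()
    keep = n_dropped[n_dropped < dropped_week_threshold].index
    wk.data = wk.data[wk.data["patient_id"].isin(keep)].reset_index(drop=True)
    return wk


def impute_missing(
    weekly: WeeklyObservations,
    impute_from_dropped_weeks: bool = True,
    cohort_fallback: bool = True,
) -> WeeklyObservations:
    """Fill missing slots of retained, non-dropped weeks.

    Each missing slot takes the mean of the same feature's non-missing
    day-slots from the patient's immediately preceding week (by default
    even if that week was dropped — its observed values are still
    informative).  Fallbacks, in order: the patient's own mean of the
    feature over all their observed days, then the cohort feature mean.
    The returned ``imputed`` mask records every filled slot.
    """
    wk = weekly.copy()
    df = wk.data.sort_values(KEY_COLS).reset_index(drop=True)
    slots = wk.slots
    imputed = pd.DataFrame(False, index=df.index, columns=slots)
    active = ~df["dropped"].to_numpy(dtype=bool)

    for f in wk.features:
        cols = [f"{f}_d{d}" for d in range(1, 8)]
        block = df[cols]
        # previous calendar week's per-feature mean, per patient
        week_mean = block.mean(axis=1)
        if not impute_from_dropped_weeks:
            week_mean = week_mean.where(~df["dropped"])
        lookup = pd.Series(
            week_mean.values,
            index=pd.MultiIndex.from_frame(df[KEY_COLS]),
        )
        prev_key = pd.MultiIndex.from_arrays([df["patient_id"], df["week_index"] - 1])
        prev_mean = pd.Series(lookup.reindex(prev_key).to_numpy(), index=df.index)
        per_patient = (
            df.assign(_fmean=week_mean, _fn=block.notna().sum(axis=1))
            .groupby("patient_id", sort=False)
            .apply(
                lambda g: np.nansum(g["_fmean"] * g["_fn"]) / g["_fn"].sum()
                if g["_fn"].sum() > 0
                else np.nan,
                include_groups=False,
            )
        )
        patient_mean = df["patient_id"].map(per_patient)
        fill = prev_mean.fillna(patient_mean)
        if cohort_fallback:
            vals = block.to_numpy()
            cohort_mean = (
                np.nanmean(vals)
                if np.isfinite(vals).any()
                else TABLE1_FEATURES.get(f, (np.nan,))[0]
            )
            fill = fill.fillna(cohort_mean)
        for c in cols:
            missing = df[c].isna().to_numpy() & active
            df.loc[missing, c] = fill[missing]
            imputed.loc[missing, c] = True

    wk.data = df
    wk.imputed = imputed
    return wk


def remelt_daily(weekly: WeeklyObservations) -> pd.DataFrame:
    """Inverse of :func:`unmelt_weekly` (for round-trip checks)."""
    rows = []
    for _, r in weekly.data.iterrows():
        for d in range(1, 8):
            row = {
                "patient_id": r["patient_id"],
                "week_index": r["week_index"],
                "day_of_week": d,
            }
            for f in weekly.features:
                row[f] = r[f"{f}_d{d}"]
            rows.append(row)
    return pd.DataFrame(rows)


def preprocess_daily(
    daily: pd.DataFrame, config: PreprocessConfig | None = None
) -> WeeklyObservations:
    """Full weekly-assembly pipeline: unmelt, flag dropped weeks, exclude
    non-adherent patients, impute the remaining gaps."""
    cfg = config or PreprocessConfig()
    wk = unmelt_weekly(daily)
    wk = flag_dropped_weeks(wk, cfg.missing_day_threshold)
    wk = exclude_patients(wk, cfg.dropped_week_threshold)
    wk = impute_missing(
        wk,
        impute_from_dropped_weeks=cfg.impute_from_dropped_weeks,
        cohort_fallback=cfg.cohort_fallback,
    )
    return wk
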