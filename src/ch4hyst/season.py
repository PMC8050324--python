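"""Frost-free-season detection and earlier/later branch splitting.

The analysis window of a site-year is the longest run of days on which the
chosen driver exceeds its threshold (air or soil temperature > 0 degC, or a
GPP-based alternative).  Interior cold snaps of up to ``gap_tolerance``
below-threshold days do not break the run, but those days are excluded from
fitting.  The season splits into an *earlier* (warming) and a *later*
(cooling) branch at the day of the seasonal driver maximum; the maximum day
itself belongs to the earlier branch, and ties go to the earliest date.

Southern-hemisphere sites use a 1 July - 30 June season-year window so one
austral season stays contiguous; the season-year label is the starting
calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DailySeries, NUMERIC_FIELDS
from .errors import AnchorError, NoSeasonError

THRESHOLD_MODES = ("temp_above_zero", "gpp_above_zero", "gpp_above_5pct_max")
DRIVERS = ("t_air", "t_soil_shallow", "t_soil_deep")


@dataclass(frozen=True)
class SeasonPolicy:
    """How the analysis season is delimited."""

    threshold_mode: str = "temp_above_zero"
    driver: str = "t_air"
    hemisphere_wrap: bool = True
    min_season_days: int = 30
    resolution: str = "daily"
    gap_tolerance: int = 3  # interior below-threshold days tolerated; 0 = strict

    def __post_init__(self) -> None:
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"threshold_mode must be one of {THRESHOLD_MODES}")
        if self.driver not in DRIVERS:
            raise ValueError(f"driver must be one of {DRIVERS}")
        if self.resolution not in ("daily", "monthly"):
            raise ValueError("resolution must be 'daily' or 'monthly'")


@dataclass
class FrostFreeSeason:
    """One site-year's analysis window with its branch split."""

    site_id: str
    season_year: int
    day_indices: pd.DatetimeIndex
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    t_max: float
    t_max_day: pd.Timestamp
    f_at_tmax: float
    earlier_indices: pd.DatetimeIndex
    later_indices: pd.DatetimeIndex
    driver: str = "t_air"
    degenerate_branch: bool = False

    def __len__(self) -> int:
        return len(self.day_indices)


def season_year_window(year: int, southern: bool) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Calendar window of one season-year (Jul-Jun when ``southern``)."""
    if southern:
        return pd.Timestamp(year, 7, 1), pd.Timestamp(year + 1, 6, 30)
    return pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31)


def _threshold_mask(df: pd.DataFrame, policy: SeasonPolicy) -> pd.Series:
    if policy.threshold_mode == "temp_above_zero":
        return df[policy.driver] > 0.0
    gpp = df["gpp"]
    if policy.threshold_mode == "gpp_above_zero":
        return gpp > 0.0
    gmax = gpp.max()
    if not np.isfinite(gmax) or gmax <= 0:
        return pd.Series(False, index=df.index)
    return gpp > 0.05 * gmax


def _longest_run(mask: np.ndarray, gap_tolerance: int) -> np.ndarray | None:
    """Positions of above-threshold days in the longest tolerant run.

    Runs are clusters of True positions where consecutive True days are at most
    ``gap_tolerance + 1`` apart; the longest counts above-threshold days, ties
    going to the earlier run.
    """
    pos = np.flatnonzero(mask)
    if pos.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(pos) > gap_tolerance + 1)
    clusters = np.split(pos, breaks + 1)
    sizes = [c.size for c in clusters]
    return clusters[int(np.argmax(sizes))]


def _anchor_flux(df: pd.DataFrame, season_days: pd.DatetimeIndex,
                 t_max_day: pd.Timestamp, t_max: float, driver: str) -> float:
    """Flux anchor at the seasonal maximum, with nearest-day fallback.

    When the flux is missing on the maximum day, the anchor is the mean flux
    over the nearest (<=2 per side) season days whose driver lies within 1 degC
    of the maximum; if no such day exists the site-year is unusable.
    """
    f = df.loc[t_max_day, "f_ch4"]
    if np.isfinite(f):
        return float(f)
    before = [d for d in season_days if d < t_max_day]
    after = [d for d in season_days if d > t_max_day]
    candidates = []
    for side in (before[::-1], after):
        taken = 0
        for d in side:
            if taken >= 2:
                break
            fv = df.loc[d, "f_ch4"]
            tv = df.loc[d, driver]
            if np.isfinite(fv) and np.isfinite(tv) and abs(tv - t_max) <= 1.0:
                candidates.append(float(fv))
                taken += 1
    if not candidates:
        raise AnchorError(f"no flux anchor near seasonal maximum on {t_max_day.date()}")
    return float(np.mean(candidates))


def extract_season(
    series: DailySeries,
    policy: SeasonPolicy,
    year_label: int,
    latitude: float | None = None,
) -> FrostFreeSeason:
    """Detect one site-year's frost-free (or GPP-thresholded) season.

    Raises :class:`NoSeasonError` when no above-threshold day exists or the
    longest run is shorter than ``min_season_days``, and :class:`AnchorError`
    when the flux anchor at the driver maximum cannot be determined.
    """
    if latitude is None and series.meta is not None:
        latitude = series.meta.latitude
    southern = bool(policy.hemisphere_wrap and latitude is not None and latitude < 0)
    start, end = season_year_window(year_label, southern)
    df = series.data.loc[(series.data.index >= start) & (series.data.index <= end)]
    if df.empty:
        raise NoSeasonError(f"{series.site_id} {year_label}: no data in window")

    mask = _threshold_mask(df, policy).fillna(False).to_numpy(dtype=bool)
    run = _longest_run(mask, policy.gap_tolerance)
    if run is None:
        raise NoSeasonError(f"{series.site_id} {year_label}: no above-threshold day")
    season_days = df.index[run]
    if len(season_days) < policy.min_season_days:
        raise NoSeasonError(
            f"{series.site_id} {year_label}: season of {len(season_days)} days "
            f"shorter than {policy.min_season_days}"
        )

    drv = df.loc[season_days, policy.driver].to_numpy(dtype=float)
    i_max = int(np.argmax(drv))  # argmax returns the first maximum: earliest tie-break
    t_max = float(drv[i_max])
    t_max_day = season_days[i_max]
    f_at_tmax = _anchor_flux(df, season_days, t_max_day, t_max, policy.driver)

    season = FrostFreeSeason(
        site_id=series.site_id,
        season_year=year_label,
        day_indices=season_days,
        start_date=season_days[0],
        end_date=season_days[-1],
        t_max=t_max,
        t_max_day=t_max_day,
        f_at_tmax=f_at_tmax,
        earlier_indices=season_days[: i_max + 1],
        later_indices=season_days[i_max + 1 :],
        driver=policy.driver,
    )
    season.degenerate_branch = len(season.later_indices) == 0
    return season


def split_branches(season: FrostFreeSeason) -> tuple[pd.DatetimeIndex, pd.DatetimeIndex]:
    """Earlier (up to and including the maximum day) and later branch days."""
    return season.earlier_indices, season.later_indices


def aggregate_monthly(series: DailySeries, min_valid_days: int = 15) -> pd.DataFrame:
    """Calendar-month means of each numeric field over non-missing days.

    A month with fewer than ``min_valid_days`` valid days for a field is
    missing for that field.  The result is indexed by month-start dates so it
    can be fed through the same season/branch machinery at monthly resolution.
    """
    df = series.data
    grouper = pd.Grouper(freq="MS")
    means = df[list(NUMERIC_FIELDS)].groupby(grouper).mean()
    counts = df[list(NUMERIC_FIELDS)].groupby(grouper).count()
    return means.where(counts >= min_valid_days)
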