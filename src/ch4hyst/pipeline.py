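"""End-to-end site-year analysis: QC -> season -> branch fits -> H_A / H_mu.

`analyze_site_year` turns one site's daily series and one season-year label
into a :class:`~ch4hyst.hysteresis.HysteresisResult`; `analyze_dataset` loops
it over a whole network and additionally returns the day-level table (one row
per analyzable season day, with site / season-year / branch labels) that the
tiered model comparison and the hybrid model consume.  Site-years that fail
(no season, missing anchor, too few branch days) are skipped with a logged
reason rather than aborting the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DailySeries, QCPolicy, SiteMeta, apply_qc
from .errors import AnchorError, DegenerateFitError, NoSeasonError
from .hysteresis import (
    HysteresisResult,
    classify_sign,
    fit_branch,
    hysteresis_area,
    hysteresis_mean,
)
from .season import FrostFreeSeason, SeasonPolicy, extract_season

logger = logging.getLogger(__name__)


@dataclass
class SkipRecord:
    site_id: str
    season_year: int
    reason: str


def _branch_values(series: DailySeries, season: FrostFreeSeason, idx, driver: str):
    sub = series.data.loc[idx, [driver, "f_ch4"]]
    sub = sub.dropna()
    return sub[driver].to_numpy(float), sub["f_ch4"].to_numpy(float), sub.index


def analyze_site_year(
    series: DailySeries,
    year_label: int,
    season_policy: SeasonPolicy | None = None,
    qc_policy: QCPolicy | None = None,
    qc_applied: bool = False,
) -> tuple[HysteresisResult, pd.DataFrame]:
    """Full hysteresis analysis of one site-year.

    Returns the result plus the day-level table of analyzable season days
    (columns: date, driver value ``t``, flux ``f``, branch label).  Raises the
    pipeline's domain errors when the site-year is not analyzable.
    """
    season_policy = season_policy or SeasonPolicy()
    qc_policy = qc_policy or QCPolicy()
    if not qc_applied:
        series = apply_qc(series, qc_policy)
    season = extract_season(series, season_policy, year_label)
    if season.t_max <= 0:
        raise NoSeasonError(f"{series.site_id} {year_label}: non-positive seasonal maximum")

    driver = season_policy.driver
    te, fe, ide = _branch_values(series, season, season.earlier_indices, driver)
    tl, fl, idl = _branch_values(series, season, season.later_indices, driver)
    if len(te) < qc_policy.min_days_per_branch or len(tl) < qc_policy.min_days_per_branch:
        raise DegenerateFitError(
            f"{series.site_id} {year_label}: branch days "
            f"({len(te)}, {len(tl)}) below minimum {qc_policy.min_days_per_branch}"
        )

    fit_e = fit_branch(te, fe, season.t_max, season.f_at_tmax, branch="earlier")
    fit_l = fit_branch(tl, fl, season.t_max, season.f_at_tmax, branch="later")
    h_a = hysteresis_area(fit_e, fit_l)
    h_mu = hysteresis_mean(fe, fl)

    meta = series.meta
    result = HysteresisResult(
        site_id=series.site_id,
        season_year=year_label,
        driver=driver,
        h_area=h_a,
        h_mu=h_mu,
        fit_earlier=fit_e,
        fit_later=fit_l,
        sign=classify_sign(h_a),
        season_start=season.start_date,
        season_end=season.end_date,
        ecosystem_type=meta.ecosystem_type if meta else None,
        latitude=meta.latitude if meta else None,
    )

    days = pd.DataFrame(
        {
            "date": np.concatenate([ide.to_numpy(), idl.to_numpy()]),
            "t": np.concatenate([te, tl]),
            "f": np.concatenate([fe, fl]),
            "branch": ["earlier"] * len(te) + ["later"] * len(tl),
        }
    )
    days["site_id"] = series.site_id
    days["season_year"] = year_label
    if meta is not None:
        days["ecosystem_type"] = meta.ecosystem_type
    return result, days


def candidate_years(series: DailySeries, southern: bool) -> list[int]:
    idx = series.data.index
    if len(idx) == 0:
        return []
    years = sorted(set(idx.year))
    if southern:
        return sorted({y for y in range(min(years) - 1, max(years) + 1)})
    return years


def analyze_dataset(
    dataset: dict[str, DailySeries],
    season_policy: SeasonPolicy | None = None,
    qc_policy: QCPolicy | None = None,
):
    """Analyze every site-year of a network.

    Returns ``(results, day_table, skipped)`` where ``day_table`` stacks the
    per-site-year day tables and ``skipped`` records every site-year that
    could not be analyzed, with its reason.
    """
    season_policy = season_policy or SeasonPolicy()
    qc_policy = qc_policy or QCPolicy()
    results: list[HysteresisResult] = []
    tables: list[pd.DataFrame] = []
    skipped: list[SkipRecord] = []
    for site_id, series in dataset.items():
        qc_series = apply_qc(series, qc_policy)
        lat = series.meta.latitude if series.meta else None
        southern = bool(
            season_policy.hemisphere_wrap and lat is not None and lat < 0
        )
        for year in candidate_years(qc_series, southern):
            try:
                res, days = analyze_site_year(
                    qc_series, year, season_policy, qc_policy, qc_applied=True
                )
            except (NoSeasonError, AnchorError, DegenerateFitError) as exc:
                skipped.append(SkipRecord(site_id, year, str(exc)))
                logger.info("skipping %s %s: %s", site_id, year, exc)
                continue
            results.append(res)
            tables.append(days)
    day_table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=["date", "t", "f", "branch", "site_id", "season_year", "ecosystem_type"]
        )
    )
    return results, day_table, skipped


def results_to_frame(results) -> pd.DataFrame:
    """Tabulate a collection of hysteresis results (one row per site-year)."""
    rows = []
    for r in results:
        rows.append(
            {
                "site_id": r.site_id,
                "season_year": r.season_year,
                "driver": r.driver,
                "ecosystem_type": r.ecosystem_type,
                "latitude": r.latitude,
                "h_area": r.h_area,
                "h_mu": r.h_mu,
                "a_early": r.fit_earlier.a_hys,
                "a_late": r.fit_later.a_hys,
                "t_max": r.fit_earlier.t_max,
                "f_at_tmax": r.fit_earlier.f_at_tmax,
                "n_earlier": r.fit_earlier.n_points,
                "n_later": r.fit_later.n_points,
                "sign": r.sign,
            }
        )
    return pd.DataFrame(rows)


def positive_fraction(results) -> float:
    """Fraction of site-years with positive H_A."""
    signs = [r.sign for r in results]
    if not signs:
        return float("nan")
    return sum(s == "positive" for s in signs) / len(signs)
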