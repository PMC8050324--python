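"""Core records, FLUXNET-CH4-style daily CSV I/O, and quality control.

The daily product is a plain CSV with a header row, one row per day, missing
values encoded as ``-9999`` or empty cells.  Default column names follow the
FLUXNET daily dialect (``TIMESTAMP, TA, TS_1, TS_2, FCH4, FCH4_F, GPP, WTD,
P, WS, PA``); other dialects are handled through a column-remap dict.

Sign and unit conventions
-------------------------
* CH4 flux ``f_ch4`` is in mg C m-2 d-1 and may be negative (uptake).
* Water-table depth ``wtd`` is in cm, positive when the water table stands
  above the soil surface, negative below.
* ``FCH4_F`` is read as a per-day boolean gap-fill flag (nonzero = gap-filled);
  when the column is absent every day is treated as measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

ECOSYSTEM_TYPES = frozenset(
    {"bog", "fen", "marsh", "peat_plateau", "rice", "salt_marsh", "swamp", "wet_tundra"}
)

MISSING_SENTINEL = -9999.0

#: canonical internal field -> default CSV column
DEFAULT_COLUMNS = {
    "t_air": "TA",
    "t_soil_shallow": "TS_1",
    "t_soil_deep": "TS_2",
    "f_ch4": "FCH4",
    "f_ch4_gapfilled": "FCH4_F",
    "gpp": "GPP",
    "wtd": "WTD",
    "precip": "P",
    "wind_speed": "WS",
    "pressure": "PA",
}

NUMERIC_FIELDS = (
    "t_air",
    "t_soil_shallow",
    "t_soil_deep",
    "f_ch4",
    "gpp",
    "wtd",
    "precip",
    "wind_speed",
    "pressure",
)


@dataclass(frozen=True)
class SiteMeta:
    """Static description of one flux-tower site."""

    site_id: str
    ecosystem_type: str
    latitude: float
    longitude: float = float("nan")

    def __post_init__(self) -> None:
        if self.ecosystem_type not in ECOSYSTEM_TYPES:
            raise ValueError(
                f"unknown ecosystem type {self.ecosystem_type!r}; "
                f"expected one of {sorted(ECOSYSTEM_TYPES)}"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")


@dataclass
class DailySeries:
    """One site's daily observations: drivers, fluxes, and QC flags.

    ``data`` is indexed by calendar date (strictly increasing) and carries the
    canonical numeric fields plus a boolean ``f_ch4_gapfilled`` column; columns
    the reader did not recognise are preserved untouched.
    """

    site_id: str
    data: pd.DataFrame
    meta: SiteMeta | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx) and not idx.is_monotonic_increasing:
            raise IntegrityError(f"{self.site_id}: dates are not increasing")
        if idx.has_duplicates:
            raise IntegrityError(f"{self.site_id}: duplicate dates")
        for col in NUMERIC_FIELDS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        if "f_ch4_gapfilled" not in self.data.columns:
            self.data["f_ch4_gapfilled"] = False

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "DailySeries":
        return DailySeries(self.site_id, self.data.copy(), self.meta)


@dataclass(frozen=True)
class QCPolicy:
    """What counts as an analyzable day and how small a branch may be."""

    use_gapfilled: bool = False
    min_days_per_branch: int = 10
    required_fields: frozenset = frozenset({"t_air", "f_ch4"})

    def __post_init__(self) -> None:
        if self.min_days_per_branch < 3:
            raise ValueError("min_days_per_branch must be >= 3")
        object.__setattr__(self, "required_fields", frozenset(self.required_fields))


def _parse_timestamps(raw: pd.Series) -> pd.DatetimeIndex:
    s = raw.astype(str).str.strip()
    # YYYYMMDD integers or ISO dates
    if s.str.fullmatch(r"\d{8}").all():
        parsed = pd.to_datetime(s, format="%Y%m%d", errors="coerce")
    else:
        parsed = pd.to_datetime(s, errors="coerce")
    if parsed.isna().any():
        bad = s[parsed.isna()].iloc[0]
        raise FormatError(f"unparseable timestamp {bad!r}")
    return pd.DatetimeIndex(parsed)


def read_daily_table(
    path,
    meta: SiteMeta | None = None,
    column_map: dict | None = None,
    timestamp_column: str = "TIMESTAMP",
) -> DailySeries:
    """Read one site's daily CSV into a :class:`DailySeries`.

    ``column_map`` overrides entries of :data:`DEFAULT_COLUMNS` (canonical
    field -> CSV column) for non-default dialects.  ``-9999`` and empty cells
    become missing; unknown columns are kept as opaque extras.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    raw = pd.read_csv(path, na_values=[MISSING_SENTINEL, str(int(MISSING_SENTINEL))])
    if timestamp_column not in raw.columns:
        raise FormatError(f"missing timestamp column {timestamp_column!r} in {path}")
    idx = _parse_timestamps(raw[timestamp_column])
    if idx.has_duplicates:
        raise IntegrityError(f"duplicate dates in {path}")
    if len(idx) and not idx.is_monotonic_increasing:
        raise IntegrityError(f"non-monotone dates in {path}")

    df = pd.DataFrame(index=idx)
    used = {timestamp_column}
    for field_name, col in cols.items():
        if col in raw.columns:
            used.add(col)
            if field_name == "f_ch4_gapfilled":
                flag = pd.to_numeric(raw[col], errors="coerce").fillna(0.0)
                df[field_name] = (flag != 0).to_numpy()
            else:
                df[field_name] = pd.to_numeric(raw[col], errors="coerce").to_numpy()
    for col in raw.columns:
        if col not in used:
            df[col] = raw[col].to_numpy()
    site_id = meta.site_id if meta is not None else str(path)
    return DailySeries(site_id=site_id, data=df, meta=meta)


def read_site_metadata(path) -> dict[str, SiteMeta]:
    """Read the site-metadata CSV (``SITE_ID, TYPE, LAT, LON``)."""
    raw = pd.read_csv(path)
    needed = {"SITE_ID", "TYPE", "LAT"}
    if not needed.issubset(raw.columns):
        raise FormatError(f"site metadata must carry columns {sorted(needed)}")
    out: dict[str, SiteMeta] = {}
    for _, row in raw.iterrows():
        sid = str(row["SITE_ID"])
        if sid in out:
            raise IntegrityError(f"duplicate site id {sid!r}")
        out[sid] = SiteMeta(
            site_id=sid,
            ecosystem_type=str(row["TYPE"]),
            latitude=float(row["LAT"]),
            longitude=float(row["LON"]) if "LON" in raw.columns else float("nan"),
        )
    return out


def apply_qc(series: DailySeries, policy: QCPolicy) -> DailySeries:
    """Return a QC-filtered copy; the input series is left unmodified.

    Gap-filled flux days are masked unless ``use_gapfilled``; a day missing any
    required field has its flux masked so it drops out of every analysis.
    Idempotent: applying the same policy twice changes nothing further.
    """
    out = series.copy()
    df = out.data
    mask = pd.Series(False, index=df.index)
    if not policy.use_gapfilled:
        mask |= df["f_ch4_gapfilled"].astype(bool)
    for field_name in policy.required_fields:
        mask |= df[field_name].isna()
    df.loc[mask, "f_ch4"] = np.nan
    return out


def analyzable_days(series: DailySeries) -> int:
    """Days with a usable (non-missing, QC-passing) flux value."""
    return int(series.data["f_ch4"].notna().sum())


SUMMARY_COLUMNS = [
    "site_id",
    "season_year",
    "driver",
    "h_area",
    "h_mu",
    "a_early",
    "a_late",
    "t_max",
    "f_at_tmax",
    "season_start",
    "season_end",
    "n_earlier",
    "n_later",
    "sign",
]


def write_siteyear_summary(results, path) -> pd.DataFrame:
    """Write one CSV row per (site, season-year, driver) hysteresis result.

    Values are written at full float precision, so a read-back reproduces
    ``h_area`` etc. exactly.  An empty collection yields a header-only file.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "site_id": r.site_id,
                "season_year": r.season_year,
                "driver": r.driver,
                "h_area": r.h_area,
                "h_mu": r.h_mu,
                "a_early": r.fit_earlier.a_hys,
                "a_late": r.fit_later.a_hys,
                "t_max": r.fit_earlier.t_max,
                "f_at_tmax": r.fit_earlier.f_at_tmax,
                "season_start": r.season_start,
                "season_end": r.season_end,
                "n_earlier": r.fit_earlier.n_points,
                "n_later": r.fit_later.n_points,
                "sign": r.sign,
            }
        )
    frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    frame.to_csv(path, index=False)
    return frame


def read_siteyear_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["season_start", "season_end"])
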