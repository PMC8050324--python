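"""Synthetic multi-site daily flux datasets with controllable hysteresis.

Two flux generators, on purpose:

* the *parametric* generator inverts the constrained quadratic — it draws a
  seasonal temperature cycle, locates the frost-free season and its maximum,
  and emits branch-specific fluxes from the quadratic with injected
  ``a_early`` / ``a_late``, so the analysis pipeline can be scored against
  exact ground truth (noise-free generation round-trips to <= 1e-9);
* the *mechanistic* generator runs a lagged substrate pool (GPP feeds a
  carbon store that decays into emission with a Q10 temperature response), a
  minimal implementation of the substrate-mediated mechanism thought to
  produce predominantly positive seasonal hysteresis — emission keeps running
  on accumulated substrate after the temperature peak.

Noise on flux is multiplicative lognormal (flux magnitudes span orders of
magnitude across sites); sub-zero-temperature days emit a small positive
floor, N(0.5, 0.2^2) truncated at zero, so winter days stay non-informative
without zeros breaking log-scale plots.  Every generator output is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import DailySeries, SiteMeta
from .errors import DegenerateFitError, StabilityError
from .hysteresis import BranchFit, eval_curve
from .season import SeasonPolicy, extract_season

DAYS_PER_YEAR = 365.25
#: day-of-year phase shift putting the noise-free temperature peak near day 182
PHASE_SHIFT = 91.0

FLOOR_MEAN = 0.5   # mg C m-2 d-1, sub-zero flux floor
FLOOR_SD = 0.2


@dataclass(frozen=True)
class SynthSiteConfig:
    """Everything needed to generate one synthetic site, reproducibly."""

    site_id: str
    ecosystem_type: str
    latitude: float
    years: int = 3
    start_year: int = 2010
    t_mean: float = 8.0          # degC annual mean air temperature
    t_amplitude: float = 14.0    # degC seasonal semi-amplitude
    t_noise_sd: float = 1.5      # degC AR(1) innovation sd
    t_ar1: float = 0.6
    a_early: float = 0.2         # mg C m-2 d-1 degC-2
    a_late: float = -0.2
    f_peak: float = 100.0        # mg C m-2 d-1, flux at the seasonal T maximum
    flux_noise_cv: float = 0.1
    generator: str = "parametric"
    seed: int = 0
    # covariate parameters
    gpp_max: float = 8.0         # g C m-2 d-1
    precip_prob: float = 0.3
    precip_gamma_shape: float = 1.2
    precip_gamma_scale: float = 5.0  # mm
    wtd_floor: float = -60.0     # cm
    wtd_cap: float = 10.0

    def __post_init__(self) -> None:
        if self.t_amplitude <= 0:
            raise ValueError("t_amplitude must be positive")
        if self.flux_noise_cv < 0:
            raise ValueError("flux_noise_cv must be >= 0")
        if not 0 <= self.t_ar1 < 1:
            raise ValueError("t_ar1 must lie in [0, 1)")


@dataclass(frozen=True)
class MechanisticParams:
    """Lagged substrate-pool emission model parameters."""

    gpp_to_substrate: float = 0.1   # fraction of GPP entering the pool
    substrate_lag: int = 20         # days from fixation to availability
    decay_rate: float = 0.02        # d-1 at t_ref
    q10: float = 2.5
    t_ref: float = 10.0             # degC
    unit_scale: float = 1000.0      # g C -> mg C

    def __post_init__(self) -> None:
        for name in ("gpp_to_substrate", "decay_rate", "q10", "t_ref", "unit_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.substrate_lag < 0:
            raise ValueError("substrate_lag must be >= 0")


def _dates(cfg: SynthSiteConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(cfg.start_year, 1, 1)
    end = pd.Timestamp(cfg.start_year + cfg.years - 1, 12, 31)
    return pd.date_range(start, end, freq="D")


def gen_temperature(cfg: SynthSiteConfig, rng: np.random.Generator | None = None) -> pd.Series:
    """Sinusoidal seasonal cycle plus stationary AR(1) noise.

    ``t(d) = t_mean + t_amplitude * sin(2*pi*(doy - 91)/365.25)`` with the
    phase flipped for southern-hemisphere sites; the AR(1) component is
    initialised from its stationary distribution
    (sd ``t_noise_sd / sqrt(1 - t_ar1**2)``).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    dates = _dates(cfg)
    doy = dates.dayofyear.to_numpy(dtype=float)
    phase = np.sin(2.0 * np.pi * (doy - PHASE_SHIFT) / DAYS_PER_YEAR)
    if cfg.latitude < 0:
        phase = -phase
    clean = cfg.t_mean + cfg.t_amplitude * phase
    n = len(dates)
    noise = np.zeros(n)
    if cfg.t_noise_sd > 0:
        stat_sd = cfg.t_noise_sd / np.sqrt(1.0 - cfg.t_ar1**2)
        noise[0] = rng.normal(0.0, stat_sd)
        innov = rng.normal(0.0, cfg.t_noise_sd, size=n - 1)
        for i in range(1, n):
            noise[i] = cfg.t_ar1 * noise[i - 1] + innov[i - 1]
    return pd.Series(clean + noise, index=dates, name="t_air")


def gen_covariates(
    cfg: SynthSiteConfig,
    t_air: pd.Series,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """GPP, precipitation and water-table depth consistent with temperature.

    GPP is a seasonal envelope times a temperature limitation (zero below
    0 degC, saturating by 10 degC) with multiplicative lognormal noise;
    precipitation follows a seeded occurrence(p)-amount(gamma) model; WTD is
    a bounded random walk recharged by precipitation with a constant drydown.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    dates = t_air.index
    doy = dates.dayofyear.to_numpy(dtype=float)
    phase = np.sin(2.0 * np.pi * (doy - PHASE_SHIFT) / DAYS_PER_YEAR)
    if cfg.latitude < 0:
        phase = -phase
    t = t_air.to_numpy(dtype=float)
    temp_limit = np.clip(t / 10.0, 0.0, 1.0)
    base = cfg.gpp_max * np.clip(phase, 0.0, None) * temp_limit
    gpp = base * rng.lognormal(mean=0.0, sigma=0.2, size=len(dates))

    wet = rng.random(len(dates)) < cfg.precip_prob
    amounts = rng.gamma(cfg.precip_gamma_shape, cfg.precip_gamma_scale, size=len(dates))
    precip = np.where(wet, amounts, 0.0)

    wtd = np.empty(len(dates))
    level = -10.0
    for i in range(len(dates)):
        level = level + 0.5 * precip[i] - 0.4
        level = min(max(level, cfg.wtd_floor), cfg.wtd_cap)
        wtd[i] = level

    return pd.DataFrame({"gpp": gpp, "precip": precip, "wtd": wtd}, index=dates)


def _flux_floor(n: int, rng: np.random.Generator) -> np.ndarray:
    return np.clip(rng.normal(FLOOR_MEAN, FLOOR_SD, size=n), 0.0, None)


def _season_for_year(t_air: pd.Series, cfg: SynthSiteConfig, year: int):
    series = DailySeries(
        site_id=cfg.site_id,
        data=pd.DataFrame({"t_air": t_air, "f_ch4": np.ones(len(t_air))}),
    )
    policy = SeasonPolicy(min_season_days=30)
    return extract_season(series, policy, year, latitude=cfg.latitude)


def gen_flux_parametric(
    t_air: pd.Series,
    cfg: SynthSiteConfig,
    rng: np.random.Generator | None = None,
    per_year_params: dict[int, tuple[float, float, float]] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Branch-specific quadratic flux with injected hysteresis.

    For each season-year the frost-free season and its temperature maximum
    are located on the generated temperature; earlier-branch days follow the
    constrained quadratic with ``a_early``, later-branch days with
    ``a_late``, both anchored at ``(t_max, f_peak)``.  ``per_year_params``
    optionally overrides ``(a_early, a_late, f_peak)`` per season-year.
    Returns the flux series and the ground-truth table (one row per
    season-year).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    flux = pd.Series(_flux_floor(len(t_air), rng), index=t_air.index, name="f_ch4")
    truth_rows = []
    start_years = sorted(set(t_air.index.year)) if cfg.latitude >= 0 else sorted(
        set(t_air.index.year)
    )
    for year in start_years:
        try:
            season = _season_for_year(t_air, cfg, year)
        except Exception:
            continue
        if season.degenerate_branch or len(season.earlier_indices) < 2:
            continue
        a_e, a_l, f_pk = (
            per_year_params.get(year, (cfg.a_early, cfg.a_late, cfg.f_peak))
            if per_year_params
            else (cfg.a_early, cfg.a_late, cfg.f_peak)
        )
        for branch, idx, a in (
            ("earlier", season.earlier_indices, a_e),
            ("later", season.later_indices, a_l),
        ):
            fit = BranchFit(
                a_hys=a, t_max=season.t_max, f_at_tmax=f_pk,
                branch=branch, n_points=len(idx), rmse=0.0,
            )
            clean = eval_curve(fit, t_air.loc[idx].to_numpy(dtype=float))
            if cfg.flux_noise_cv > 0:
                sigma = np.sqrt(np.log(1.0 + cfg.flux_noise_cv**2))
                mult = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=len(idx))
                clean = clean * mult
            flux.loc[idx] = clean
        truth_rows.append(
            {
                "site_id": cfg.site_id,
                "season_year": year,
                "a_early": a_e,
                "a_late": a_l,
                "f_peak": f_pk,
                "t_max": season.t_max,
                "hysteresis_sign": "positive" if a_e > a_l else (
                    "negative" if a_e < a_l else "zero"),
            }
        )
    return flux, pd.DataFrame(truth_rows)


def gen_flux_mechanistic(
    t_air: pd.Series,
    gpp: pd.Series,
    params: MechanisticParams,
    rng: np.random.Generator | None = None,
    flux_noise_cv: float = 0.1,
    s0: float = 0.0,
) -> pd.Series:
    """Flux from a lagged substrate pool with a Q10 emission response.

    ``S(d+1) = S(d) + gpp_to_substrate * GPP(d - lag) - k(T) * S(d)`` with
    ``k(T) = decay_rate * q10**((T - t_ref)/10)``; emission is the decay term
    (scaled to mg C) plus multiplicative lognormal noise.  The pool is kept
    non-negative and integration aborts if it diverges.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    t = t_air.to_numpy(dtype=float)
    g = np.nan_to_num(gpp.to_numpy(dtype=float), nan=0.0)
    n = len(t)
    S = s0
    limit = 1e6 * max(s0, 1.0)
    flux = np.empty(n)
    for i in range(n):
        k = params.decay_rate * params.q10 ** ((t[i] - params.t_ref) / 10.0)
        k = min(k, 1.0)  # cannot emit more than the pool in one day
        emission = k * S
        lag_i = i - params.substrate_lag
        inflow = params.gpp_to_substrate * g[lag_i] if lag_i >= 0 else 0.0
        S = max(S + inflow - emission, 0.0)
        if S > limit:
            raise StabilityError(f"substrate pool diverged at day {i} (S={S:.3g})")
        flux[i] = emission * params.unit_scale
    if flux_noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + flux_noise_cv**2))
        flux = flux * rng.lognormal(-sigma**2 / 2.0, sigma, size=n)
    return pd.Series(flux, index=t_air.index, name="f_ch4")


def gen_site(cfg: SynthSiteConfig, mech_params: MechanisticParams | None = None,
             per_year_params=None) -> tuple[DailySeries, pd.DataFrame]:
    """Generate one full synthetic site (drivers, covariates, flux, truth).

    A degenerate season (e.g. the temperature maximum falling on the last
    season day) triggers regeneration with a new sub-seed, at most 5 tries.
    """
    last_exc: Exception | None = None
    for attempt in range(6):
        sub = replace(cfg, seed=cfg.seed + 1000 * attempt)
        rng = np.random.default_rng([sub.seed, 7])
        t_air = gen_temperature(sub, rng)
        cov = gen_covariates(sub, t_air, rng)
        try:
            if cfg.generator == "mechanistic":
                params = mech_params or MechanisticParams()
                flux = gen_flux_mechanistic(t_air, cov["gpp"], params, rng,
                                            flux_noise_cv=cfg.flux_noise_cv)
                truth = pd.DataFrame()
            else:
                flux, truth = gen_flux_parametric(t_air, sub, rng, per_year_params)
                if truth.empty:
                    raise DegenerateFitError("no usable season-year generated")
        except (DegenerateFitError, StabilityError) as exc:
            last_exc = exc
            continue
        df = pd.DataFrame(
            {
                "t_air": t_air,
                "t_soil_shallow": t_air.rolling(7, min_periods=1).mean(),
                "f_ch4": flux,
                "gpp": cov["gpp"],
                "wtd": cov["wtd"],
                "precip": cov["precip"],
            }
        )
        meta = SiteMeta(cfg.site_id, cfg.ecosystem_type, cfg.latitude, 0.0)
        return DailySeries(site_id=cfg.site_id, data=df, meta=meta), truth
    raise DegenerateFitError(
        f"{cfg.site_id}: no valid season after 5 regeneration attempts ({last_exc})"
    )


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

#: loosely realistic type-level peak-flux baselines, mg C m-2 d-1
TYPE_PEAK_FLUX = {
    "bog": 40.0,
    "fen": 80.0,
    "marsh": 200.0,
    "peat_plateau": 25.0,
    "rice": 150.0,
    "salt_marsh": 60.0,
    "swamp": 100.0,
    "wet_tundra": 35.0,
}

#: type-level central latitudes (degrees) and spread
TYPE_LATITUDE = {
    "bog": (55.0, 8.0),
    "fen": (60.0, 6.0),
    "marsh": (40.0, 12.0),
    "peat_plateau": (66.0, 3.0),
    "rice": (35.0, 6.0),
    "salt_marsh": (35.0, 8.0),
    "swamp": (30.0, 10.0),
    "wet_tundra": (70.0, 2.0),
}


@dataclass
class NetworkTruth:
    """Dataset plus its generating parameters, for recovery scoring."""

    dataset: dict[str, DailySeries]
    metas: dict[str, SiteMeta]
    truth: pd.DataFrame          # one row per site-year
    configs: list[SynthSiteConfig]
    positive_fraction_constructed: float


def gen_network(
    n_sites: int = 48,
    seed: int = 0,
    positive_fraction: float = 0.75,
    flux_noise_cv: float = 0.2,
    years_range: tuple[int, int] = (2, 6),
    delta_range: tuple[float, float] = (0.1, 0.6),
    southern_fraction: float = 0.04,
    type_distribution: dict[str, float] | None = None,
) -> NetworkTruth:
    """Generate a multi-site network with a constructed hysteresis-sign mix.

    Ecosystem types are assigned round-robin over the 8 types (or drawn from
    ``type_distribution``); per-site temperature climate follows latitude.
    The magnitude of the branch-parameter gap ``|a_early - a_late|`` is drawn
    uniformly from ``delta_range`` (scaled to each site's flux magnitude) and
    its sign is assigned deterministically so that exactly
    ``round(positive_fraction * n_site_years)`` site-years are
    positive-hysteresis by construction.
    """
    rng = np.random.default_rng(seed)
    types = sorted(TYPE_PEAK_FLUX)
    if type_distribution:
        names = sorted(type_distribution)
        probs = np.array([type_distribution[k] for k in names], dtype=float)
        site_types = list(rng.choice(names, size=n_sites, p=probs / probs.sum()))
    else:
        site_types = [types[i % len(types)] for i in range(n_sites)]

    # pre-draw site-years so the sign assignment can be exact by construction
    years_per_site = rng.integers(years_range[0], years_range[1] + 1, size=n_sites)
    n_siteyears = int(np.sum(years_per_site))
    n_pos = int(round(positive_fraction * n_siteyears))
    signs = np.array([1.0] * n_pos + [-1.0] * (n_siteyears - n_pos))
    rng.shuffle(signs)

    configs: list[SynthSiteConfig] = []
    dataset: dict[str, DailySeries] = {}
    metas: dict[str, SiteMeta] = {}
    truths: list[pd.DataFrame] = []
    sy_cursor = 0
    for i in range(n_sites):
        etype = site_types[i]
        lat_mu, lat_sd = TYPE_LATITUDE[etype]
        lat = float(np.clip(rng.normal(lat_mu, lat_sd), 5.0, 75.0))
        if rng.random() < southern_fraction:
            lat = -lat
        t_mean = 26.0 - 0.45 * abs(lat) + rng.normal(0.0, 1.5)
        t_amp = 4.0 + 0.3 * abs(lat) + rng.normal(0.0, 1.0)
        f_peak_site = TYPE_PEAK_FLUX[etype] * rng.lognormal(0.0, 0.4)
        site_id = f"SY{i:03d}"
        n_years = int(years_per_site[i])
        cfg = SynthSiteConfig(
            site_id=site_id,
            ecosystem_type=etype,
            latitude=lat,
            years=n_years,
            start_year=2010,
            t_mean=t_mean,
            t_amplitude=max(t_amp, 6.0),
            t_noise_sd=1.5,
            t_ar1=0.6,
            f_peak=f_peak_site,
            flux_noise_cv=flux_noise_cv,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # per-season-year parameters: shared site centre, per-year delta/sign
        centre = rng.uniform(-0.1, 0.1) * f_peak_site / 100.0
        per_year = {}
        for y in range(cfg.start_year, cfg.start_year + n_years):
            delta = rng.uniform(*delta_range) * f_peak_site / 100.0
            sign = signs[sy_cursor]
            sy_cursor += 1
            a_e = centre + sign * delta / 2.0
            a_l = centre - sign * delta / 2.0
            f_pk = f_peak_site * rng.lognormal(0.0, 0.15)
            per_year[y] = (a_e, a_l, f_pk)
        series, truth = gen_site(cfg, per_year_params=per_year)
        configs.append(cfg)
        dataset[site_id] = series
        metas[site_id] = series.meta
        truths.append(truth)

    truth = pd.concat(truths, ignore_index=True)
    constructed = float((truth["a_early"] > truth["a_late"]).mean())
    return NetworkTruth(
        dataset=dataset,
        metas=metas,
        truth=truth,
        configs=configs,
        positive_fraction_constructed=constructed,
    )


# ---------------------------------------------------------------------------
# CSV emission (same dialect the reader consumes)
# ---------------------------------------------------------------------------

def write_network(net: NetworkTruth, out_dir) -> None:
    """Emit the network as FLUXNET-style CSVs plus truth and config sidecars.

    Deterministic formatting (fixed precision, fixed column order) so the
    same seed yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for site_id, series in net.dataset.items():
        df = series.data
        table = pd.DataFrame(
            {
                "TIMESTAMP": df.index.strftime("%Y%m%d"),
                "TA": df["t_air"].round(6),
                "TS_1": df["t_soil_shallow"].round(6),
                "FCH4": df["f_ch4"].round(6),
                "GPP": df["gpp"].round(6),
                "WTD": df["wtd"].round(6),
                "P": df["precip"].round(6),
            }
        )
        table.to_csv(out / f"{site_id}_daily.csv", index=False)
        m = net.metas[site_id]
        meta_rows.append({"SITE_ID": m.site_id, "TYPE": m.ecosystem_type,
                          "LAT": round(m.latitude, 4), "LON": m.longitude})
    pd.DataFrame(meta_rows).to_csv(out / "site_metadata.csv", index=False)
    net.truth.to_csv(out / "ground_truth.csv", index=False)
    cfg_dump = [
        {k: (float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v)
         for k, v in c.__dict__.items()}
        for c in net.configs
    ]
    with open(out / "network_config.yaml", "w") as fh:
        yaml.safe_dump({"sites": cfg_dump}, fh, sort_keys=True)


def read_network(data_dir) -> dict[str, DailySeries]:
    """Load a directory of ``*_daily.csv`` files plus ``site_metadata.csv``."""
    from .datamodel import read_daily_table, read_site_metadata

    data_dir = Path(data_dir)
    metas = read_site_metadata(data_dir / "site_metadata.csv")
    dataset = {}
    for site_id, meta in metas.items():
        path = data_dir / f"{site_id}_daily.csv"
        if path.exists():
            dataset[site_id] = read_daily_table(path, meta)
    return dataset
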