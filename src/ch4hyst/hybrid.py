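"""Tree-ensemble regression of the hysteresis parameter and the hybrid model.

The response is the per-branch hysteresis parameter ``a_hys``; the ten
predictors are the seasonal branch, branch-cumulative GPP and precipitation,
the seasonal temperature maximum, the branch-mean temperature, ecosystem
type, latitude, site, site-year, and the flux measured at the temperature
maximum.  Branch, ecosystem type, site and site-year are categorical; the
rest numeric.  Predictors with limited predictive power (observation year,
branch-mean WTD / wind speed / pressure) are computed and stored but excluded
from the default set.

A seeded :class:`sklearn.ensemble.RandomForestRegressor` sits behind the
regressor contract; categoricals are one-hot encoded with category order
fixed by first appearance so identical seed + data give identical
predictions.  Permutation importance permutes each *raw* predictor column
(all dummy columns of a categorical jointly) and reports the mean increase in
squared error over seeded repeats.

The hybrid flux model plugs the forest's predicted ``a_hys`` into the
constrained quadratic with the site-year's anchors, so its predictions still
honour the closed-loop constraints exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import InsufficientDataError
from .hysteresis import BranchFit, eval_curve

CATEGORICAL_PREDICTORS = ("seasonal_branch", "ecosystem_type", "site_id", "site_year")
NUMERIC_PREDICTORS = (
    "gpp_cum_branch",
    "precip_cum_branch",
    "t_max",
    "t_mean_branch",
    "latitude",
    "f_at_tmax",
)
DEFAULT_PREDICTORS = CATEGORICAL_PREDICTORS + NUMERIC_PREDICTORS
#: computed and stored, excluded from the default predictor set
EXTRA_PREDICTORS = ("year", "wtd_mean_branch", "wind_speed_mean_branch", "pressure_mean_branch")

DEFAULT_N_TREES = 500
DEFAULT_SEED = 20210415
DEFAULT_PERMUTATION_REPEATS = 10


def build_training_table(results, dataset) -> pd.DataFrame:
    """One row per (site-year, branch) with the ten predictors and ``a_hys``.

    ``results`` is a collection of
    :class:`~ch4hyst.hysteresis.HysteresisResult`; ``dataset`` maps site id to
    its :class:`~ch4hyst.datamodel.DailySeries` (used for branch-cumulative
    covariates).  Rows with missing latitude are dropped; the number dropped
    is recorded in ``table.attrs["n_dropped_missing_latitude"]``, and each
    row carries the covariate coverage fraction of its branch.
    """
    from .season import SeasonPolicy, extract_season  # local: avoids cycle at import

    rows = []
    n_dropped = 0
    for r in results:
        series = dataset[r.site_id]
        policy = SeasonPolicy(driver=r.driver)
        season = extract_season(series, policy, r.season_year)
        for branch, fit, idx in (
            ("earlier", r.fit_earlier, season.earlier_indices),
            ("later", r.fit_later, season.later_indices),
        ):
            sub = series.data.loc[idx]
            if r.latitude is None or not np.isfinite(r.latitude):
                n_dropped += 1
                continue
            gpp = sub["gpp"].dropna()
            pr = sub["precip"].dropna()
            rows.append(
                {
                    "site_id": r.site_id,
                    "site_year": f"{r.site_id}_{r.season_year}",
                    "seasonal_branch": branch,
                    "ecosystem_type": r.ecosystem_type,
                    "latitude": float(r.latitude),
                    "gpp_cum_branch": float(gpp.sum()),
                    "precip_cum_branch": float(pr.sum()),
                    "t_max": fit.t_max,
                    "t_mean_branch": float(sub[r.driver].mean()),
                    "f_at_tmax": fit.f_at_tmax,
                    "a_hys": fit.a_hys,
                    "year": int(r.season_year),
                    "wtd_mean_branch": float(sub["wtd"].mean()),
                    "wind_speed_mean_branch": float(sub["wind_speed"].mean()),
                    "pressure_mean_branch": float(sub["pressure"].mean()),
                    "gpp_coverage": float(len(gpp)) / max(len(sub), 1),
                    "precip_coverage": float(len(pr)) / max(len(sub), 1),
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["n_dropped_missing_latitude"] = n_dropped
    return table


@dataclass
class AhysRegressor:
    """Seeded forest + the one-hot encoding needed to apply it to raw rows."""

    forest: RandomForestRegressor
    predictors: tuple
    categories: dict            # categorical predictor -> first-appearance ordering
    feature_names: list
    oob_r2: float
    in_sample_r2: float
    n_trees: int
    seed: int

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        names = []
        for p in self.predictors:
            if p in self.categories:
                cats = self.categories[p]
                codes = pd.Categorical(table[p], categories=cats)
                dummies = np.zeros((len(table), len(cats)))
                valid = codes.codes >= 0  # unseen categories encode as all-zero
                dummies[np.arange(len(table))[valid], codes.codes[valid]] = 1.0
                cols.append(dummies)
                names.extend(f"{p}={c}" for c in cats)
            else:
                cols.append(table[p].to_numpy(dtype=float)[:, None])
                names.append(p)
        X = np.hstack(cols)
        if self.feature_names and names != self.feature_names:
            raise ValueError("encoding drifted from training feature layout")
        return X

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(self.encode(table))


def fit_ahys_regressor(
    table: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = DEFAULT_SEED,
    min_rows: int = 30,
) -> AhysRegressor:
    """Fit the seeded random forest for ``a_hys``.

    Determinism contract: identical seed and data give bit-identical
    predictions.  Out-of-bag R2 serves as the held-out error estimate.
    """
    if len(table) < min_rows:
        raise InsufficientDataError(f"{len(table)} rows < required {min_rows}")
    categories = {}
    for p in predictors:
        if p in CATEGORICAL_PREDICTORS:
            categories[p] = list(pd.unique(table[p]))
    reg = AhysRegressor(
        forest=RandomForestRegressor(
            n_estimators=n_trees,
            random_state=seed,
            oob_score=True,
            bootstrap=True,
            n_jobs=1,
        ),
        predictors=tuple(predictors),
        categories=categories,
        feature_names=[],
        oob_r2=np.nan,
        in_sample_r2=np.nan,
        n_trees=n_trees,
        seed=seed,
    )
    X = reg.encode(table)
    # freeze the layout after first encode
    names = []
    for p in reg.predictors:
        if p in categories:
            names.extend(f"{p}={c}" for c in categories[p])
        else:
            names.append(p)
    reg.feature_names = names
    y = table["a_hys"].to_numpy(dtype=float)
    reg.forest.fit(X, y)
    reg.oob_r2 = float(reg.forest.oob_score_)
    reg.in_sample_r2 = float(reg.forest.score(X, y))
    return reg


def grouped_holdout_r2(
    table: pd.DataFrame,
    group_column: str = "site_id",
    predictors=DEFAULT_PREDICTORS,
    n_trees: int = 100,
    seed: int = DEFAULT_SEED,
) -> float:
    """Leave-one-group-out R2 (default: leave-site-out).

    The leakage audit: with ``site_year`` among the predictors the in-sample
    fit is near-perfect, so honest skill must be judged on held-out sites.
    """
    y_true, y_pred = [], []
    groups = pd.unique(table[group_column])
    for g in groups:
        train = table[table[group_column] != g]
        test = table[table[group_column] == g]
        if len(train) < 10:
            continue
        reg = fit_ahys_regressor(
            train, predictors=predictors, n_trees=n_trees, seed=seed, min_rows=10
        )
        y_true.append(test["a_hys"].to_numpy(dtype=float))
        y_pred.append(reg.predict(test))
    yt = np.concatenate(y_true)
    yp = np.concatenate(y_pred)
    ss_res = float(np.sum((yt - yp) ** 2))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class ImportanceReport:
    scores: pd.Series      # mean MSE increase per predictor, descending
    ranks: pd.Series       # 1 = most important
    n_repeats: int
    seed: int


def permutation_importance(
    reg: AhysRegressor,
    table: pd.DataFrame,
    seed: int = DEFAULT_SEED,
    n_repeats: int = DEFAULT_PERMUTATION_REPEATS,
) -> ImportanceReport:
    """Mean increase in squared error when one predictor column is shuffled.

    Each raw predictor is permuted (a categorical's dummies move together)
    over ``n_repeats`` seeded shuffles.
    """
    rng = np.random.default_rng(seed)
    y = table["a_hys"].to_numpy(dtype=float)
    base_mse = float(np.mean((reg.predict(table) - y) ** 2))
    scores = {}
    for p in reg.predictors:
        increases = []
        for _ in range(n_repeats):
            shuffled = table.copy()
            shuffled[p] = rng.permutation(shuffled[p].to_numpy())
            mse = float(np.mean((reg.predict(shuffled) - y) ** 2))
            increases.append(mse - base_mse)
        scores[p] = float(np.mean(increases))
    s = pd.Series(scores).sort_values(ascending=False)
    ranks = pd.Series(np.arange(1, len(s) + 1), index=s.index)
    return ImportanceReport(scores=s, ranks=ranks, n_repeats=n_repeats, seed=seed)


def hybrid_predict(
    reg: AhysRegressor,
    predictor_row: pd.DataFrame,
    T,
) -> np.ndarray:
    """Daily flux from the constrained quadratic with forest-predicted a_hys.

    ``predictor_row`` is a single-row frame carrying the branch's predictors
    plus the ``t_max`` / ``f_at_tmax`` anchors; the anchors are honoured
    exactly regardless of the predicted parameter.
    """
    if len(predictor_row) != 1:
        raise ValueError("predictor_row must contain exactly one row")
    row = predictor_row.iloc[0]
    if not (np.isfinite(row["t_max"]) and np.isfinite(row["f_at_tmax"])):
        raise ValueError("missing t_max / f_at_tmax anchors")
    a = float(reg.predict(predictor_row)[0])
    fit = BranchFit(
        a_hys=a,
        t_max=float(row["t_max"]),
        f_at_tmax=float(row["f_at_tmax"]),
        branch=str(row.get("seasonal_branch", "full")),
        n_points=0,
        rmse=float("nan"),
    )
    return eval_curve(fit, T)


def hybrid_day_predictions(
    reg: AhysRegressor, table: pd.DataFrame, day_table: pd.DataFrame
) -> np.ndarray:
    """Hybrid-model prediction for every row of the day-level table."""
    a_hat = pd.Series(reg.predict(table), index=pd.MultiIndex.from_frame(
        table[["site_year", "seasonal_branch"]]))
    key = pd.MultiIndex.from_arrays(
        [
            day_table["site_id"].astype(str) + "_" + day_table["season_year"].astype(str),
            day_table["branch"],
        ]
    )
    anchors = table.set_index(["site_year", "seasonal_branch"])[["t_max", "f_at_tmax"]]
    a = a_hat.reindex(key).to_numpy(dtype=float)
    tm = anchors["t_max"].reindex(key).to_numpy(dtype=float)
    fm = anchors["f_at_tmax"].reindex(key).to_numpy(dtype=float)
    t = day_table["t"].to_numpy(dtype=float)
    return a * t**2 + (fm / tm - a * tm) * t
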