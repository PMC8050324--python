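"""Tiered pooled temperature-dependence models and bias scoring.

Six regression tiers pool the day-level data at different resolutions by
activating subsets of the variability factors

* ``type``  - ecosystem-type variability (8 groups),
* ``site``  - inter-site variability,
* ``IAV``   - inter-annual variability (site-year groups; requires ``site``),
* ``ISV``   - intra-seasonal variability (earlier/later branch split),

always on top of the temperature driver ``T``.  Each group gets its own
quadratic-through-origin curve ``F = b1*T + b2*T**2`` (or optionally a
Boltzmann-Arrhenius curve); a group with fewer than 3 days inherits its
parent (coarser) group's fit, and an unresolvable group at prediction time
falls back the same way.  The seventh, hybrid tier (random-forest predicted
hysteresis parameter plugged into the constrained quadratic) lives in
:mod:`ch4hyst.hybrid`.

Bias metrics follow the descriptive comparison of the study design:
``absolute_bias`` is 100 * sum|pred - obs| / sum(obs) per ecosystem type, and
``branch_bias`` the signed per-site-year relative bias per season branch
(ratio of sums), summarised as mean +/- sd across site-years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateFitError
from .hysteresis import BOLTZMANN_EV, CELSIUS_ZERO, fit_arrhenius, arrhenius_predict

FACTORS = ("type", "site", "IAV", "ISV")

TIER_LABELS = (
    "T",
    "T+type",
    "T+type+ISV",
    "T+site",
    "T+site+IAV",
    "T+site+IAV+ISV",
)

_FACTOR_COLUMNS = {
    "type": ("ecosystem_type",),
    "site": ("site_id",),
    "IAV": ("site_id", "season_year"),
    "ISV": ("branch",),
}


@dataclass(frozen=True)
class TierSpec:
    """Which variability factors a pooled tier resolves."""

    factors: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.factors) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors {sorted(unknown)}")
        if "IAV" in self.factors and "site" not in self.factors:
            raise ValueError("IAV requires site")
        object.__setattr__(self, "factors", frozenset(self.factors))
        if not self.label:
            object.__setattr__(self, "label", spec_label(self.factors))

    @classmethod
    def from_label(cls, label: str) -> "TierSpec":
        parts = [p for p in label.split("+") if p != "T"]
        return cls(factors=frozenset(parts), label=label)


def spec_label(factors) -> str:
    order = ["type", "site", "IAV", "ISV"]
    parts = ["T"] + [f for f in order if f in factors]
    return "+".join(parts)


def standard_specs() -> list[TierSpec]:
    return [TierSpec.from_label(lbl) for lbl in TIER_LABELS]


def group_columns(spec: TierSpec) -> list[str]:
    cols: list[str] = []
    for f in ("type", "site", "IAV", "ISV"):
        if f in spec.factors:
            for c in _FACTOR_COLUMNS[f]:
                if c not in cols:
                    cols.append(c)
    return cols


def partition_data(day_table: pd.DataFrame, spec: TierSpec):
    """Group the day table by the spec's active factors.

    With no factors the whole table is one global group keyed ``()``.  Every
    analyzable day lands in exactly one group.
    """
    cols = group_columns(spec)
    if not cols:
        return {(): day_table}
    groups = {}
    for key, sub in day_table.groupby(cols, sort=False, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        groups[key] = sub
    return groups


def _parent_spec(spec: TierSpec) -> TierSpec | None:
    """Coarsen by dropping one factor: ISV first, then IAV, then site, then type."""
    for f in ("ISV", "IAV", "site", "type"):
        if f in spec.factors:
            return TierSpec(factors=spec.factors - {f})
    return None


def _fit_quadratic_origin(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    X = np.column_stack([t, t**2])
    coef, *_ = np.linalg.lstsq(X, f, rcond=None)
    return float(coef[0]), float(coef[1])


@dataclass
class TierModel:
    """A fitted pooled tier: one curve per group plus a coarser fallback chain."""

    spec: TierSpec
    form: str
    curves: dict = field(default_factory=dict)
    parent: "TierModel | None" = None
    inherited_groups: list = field(default_factory=list)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Evaluate each day's group curve at its driver value.

        Days of unseen groups fall back to the parent tier's prediction.
        """
        t = rows["t"].to_numpy(dtype=float)
        out = np.empty(len(rows), dtype=float)
        cols = group_columns(self.spec)
        if not cols:
            out[:] = self._eval((), t)
            return out
        frame = rows.reset_index(drop=True)
        unresolved_idx: list[np.ndarray] = []
        for key, sub in frame.groupby(cols, sort=False, observed=True):
            if not isinstance(key, tuple):
                key = (key,)
            idx = sub.index.to_numpy()
            if key in self.curves:
                out[idx] = self._eval(key, t[idx])
            else:
                unresolved_idx.append(idx)
        if unresolved_idx:
            if self.parent is None:
                raise DegenerateFitError("unresolvable group with no parent tier")
            idx = np.concatenate(unresolved_idx)
            out[idx] = self.parent.predict(frame.iloc[idx])
        return out

    def _eval(self, key, t: np.ndarray) -> np.ndarray:
        params = self.curves[key]
        if self.form == "quadratic_origin":
            b1, b2 = params
            return b1 * t + b2 * t**2
        return arrhenius_predict(params, t + CELSIUS_ZERO)


def fit_tier(
    day_table: pd.DataFrame,
    spec: TierSpec,
    form: str = "quadratic_origin",
    min_group_days: int = 3,
) -> TierModel:
    """Fit one pooled tier; small groups inherit the parent tier's fit."""
    if form not in ("quadratic_origin", "arrhenius"):
        raise ValueError(f"unknown functional form {form!r}")
    parent_spec = _parent_spec(spec)
    parent = (
        fit_tier(day_table, parent_spec, form=form, min_group_days=min_group_days)
        if parent_spec is not None
        else None
    )
    model = TierModel(spec=spec, form=form, parent=parent)
    groups = partition_data(day_table, spec)
    n_fit = 0
    for key, sub in groups.items():
        t = sub["t"].to_numpy(dtype=float)
        f = sub["f"].to_numpy(dtype=float)
        if len(sub) < min_group_days and parent is not None:
            model.inherited_groups.append(key)
            continue
        try:
            if form == "quadratic_origin":
                model.curves[key] = _fit_quadratic_origin(t, f)
            else:
                model.curves[key] = fit_arrhenius(t + CELSIUS_ZERO, f)
            n_fit += 1
        except Exception:
            model.inherited_groups.append(key)
    if n_fit == 0 and parent is None:
        raise DegenerateFitError(f"no fittable group for tier {spec.label}")
    return model


# ---------------------------------------------------------------------------
# bias metrics
# ---------------------------------------------------------------------------

def absolute_bias(pred, obs) -> float:
    """100 * sum|pred - obs| / sum(obs).  Undefined for sum(obs) <= 0."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    denom = float(np.sum(obs))
    if denom <= 0:
        raise DegenerateFitError("sum of observations is non-positive; bias undefined")
    return 100.0 * float(np.sum(np.abs(pred - obs))) / denom


def absolute_bias_by_type(day_table: pd.DataFrame, pred: np.ndarray) -> pd.Series:
    """Absolute bias aggregated within each ecosystem type (plus 'all')."""
    df = day_table.assign(pred=pred)
    out = {}
    for etype, sub in df.groupby("ecosystem_type", observed=True):
        try:
            out[etype] = absolute_bias(sub["pred"], sub["f"])
        except DegenerateFitError:
            out[etype] = np.nan
    out["all"] = absolute_bias(df["pred"], df["f"])
    return pd.Series(out, name="absolute_bias_pct")


def branch_bias(day_table: pd.DataFrame, pred: np.ndarray) -> pd.DataFrame:
    """Signed relative bias per branch: mean +/- sd across site-years.

    Per site-year and branch: 100 * (sum(pred) - sum(obs)) / sum(obs);
    site-year-branches with non-positive total observation are excluded and
    counted.  Overprediction is positive.
    """
    df = day_table.assign(pred=pred)
    rows = []
    excluded = {"earlier": 0, "later": 0}
    for (sid, year, branch), sub in df.groupby(
        ["site_id", "season_year", "branch"], observed=True
    ):
        so = float(sub["f"].sum())
        if so <= 0:
            excluded[branch] += 1
            continue
        sp = float(sub["pred"].sum())
        rows.append({"site_id": sid, "season_year": year, "branch": branch,
                     "bias_pct": 100.0 * (sp - so) / so})
    per = pd.DataFrame(rows)
    summary = []
    for branch in ("earlier", "later"):
        vals = per.loc[per["branch"] == branch, "bias_pct"] if len(per) else pd.Series(dtype=float)
        summary.append(
            {
                "branch": branch,
                "mean_pct": float(vals.mean()) if len(vals) else np.nan,
                "sd_pct": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n_siteyears": int(len(vals)),
                "n_excluded": excluded[branch],
            }
        )
    return pd.DataFrame(summary).set_index("branch")


def compare_tiers(
    day_table: pd.DataFrame,
    specs=None,
    form: str = "quadratic_origin",
) -> tuple[pd.DataFrame, dict]:
    """Fit every tier on the same days and score absolute bias per type.

    Returns the bias table (rows: tier label; columns: ecosystem types and
    'all') and the dict of fitted models keyed by label.  In-sample scoring,
    as in the descriptive comparison the pipeline mirrors.
    """
    specs = specs or standard_specs()
    models = {}
    rows = {}
    for spec in specs:
        model = fit_tier(day_table, spec, form=form)
        pred = model.predict(day_table)
        models[spec.label] = model
        rows[spec.label] = absolute_bias_by_type(day_table, pred)
    table = pd.DataFrame(rows).T
    table.index.name = "tier"
    return table, models
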