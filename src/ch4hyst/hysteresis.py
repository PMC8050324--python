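"""Constrained branch fits, hysteresis statistics, and Arrhenius fits.

The emergent flux-temperature curve of one season branch is the quadratic

    F(T) = a_hys * T**2 + (F_Tmax / T_max - a_hys * T_max) * T,

a one-parameter family forced through the origin (zero flux at 0 degC) and
through the measured flux at the seasonal temperature maximum, so the earlier
and later branch curves of one site-year always form a closed loop.  The loop
is summarised by

* ``H_A``: the signed area between the later and earlier curves on
  [0, T_max], normalized by T_max times the largest absolute fitted flux of
  either curve (dimensionless), and
* ``H_mu``: the difference of mean *measured* daily flux, later minus earlier
  branch (mg C m-2 d-1).

Positive values of both mean higher flux later in the season at the same
temperature, i.e. a counterclockwise loop.  Because ``T**2 - T_max*T`` is
negative on (0, T_max), the later curve lies above the earlier curve exactly
when ``a_early > a_late``.

Apparent activation energies come from an ordinary least-squares fit of
``ln F`` against ``-1/(kT)`` (Boltzmann-Arrhenius form) with
k = 8.62e-5 eV K-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .errors import (
    ConstraintError,
    DegenerateFitError,
    InsufficientDataError,
    UndefinedAreaError,
)

#: Boltzmann constant in eV per kelvin (fixed, never estimated).
BOLTZMANN_EV = 8.62e-5

CELSIUS_ZERO = 273.15


# ---------------------------------------------------------------------------
# constrained polynomial least squares
# ---------------------------------------------------------------------------

def _check_fixed_points(fixed_points):
    seen: dict[float, float] = {}
    for x0, y0 in fixed_points:
        if x0 in seen:
            if seen[x0] != y0:
                raise ConstraintError(
                    f"conflicting constraints at x={x0}: y={seen[x0]} vs y={y0}"
                )
        else:
            seen[x0] = y0
    return [(x, y) for x, y in seen.items()]


def constrained_polyfit(x, y, degree: int, fixed_points=()):
    """Least-squares polynomial fit subject to exact interpolation constraints.

    Minimizes ``sum((y - p(x))**2)`` over degree-``degree`` polynomials with
    ``p(x0) = y0`` for every ``(x0, y0)`` in ``fixed_points``.  Constraints are
    eliminated by splitting the coefficient space into a particular solution
    plus the null space of the constraint matrix and solving an ordinary
    least-squares problem in the free directions.

    Returns coefficients in ascending order (constant term first), suitable
    for :func:`numpy.polynomial.polynomial.polyval`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    fixed = _check_fixed_points(fixed_points)
    n_con = len(fixed)
    if degree < max(n_con - 1, 0):
        raise ValueError(f"degree {degree} cannot satisfy {n_con} constraints")
    n_coef = degree + 1

    V = np.vander(x, n_coef, increasing=True)
    if n_con == 0:
        coef, *_ = np.linalg.lstsq(V, y, rcond=None)
        return coef

    xf = np.array([p[0] for p in fixed])
    yf = np.array([p[1] for p in fixed])
    A = np.vander(xf, n_coef, increasing=True)
    c_part, *_ = np.linalg.lstsq(A, yf, rcond=None)
    N = null_space(A)
    if N.shape[1] == 0:
        return c_part
    design = V @ N
    if len(x) and np.linalg.matrix_rank(design) < N.shape[1] and len(x) >= N.shape[1]:
        raise DegenerateFitError("free design is rank deficient")
    resid_y = y - V @ c_part
    z, *_ = np.linalg.lstsq(design, resid_y, rcond=None)
    # a few steps of iterative refinement: high-degree Vandermonde designs are
    # ill-conditioned enough that a single lstsq loses ~1e-8 relative accuracy
    gram = design.T @ design
    for _ in range(3):
        r = design.T @ (resid_y - design @ z)
        dz, *_ = np.linalg.lstsq(gram, r, rcond=None)
        z = z + dz
    coef = c_part + N @ z

    resid = np.abs(A @ coef - yf)
    scale = np.maximum(np.abs(yf), 1.0)
    if np.any(resid > 1e-9 * scale):
        raise DegenerateFitError("constraints not satisfied to tolerance")
    return coef


def constrained_polyfit_kkt(x, y, degree: int, fixed_points=()):
    """Lagrange-multiplier (KKT) solve of the same constrained problem.

    Independent of :func:`constrained_polyfit`; kept as an internal oracle the
    tests compare against.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fixed = _check_fixed_points(fixed_points)
    n_coef = degree + 1
    V = np.vander(x, n_coef, increasing=True)
    if not fixed:
        coef, *_ = np.linalg.lstsq(V, y, rcond=None)
        return coef
    xf = np.array([p[0] for p in fixed])
    yf = np.array([p[1] for p in fixed])
    A = np.vander(xf, n_coef, increasing=True)
    m = len(fixed)
    kkt = np.zeros((n_coef + m, n_coef + m))
    kkt[:n_coef, :n_coef] = 2.0 * V.T @ V
    kkt[:n_coef, n_coef:] = A.T
    kkt[n_coef:, :n_coef] = A
    rhs = np.concatenate([2.0 * V.T @ y, yf])
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    for _ in range(3):  # iterative refinement, same rationale as the primal path
        r = rhs - kkt @ sol
        d, *_ = np.linalg.lstsq(kkt, r, rcond=None)
        sol = sol + d
    return sol[:n_coef]


# ---------------------------------------------------------------------------
# branch fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchFit:
    """The fitted hysteresis parameter of one branch plus its two anchors."""

    a_hys: float        # mg C m-2 d-1 degC-2
    t_max: float        # degC
    f_at_tmax: float    # mg C m-2 d-1
    branch: str         # earlier | later | full
    n_points: int
    rmse: float
    intercept: float = 0.0  # flux anchored at 0 degC (nonzero for the
                            # near-zero-flux sensitivity variant)

    def linear_coef(self) -> float:
        return (self.f_at_tmax - self.intercept) / self.t_max - self.a_hys * self.t_max


def eval_curve(fit: BranchFit, T) -> np.ndarray:
    """Evaluate the constrained quadratic at temperatures ``T`` (degC)."""
    T = np.asarray(T, dtype=float)
    return fit.a_hys * T**2 + fit.linear_coef() * T + fit.intercept


def fit_branch(
    T,
    F,
    t_max: float,
    f_at_tmax: float,
    branch: str = "full",
    intercept: float = 0.0,
) -> BranchFit:
    """Least-squares fit of the one-parameter constrained quadratic.

    Closed form: with ``x' = T**2 - T_max*T`` and ``y'`` the flux after
    removing the anchored chord, ``a_hys = sum(x'y') / sum(x'**2)``.  This is
    exactly the degree-2 :func:`constrained_polyfit` with fixed points
    ``(0, intercept)`` and ``(t_max, f_at_tmax)``.
    """
    if t_max <= 0:
        raise ValueError(f"t_max must be positive (got {t_max})")
    T = np.asarray(T, dtype=float)
    F = np.asarray(F, dtype=float)
    ok = np.isfinite(T) & np.isfinite(F)
    T, F = T[ok], F[ok]
    if T.size == 0:
        raise DegenerateFitError(f"empty {branch} branch")
    chord = (f_at_tmax - intercept) / t_max
    xp = T**2 - t_max * T
    yp = F - intercept - chord * T
    sxx = float(np.sum(xp * xp))
    if sxx == 0.0:
        raise DegenerateFitError("all temperatures sit on the anchors; a_hys unidentifiable")
    a = float(np.sum(xp * yp) / sxx)
    fit = BranchFit(
        a_hys=a,
        t_max=float(t_max),
        f_at_tmax=float(f_at_tmax),
        branch=branch,
        n_points=int(T.size),
        rmse=0.0,
        intercept=float(intercept),
    )
    rmse = float(np.sqrt(np.mean((eval_curve(fit, T) - F) ** 2)))
    return BranchFit(**{**fit.__dict__, "rmse": rmse})


def fit_alternative_intercept(T, F, t_max, f_at_tmax, F_near_zero, branch="full"):
    """Branch fit anchored at the mean flux measured between -0.5 and 0.5 degC.

    Falls back to the zero intercept when no near-zero measurement exists;
    returns ``(fit, used_fallback)``.
    """
    F_near_zero = np.asarray(F_near_zero, dtype=float)
    F_near_zero = F_near_zero[np.isfinite(F_near_zero)]
    if F_near_zero.size == 0:
        return fit_branch(T, F, t_max, f_at_tmax, branch=branch, intercept=0.0), True
    c = float(np.mean(F_near_zero))
    return fit_branch(T, F, t_max, f_at_tmax, branch=branch, intercept=c), False


# ---------------------------------------------------------------------------
# hysteresis statistics
# ---------------------------------------------------------------------------

def _curve_abs_max(fit: BranchFit) -> float:
    """max |F| over [0, t_max]; candidates are endpoints and interior vertex."""
    candidates = [abs(fit.intercept), abs(fit.f_at_tmax)]
    a, b = fit.a_hys, fit.linear_coef()
    if a != 0.0:
        tv = -b / (2.0 * a)
        if 0.0 < tv < fit.t_max:
            candidates.append(abs(eval_curve(fit, tv)))
    return float(max(candidates))


def hysteresis_area(
    fit_earlier: BranchFit,
    fit_later: BranchFit,
    normalization: str = "fitted_curves",
    measured_abs_max: float | None = None,
) -> float:
    """Normalized loop area H_A between the two branch curves.

    The numerator is closed-form: since both curves share their anchors,
    ``integral_0^Tmax (F_later - F_earlier) dT = (a_early - a_late) * Tmax**3 / 6``.
    The default denominator is the analytic max |F| over both fitted curves on
    [0, T_max] times T_max; ``normalization="measured_max"`` substitutes a
    caller-supplied measured maximum absolute flux instead.
    """
    if not np.isclose(fit_earlier.t_max, fit_later.t_max) or not np.isclose(
        fit_earlier.f_at_tmax, fit_later.f_at_tmax
    ):
        raise ValueError("branch fits do not share their anchors")
    t_max = fit_earlier.t_max
    numerator = (fit_earlier.a_hys - fit_later.a_hys) * t_max**3 / 6.0
    if normalization == "measured_max":
        if measured_abs_max is None:
            raise ValueError("measured_abs_max required for measured_max normalization")
        fmax = float(abs(measured_abs_max))
    else:
        fmax = max(_curve_abs_max(fit_earlier), _curve_abs_max(fit_later))
    if fmax == 0.0:
        raise UndefinedAreaError("both branch curves are identically zero")
    return float(numerator / (fmax * t_max))


def hysteresis_mean(F_earlier_days, F_later_days) -> float:
    """H_mu: mean measured daily flux, later branch minus earlier branch."""
    fe = np.asarray(F_earlier_days, dtype=float)
    fl = np.asarray(F_later_days, dtype=float)
    fe, fl = fe[np.isfinite(fe)], fl[np.isfinite(fl)]
    if fe.size == 0 or fl.size == 0:
        raise DegenerateFitError("empty branch in hysteresis_mean")
    return float(np.mean(fl) - np.mean(fe))


def classify_sign(h_area: float, tol: float = 1e-12) -> str:
    if h_area > tol:
        return "positive"
    if h_area < -tol:
        return "negative"
    return "zero"


@dataclass
class HysteresisResult:
    """H_A, H_mu, branch fits and sign for one site-year and one driver."""

    site_id: str
    season_year: int
    driver: str
    h_area: float
    h_mu: float
    fit_earlier: BranchFit
    fit_later: BranchFit
    sign: str
    season_start: object = None
    season_end: object = None
    ecosystem_type: str | None = None
    latitude: float | None = None


# ---------------------------------------------------------------------------
# Boltzmann-Arrhenius apparent activation energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrheniusFit:
    e_a: float          # apparent activation energy, eV
    epsilon: float      # log base-rate intercept
    n_points: int
    n_excluded: int     # non-positive-flux days dropped (log undefined)
    r_squared: float
    k: float = BOLTZMANN_EV


def fit_arrhenius(T_kelvin, F) -> ArrheniusFit:
    """OLS of ln(F) against -1/(kT); days with F <= 0 are excluded and counted."""
    T = np.asarray(T_kelvin, dtype=float)
    F = np.asarray(F, dtype=float)
    ok = np.isfinite(T) & np.isfinite(F)
    T, F = T[ok], F[ok]
    if np.any(T <= 0):
        raise ValueError("temperatures must be in kelvin (> 0)")
    pos = F > 0
    n_excl = int(np.sum(~pos))
    T, F = T[pos], F[pos]
    if T.size < 3:
        raise InsufficientDataError(f"only {T.size} positive-flux days (need >= 3)")
    x = -1.0 / (BOLTZMANN_EV * T)
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("zero temperature variance")
    y = np.log(F)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ArrheniusFit(
        e_a=float(slope),
        epsilon=float(intercept),
        n_points=int(T.size),
        n_excluded=n_excl,
        r_squared=r2,
    )


def arrhenius_predict(fit: ArrheniusFit, T_kelvin) -> np.ndarray:
    T = np.asarray(T_kelvin, dtype=float)
    return np.exp(fit.e_a * (-1.0 / (BOLTZMANN_EV * T)) + fit.epsilon)


# ---------------------------------------------------------------------------
# functional-form robustness
# ---------------------------------------------------------------------------

POLY_DEGREES = (1, 2, 3, 5)


def compare_functional_forms(T, F, t_max: float, f_at_tmax: float) -> dict:
    """RMSE of each candidate temperature-response form on the same days.

    Polynomials of degree 1, 2, 3 and 5 are fit through both anchors
    ((0, 0) and (t_max, f_at_tmax)); the Boltzmann-Arrhenius form is fit
    unconstrained on positive-flux days.  Per-form failures are recorded as
    error strings, not raised.
    """
    T = np.asarray(T, dtype=float)
    F = np.asarray(F, dtype=float)
    ok = np.isfinite(T) & np.isfinite(F)
    T, F = T[ok], F[ok]
    out: dict[str, float | str] = {}
    anchors = [(0.0, 0.0), (float(t_max), float(f_at_tmax))]
    for d in POLY_DEGREES:
        key = f"poly{d}"
        try:
            coef = constrained_polyfit(T, F, d, anchors)
            pred = np.polynomial.polynomial.polyval(T, coef)
            out[key] = float(np.sqrt(np.mean((pred - F) ** 2)))
        except Exception as exc:  # per-form errors recorded, not raised
            out[key] = f"error: {exc}"
    try:
        fit = fit_arrhenius(T + CELSIUS_ZERO, F)
        pred = arrhenius_predict(fit, T + CELSIUS_ZERO)
        out["arrhenius"] = float(np.sqrt(np.mean((pred - F) ** 2)))
    except Exception as exc:
        out["arrhenius"] = f"error: {exc}"
    return out
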