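"""Second-fermentation kinetics: pressure normalization, 5PL fits, kinetic traits.

In-bottle second fermentation is followed by the CO2 pressure a sealed bottle
builds over time (aphrometer readings, bar). Readings taken at the fermentation
temperature are first expressed at a reference temperature via a van 't Hoff
scaling of the CO2 Henry constant, then each strain x replicate curve is fitted
with a five-parameter asymmetric logistic (5PL),

    P(t) = A + (D - A) / (1 + (t/C)^(-B))^G

with lower asymptote ``A`` fixed at 0 by default (a freshly sealed bottle holds
no excess pressure). Five kinetic traits are read off the fitted curve: the
pressure plateau ``Pmax`` (= D), the maximum fermentation speed ``rate``
(bar/day, the maximum of the analytic first derivative), and the times to reach
0.5, 2 and 5 bar (``t0.5``, ``t2``, ``t5``) by monotone inversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit, least_squares, minimize_scalar

__all__ = [
    "TRAIT_NAMES",
    "TRAIT_DIRECTIONS",
    "KineticFit",
    "TraitVector",
    "normalize_pressure",
    "pl5",
    "fit_5pl",
    "extract_traits",
    "traits_from_params",
    "curve_traits",
    "solve_params_for_traits",
    "fit_curves_table",
    "aggregate_traits",
    "REF_PARAMS",
]

TRAIT_NAMES = ("Pmax", "rate", "t0.5", "t2", "t5")

#: Direction in which a trait is "better" (faster fermentation): +1 higher, -1 lower.
TRAIT_DIRECTIONS = {"Pmax": +1, "rate": +1, "t0.5": -1, "t2": -1, "t5": -1}

DEFAULT_THRESHOLDS = (0.5, 2.0, 5.0)

#: Reference 5PL parameters (D, C, B, G) of a typical well-behaved fermentation
#: curve; used as the multi-purpose initial guess / fill-in shape.
REF_PARAMS = {"d": 5.8, "c": 6.0, "b": 4.0, "g": 1.2}

_ZERO_C = -273.15


def threshold_label(x: float) -> str:
    """Canonical trait name for a pressure threshold: 0.5 -> 't0.5', 2.0 -> 't2'."""
    return f"t{x:g}"


def normalize_pressure(p_obs, t_obs_c, t_ref_c: float = 10.0, vant_hoff_k: float = 2400.0):
    """Express a pressure reading at a reference temperature.

    The dissolved/gaseous CO2 balance follows Henry's law; the Henry constant's
    temperature dependence is modelled with a van 't Hoff factor so that

        p_ref = p_obs * exp(K * (1/T_obs - 1/T_ref))       (T in kelvin)

    which is the identity when ``t_obs_c == t_ref_c`` and maps a reading taken
    warmer than the reference to a *lower* reference-scale pressure (CO2 is
    less soluble when warm, so the warm reading overstates the produced CO2).

    Parameters
    ----------
    p_obs : float or array
        Observed pressure(s), bar; must be non-negative.
    t_obs_c, t_ref_c : float or array
        Observation and reference temperatures, deg C.
    vant_hoff_k : float
        van 't Hoff constant, kelvin (enthalpy scale of CO2 dissolution).
    """
    p_obs = np.asarray(p_obs, dtype=float)
    t_obs_c = np.asarray(t_obs_c, dtype=float)
    if np.any(t_obs_c <= _ZERO_C) or np.any(np.asarray(t_ref_c) <= _ZERO_C):
        raise ValueError("temperature at or below absolute zero")
    if np.any(p_obs < 0):
        raise ValueError("negative pressure")
    t_obs_k = t_obs_c + 273.15
    t_ref_k = np.asarray(t_ref_c, dtype=float) + 273.15
    out = p_obs * np.exp(vant_hoff_k * (1.0 / t_obs_k - 1.0 / t_ref_k))
    return float(out) if out.ndim == 0 else out


def pl5(t, d, c, b, g, a: float = 0.0):
    """Five-parameter logistic P(t) = A + (D-A)/(1 + (t/C)^(-B))^G (t >= 0)."""
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    y = np.full(t_arr.shape, float(a))
    pos = t_arr > 0
    with np.errstate(divide="ignore", over="ignore", under="ignore"):
        u = (t_arr[pos] / c) ** (-b)
        y[pos] = a + (d - a) / (1.0 + u) ** g
    return float(y[0]) if scalar else y


def _pl5_slope(t, d, c, b, g, a: float = 0.0):
    """Analytic first derivative of the 5PL, bar/day."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros(t_arr.shape)
    pos = t_arr > 0
    with np.errstate(divide="ignore", over="ignore", under="ignore"):
        u = (t_arr[pos] / c) ** (-b)
        out[pos] = (d - a) * g * b * u / (t_arr[pos] * (1.0 + u) ** (g + 1.0))
    out[~np.isfinite(out)] = 0.0
    return float(out[0]) if np.asarray(t).ndim == 0 else out


@dataclass
class KineticFit:
    """A fitted 5PL curve for one strain x replicate."""

    d: float
    c: float
    b: float
    g: float
    a: float = 0.0
    residual_sd: float = float("nan")
    converged: bool = True
    n_obs: int = 0
    message: str = ""

    def __call__(self, t):
        return pl5(t, self.d, self.c, self.b, self.g, self.a)

    def slope(self, t):
        return _pl5_slope(t, self.d, self.c, self.b, self.g, self.a)

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.d, self.c, self.b, self.g)


@dataclass
class TraitVector:
    """Kinetic traits with per-trait availability.

    Unavailable traits (threshold above the plateau, or an unbounded initial
    slope) are NaN; ``available`` mirrors that as booleans.
    """

    pmax: float
    rate: float
    times: dict[float, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out = {"Pmax": self.pmax, "rate": self.rate}
        for thr in sorted(self.times):
            out[threshold_label(thr)] = self.times[thr]
        return out

    @property
    def available(self) -> dict[str, bool]:
        return {k: bool(np.isfinite(v)) for k, v in self.as_dict().items()}


def traits_from_params(d, c, b, g, a: float = 0.0, thresholds=DEFAULT_THRESHOLDS) -> TraitVector:
    """Analytic kinetic traits of a 5PL curve.

    * ``Pmax`` is the upper asymptote D.
    * ``rate`` is the maximum of dP/dt over t > 0, available when B*G > 1
      (otherwise the slope is unbounded as t -> 0+).
    * Each threshold time solves P(t) = X in closed form and is unavailable
      when X >= D (never reached) or X <= A.
    """
    if d <= a:
        raise ValueError("upper asymptote D must exceed lower asymptote A")
    if c <= 0 or b <= 0 or g <= 0:
        raise ValueError("C, B and G must be positive")
    # maximum slope: d(ln slope)/d(ln t) = 0  =>  u/(1+u) = (B+1)/(B(G+1))
    q = (b + 1.0) / (b * (g + 1.0))
    if q < 1.0:  # equivalent to B*G > 1
        u_star = q / (1.0 - q)
        t_star = c * u_star ** (-1.0 / b)
        rate = _pl5_slope(t_star, d, c, b, g, a)
    else:
        rate = float("nan")
    times: dict[float, float] = {}
    for x in thresholds:
        if a < x < d:
            u = ((d - a) / (x - a)) ** (1.0 / g) - 1.0
            times[float(x)] = c * u ** (-1.0 / b) if u > 0 else float("nan")
        else:
            times[float(x)] = float("nan")
    return TraitVector(pmax=float(d), rate=float(rate), times=times)


def extract_traits(fit: KineticFit, thresholds=DEFAULT_THRESHOLDS) -> TraitVector:
    """Kinetic traits of a converged 5PL fit (see :func:`traits_from_params`)."""
    if not fit.converged:
        raise ValueError("traits are only extracted from converged fits")
    return traits_from_params(fit.d, fit.c, fit.b, fit.g, fit.a, thresholds)


def curve_traits(f, pmax: float, thresholds=DEFAULT_THRESHOLDS, df=None,
                 t_max: float = 200.0, baseline: float = 0.0) -> TraitVector:
    """Numeric kinetic traits of an arbitrary monotone pressure curve.

    Used for ground-truth checks and for curves outside the 5PL family (e.g. a
    plain logistic). Threshold times are found by bisection to ~1e-12 and the
    rate by maximizing the derivative ``df`` (central differences when ``df``
    is not given).
    """
    if df is None:
        h = 1e-5

        def df(t, _f=f):  # noqa: E731 - small local derivative
            return (_f(t + h) - _f(t - h)) / (2.0 * h)

    res = minimize_scalar(lambda t: -df(t), bounds=(1e-9, t_max), method="bounded",
                          options={"xatol": 1e-10})
    rate = float(df(res.x))
    times: dict[float, float] = {}
    for x in thresholds:
        if baseline < x < pmax and f(t_max) > x:
            times[float(x)] = float(brentq(lambda t: f(t) - x, 1e-12, t_max, xtol=1e-12))
        else:
            times[float(x)] = float("nan")
    return TraitVector(pmax=float(pmax), rate=rate, times=times)


def fit_5pl(times, pressures, a: float | None = 0.0, thresholds=DEFAULT_THRESHOLDS) -> KineticFit:
    """Least-squares 5PL fit of one normalized pressure curve.

    Parameters
    ----------
    times, pressures : arrays
        Observation times (days, strictly increasing) and non-negative
        normalized pressures (bar). At least 5 observations are required.
    a : float or None
        Lower asymptote. Fixed at 0 by default; pass ``None`` to free it.

    Multi-start deterministic initialization: D from the maximum observed
    pressure, C from the time of half-maximum, B in {1, 2, 4} and G in
    {0.5, 1, 2}; the start with the best SSE wins. A fit that fails every
    start (or a degenerate flat curve) is returned with ``converged=False``
    and traits are withheld downstream.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(pressures, dtype=float)
    if t.ndim != 1 or t.shape != p.shape:
        raise ValueError("times and pressures must be 1-D arrays of equal length")
    if len(t) < 5:
        raise ValueError("at least 5 observations are required for a 5PL fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(p < 0):
        raise ValueError("pressures must be non-negative")

    free_a = a is None
    a0 = 0.0 if free_a else float(a)
    pmax = float(p.max())
    if pmax <= a0 + 1e-9:
        return KineticFit(d=np.nan, c=np.nan, b=np.nan, g=np.nan, a=a0,
                          converged=False, n_obs=len(t), message="flat curve")

    half = a0 + 0.5 * (pmax - a0)
    above = np.nonzero(p >= half)[0]
    c0 = float(t[above[0]]) if len(above) and t[above[0]] > 0 else max(float(t[t > 0][0]), 0.5)

    def model_fixed(tt, d, c, b, g):
        return pl5(tt, d, c, b, g, a0)

    def model_free(tt, d, c, b, g, aa):
        return pl5(tt, d, c, b, g, aa)

    t_hi = max(float(t[-1]), 1.0)
    best = None
    for b0 in (1.0, 2.0, 4.0):
        for g0 in (0.5, 1.0, 2.0):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if free_a:
                        popt, _ = curve_fit(
                            model_free, t, p, p0=[pmax, c0, b0, g0, 0.0],
                            bounds=([1e-9, 1e-6, 0.02, 0.02, -10.0],
                                    [50.0 * pmax, 200.0 * t_hi, 80.0, 80.0, pmax]),
                            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
                    else:
                        popt, _ = curve_fit(
                            model_fixed, t, p, p0=[pmax, c0, b0, g0],
                            bounds=([1e-9, 1e-6, 0.02, 0.02],
                                    [50.0 * pmax, 200.0 * t_hi, 80.0, 80.0]),
                            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except (RuntimeError, ValueError):
                continue
            resid = p - pl5(t, *popt) if free_a else p - pl5(t, *popt, a0)
            sse = float(resid @ resid)
            if math.isfinite(sse) and (best is None or sse < best[0]):
                best = (sse, popt)

    if best is None:
        return KineticFit(d=np.nan, c=np.nan, b=np.nan, g=np.nan, a=a0,
                          converged=False, n_obs=len(t), message="no start converged")
    sse, popt = best
    n_par = 5 if free_a else 4
    dof = max(len(t) - n_par, 1)
    fit_a = float(popt[4]) if free_a else a0
    return KineticFit(d=float(popt[0]), c=float(popt[1]), b=float(popt[2]),
                      g=float(popt[3]), a=fit_a,
                      residual_sd=math.sqrt(sse / dof), converged=True, n_obs=len(t))


def solve_params_for_traits(targets: dict[str, float],
                            reference: dict[str, float] = REF_PARAMS):
    """Find 5PL parameters (A=0) whose analytic traits match target values.

    ``targets`` maps trait names ("Pmax", "rate", "t0.5", "t2", "t5") to the
    desired values. D is taken from "Pmax" (reference D when absent); (C, B, G)
    are solved in log space against the rate/threshold targets. When fewer than
    three such targets are given the remainder are pinned to the reference
    curve's own traits, making the system exactly determined; with four the
    solution is the least-squares compromise.

    Returns ``(params, achieved)`` where ``achieved`` are the analytic traits
    of the solved curve (these, not the targets, are what a synthesized curve
    actually exhibits).
    """
    d = float(targets.get("Pmax", reference["d"]))
    if d <= 0:
        raise ValueError("non-physical kinetics: Pmax must be positive")
    priority = ("rate", "t2", "t5", "t0.5")
    thr_of = {"t0.5": 0.5, "t2": 2.0, "t5": 5.0}
    for k in priority:
        if k in targets and not (np.isfinite(targets[k]) and targets[k] > 0):
            raise ValueError(f"non-physical kinetics: {k} must be positive and finite")
    ref_traits = traits_from_params(d, reference["c"], reference["b"], reference["g"]).as_dict()
    goals = {k: float(targets[k]) for k in priority if k in targets}
    for k in priority:
        if len(goals) >= 3:
            break
        if k not in goals:
            goals[k] = ref_traits[k]
    keys = [k for k in priority if k in goals]
    log_goal = np.log([goals[k] for k in keys])

    def residual(x):
        c, b, g = np.exp(x)
        tv = traits_from_params(d, c, b, g, thresholds=(0.5, 2.0, 5.0)).as_dict()
        ach = np.array([tv[k] if np.isfinite(tv[k]) and tv[k] > 0 else 1e-9 for k in keys])
        return np.log(ach) - log_goal

    x0 = np.log([reference["c"], reference["b"], reference["g"]])
    sol = least_squares(residual, x0, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    c, b, g = np.exp(sol.x)
    achieved = traits_from_params(d, c, b, g).as_dict()
    return {"d": d, "c": float(c), "b": float(b), "g": float(g), "a": 0.0}, achieved


def fit_curves_table(curves, t_ref_c: float = 10.0, vant_hoff_k: float = 2400.0,
                     a: float | None = 0.0, thresholds=DEFAULT_THRESHOLDS):
    """Normalize and fit every strain x replicate curve of a long-format table.

    ``curves`` is a DataFrame with columns strain, replicate, time_days,
    pressure_bar, temperature_C. Returns ``(traits, fits)``: one row per
    strain x replicate with the extracted traits (NaN when unavailable or not
    converged) and the dict of :class:`KineticFit` keyed by (strain, replicate).
    """
    import pandas as pd

    rows = []
    fits: dict[tuple, KineticFit] = {}
    for (strain, rep), grp in curves.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("time_days")
        p_norm = normalize_pressure(grp["pressure_bar"].to_numpy(),
                                    grp["temperature_C"].to_numpy(),
                                    t_ref_c, vant_hoff_k)
        row = {"strain": strain, "replicate": rep}
        try:
            fit = fit_5pl(grp["time_days"].to_numpy(), p_norm, a=a)
        except ValueError as exc:
            fit = KineticFit(np.nan, np.nan, np.nan, np.nan, 0.0, converged=False,
                             n_obs=len(grp), message=str(exc))
        fits[(strain, rep)] = fit
        row["converged"] = fit.converged
        row["residual_sd"] = fit.residual_sd
        if fit.converged:
            row.update(extract_traits(fit, thresholds).as_dict())
        else:
            row.update({k: np.nan for k in ["Pmax", "rate"] + [threshold_label(x) for x in thresholds]})
        rows.append(row)
    return pd.DataFrame(rows), fits


def aggregate_traits(per_replicate, trait_names=None):
    """Per-strain trait means with SE and replicate counts.

    Replicates are fitted independently; the per-strain value of each trait is
    the mean over replicates where it was available.
    """
    import pandas as pd

    if trait_names is None:
        trait_names = [c for c in per_replicate.columns
                       if c not in ("strain", "replicate", "converged", "residual_sd")]
    out = []
    for strain, grp in per_replicate.groupby("strain", sort=True):
        row = {"strain": strain, "n_replicates": len(grp)}
        for tname in trait_names:
            vals = grp[tname].dropna()
            row[tname] = vals.mean() if len(vals) else np.nan
            row[f"{tname}_se"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                                  if len(vals) > 1 else np.nan)
        out.append(row)
    return pd.DataFrame(out)
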