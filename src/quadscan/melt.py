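"""Two-state van't Hoff analysis of thermal melting curves.

The observed signal (e.g. CD ellipticity near 265 nm) is modelled as a
population-weighted mix of a folded and an unfolded state, each with its
own linear baseline::

    S(T) = (b_f + m_f T) * f(T) + (b_u + m_u T) * (1 - f(T))

where the folded fraction follows a two-state equilibrium with van't Hoff
enthalpy ``dH`` and mid-transition temperature ``Tm`` (f(Tm) = 1/2)::

    K(T) = exp[-(dH / R) (1/T - 1/Tm)],   f = K / (1 + K)     (molecularity 1)

``dH < 0`` in this convention for a transition that is folded at low
temperature.  The entropy is tied to the midpoint, ``dS = dH / Tm``, so the
stability at a reference temperature is ``dG(T_ref) = dH (1 - T_ref / Tm)``
(temperatures in kelvin); negative ``dG`` means the fold is favored there.

For molecularity m > 1 (multimeric folds of unknown strand concentration)
the folded fraction is taken to solve ``theta / (1 - theta)^m =
g(1/2) * K(T)`` so the midpoint convention theta(Tm) = 1/2 is preserved
without requiring a concentration; this changes only the steepness of the
transition, not the midpoint.

Interfaces use degrees Celsius; kelvin is internal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, TextIO

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_coeffs, savgol_filter

__all__ = [
    "R_KJ",
    "CELSIUS_OFFSET",
    "Baselines",
    "MeltCurve",
    "TwoStateFit",
    "MeltFitError",
    "FlatCurveError",
    "fraction_folded",
    "tm_from_derivative",
    "fit_two_state",
    "read_curve",
    "write_report",
]

R_KJ = 8.314462618e-3  # gas constant, kJ / (mol K)
CELSIUS_OFFSET = 273.15


class MeltFitError(RuntimeError):
    """Two-state fit failed to converge; message carries diagnostics."""


class FlatCurveError(MeltFitError):
    """No transition detectable above the derivative noise floor."""


class Baselines(NamedTuple):
    """Linear baselines (intercept, slope vs degrees C) of each state."""

    folded_intercept: float
    folded_slope: float
    unfolded_intercept: float
    unfolded_slope: float


@dataclass(frozen=True)
class MeltCurve:
    """Temperature/signal series with strictly increasing temperature (C)."""

    temperatures: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("temperatures and signal must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ValueError("non-finite values in melt curve")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signal", s)

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass(frozen=True)
class TwoStateFit:
    """Result of a two-state melt fit.

    ``dg_ref_kj_mol`` is ``dH (1 - T_ref/Tm)`` at ``t_ref_celsius``;
    ``ds_kj_mol_k = dH / Tm``.  ``warnings`` flags soft problems such as a
    transition near the edge of the temperature range.
    """

    tm_celsius: float
    dh_kj_mol: float
    baselines: Baselines
    t_ref_celsius: float
    dg_ref_kj_mol: float
    ds_kj_mol_k: float
    molecularity: int
    rms: float
    covariance: np.ndarray
    n_points: int
    warnings: tuple[str, ...] = ()

    def fraction_folded(self, t_celsius):
        return fraction_folded(
            np.asarray(t_celsius, dtype=float) + CELSIUS_OFFSET,
            self.tm_celsius + CELSIUS_OFFSET,
            self.dh_kj_mol,
            self.molecularity,
        )


def _theta_multimer(k: np.ndarray, m: int) -> np.ndarray:
    # solve theta/(1-theta)^m = g(1/2) * k by bisection (g monotone on (0,1))
    g_half = 0.5 / 0.5**m
    target = g_half * k
    lo = np.zeros_like(target)
    hi = np.ones_like(target)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val = mid / (1.0 - mid) ** m
        high = val > target
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    return 0.5 * (lo + hi)


def fraction_folded(t_kelvin, tm_kelvin: float, dh_kj_mol: float, molecularity: int = 1):
    """Folded fraction of a two-state transition at temperature(s) T (K).

    Overflow-guarded: extreme arguments clamp smoothly to 0/1.  Scalar in,
    scalar out.
    """
    if tm_kelvin <= 0:
        raise ValueError("tm must be positive (kelvin)")
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive (kelvin)")
    expo = np.clip(-(dh_kj_mol / R_KJ) * (1.0 / t - 1.0 / tm_kelvin), -500, 500)
    k = np.exp(expo)
    if molecularity == 1:
        theta = k / (1.0 + k)
    else:
        theta = _theta_multimer(np.atleast_1d(k), int(molecularity))
        theta = theta.reshape(t.shape) if t.shape else theta[0]
    return float(theta) if np.isscalar(t_kelvin) else theta


def tm_from_derivative(
    curve: MeltCurve,
    window_length: int | None = None,
    polyorder: int = 3,
) -> float:
    """Tm estimate from the extremum of the smoothed melting-curve derivative.

    The signal is resampled onto a uniform grid in inverse kelvin — the
    coordinate in which a two-state transition is exactly symmetric, so the
    derivative extremum sits at Tm without the low-temperature skew the
    dS/dT curve acquires for broad transitions — smoothed with a local
    polynomial (Savitzky-Golay) filter and differentiated.  The extremum is
    refined by a parabola through the neighbouring grid points.  A curve
    with no interior derivative excursion above the noise floor (flat,
    pure drift, or transition at the range edge) raises
    :class:`FlatCurveError`.
    """
    n = len(curve)
    if n < 10:
        raise ValueError("derivative Tm needs at least 10 points")
    t_c, sig = curve.temperatures, curve.signal
    # ascending uniform grid in u = 1/T(K); T descends with u, sig reversed
    u_raw = 1.0 / (t_c + CELSIUS_OFFSET)
    u = np.linspace(u_raw[-1], u_raw[0], n)
    s = np.interp(u, u_raw[::-1], sig[::-1])
    delta = float(u[1] - u[0])
    if window_length is None:
        window_length = max(polyorder + 2, n // 10)
    window_length = min(window_length | 1, (n - 1) | 1 if n % 2 == 0 else n)
    deriv = savgol_filter(s, window_length, polyorder, deriv=1, delta=delta)
    centered = deriv - np.median(deriv)
    # point-noise estimate from second differences (std sigma*sqrt(6) for
    # iid noise; near zero for a smooth curve), propagated through the
    # derivative filter coefficients
    d2 = np.diff(s, 2)
    sigma = float(np.median(np.abs(d2 - np.median(d2)))) / (0.6745 * np.sqrt(6.0))
    coeffs = savgol_coeffs(window_length, polyorder, deriv=1, delta=delta, use="dot")
    sigma_deriv = sigma * float(np.linalg.norm(coeffs))
    scale_floor = 1e-3 * (np.ptp(s) + 1e-300) / (u[-1] - u[0])
    interior = centered[2 : n - 2]
    peak = float(np.max(np.abs(interior)))
    if peak < max(5.0 * sigma_deriv, scale_floor) or peak < float(
        np.max(np.abs(centered[[0, 1, n - 2, n - 1]]))
    ):
        raise FlatCurveError(
            f"no interior transition above derivative noise floor "
            f"(peak {peak:.3g}, derivative noise {sigma_deriv:.3g})"
        )
    i = 2 + int(np.argmax(np.abs(interior)))
    u_peak = u[i]
    y0, y1, y2 = centered[i - 1 : i + 2]
    denom = y0 - 2 * y1 + y2
    if abs(denom) > 1e-300:
        u_peak = u[i] + 0.5 * (y0 - y2) / denom * delta
    return float(1.0 / u_peak - CELSIUS_OFFSET)


def _linear_fit(t: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    if t.size < 2:
        return float(s.mean()) if t.size else 0.0, 0.0
    slope, intercept = np.polyfit(t, s, 1)
    return float(intercept), float(slope)


def fit_two_state(
    curve: MeltCurve,
    molecularity: int = 1,
    t_ref_celsius: float = 0.0,
) -> TwoStateFit:
    """Nonlinear least-squares two-state fit with floating linear baselines.

    Tm is initialized from :func:`tm_from_derivative` (falling back to the
    range midpoint, with a warning, if no transition is detectable) and
    baselines from the outer 15% of points at each end.  Non-convergence
    raises :class:`MeltFitError`.
    """
    n = len(curve)
    if n < 10:
        raise ValueError("two-state fit needs at least 10 points")
    t_c, s = curve.temperatures, curve.signal
    warnings: list[str] = []

    try:
        tm0 = tm_from_derivative(curve)
    except FlatCurveError:
        tm0 = float(0.5 * (t_c[0] + t_c[-1]))
        warnings.append("no clear transition; Tm initialized at range midpoint")
    edge = max(5.0, 0.05 * (t_c[-1] - t_c[0]))
    k = max(3, n * 15 // 100)
    bf0, mf0 = _linear_fit(t_c[:k], s[:k])
    bu0, mu0 = _linear_fit(t_c[-k:], s[-k:])
    p0 = [tm0, -250.0, bf0, mf0, bu0, mu0]

    def model(t, tm, dh, bf, mf, bu, mu):
        f = fraction_folded(t + CELSIUS_OFFSET, tm + CELSIUS_OFFSET, dh, molecularity)
        return (bf + mf * t) * f + (bu + mu * t) * (1.0 - f)

    bounds = (
        [t_c[0] - 50.0, -5000.0, -np.inf, -np.inf, -np.inf, -np.inf],
        [t_c[-1] + 50.0, -1e-3, np.inf, np.inf, np.inf, np.inf],
    )
    try:
        popt, pcov = curve_fit(model, t_c, s, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise MeltFitError(
            f"two-state fit did not converge (p0={p0}, n={n}): {err}"
        ) from err

    tm, dh, bf, mf, bu, mu = (float(v) for v in popt)
    resid = s - model(t_c, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if tm < t_c[0] + edge or tm > t_c[-1] - edge:
        warnings.append("transition near or beyond edge of temperature range")
    tm_k = tm + CELSIUS_OFFSET
    t_ref_k = t_ref_celsius + CELSIUS_OFFSET
    dg_ref = dh * (1.0 - t_ref_k / tm_k)
    return TwoStateFit(
        tm_celsius=tm,
        dh_kj_mol=dh,
        baselines=Baselines(bf, mf, bu, mu),
        t_ref_celsius=t_ref_celsius,
        dg_ref_kj_mol=dg_ref,
        ds_kj_mol_k=dh / tm_k,
        molecularity=molecularity,
        rms=rms,
        covariance=pcov,
        n_points=n,
        warnings=tuple(warnings),
    )


def read_curve(path: str | Path, metadata: dict | None = None) -> MeltCurve:
    """Read a two-column temperature(C)/signal table (CSV or TSV).

    A header row is optional and detected by non-numeric content; ``#``
    lines are comments.  Extra columns are ignored.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    first = df.iloc[0]
    try:
        [float(v) for v in first.iloc[:2]]
    except (TypeError, ValueError):
        df = df.iloc[1:]
    t = df.iloc[:, 0].astype(float).to_numpy()
    s = df.iloc[:, 1].astype(float).to_numpy()
    order = np.argsort(t)
    return MeltCurve(t[order], s[order], metadata or {})


def fit_to_dict(fit: TwoStateFit) -> dict:
    return {
        "tm_celsius": fit.tm_celsius,
        "dh_kj_mol": fit.dh_kj_mol,
        "ds_kj_mol_k": fit.ds_kj_mol_k,
        "t_ref_celsius": fit.t_ref_celsius,
        "dg_ref_kj_mol": fit.dg_ref_kj_mol,
        "molecularity": fit.molecularity,
        "baselines": list(fit.baselines),
        "rms": fit.rms,
        "n_points": fit.n_points,
        "warnings": list(fit.warnings),
    }


def write_report(fit: TwoStateFit, json_handle: TextIO | None = None,
                 tsv_handle: TextIO | None = None) -> None:
    """Write the fit as JSON and/or a one-row TSV."""
    d = fit_to_dict(fit)
    if json_handle is not None:
        json.dump(d, json_handle, indent=2)
        json_handle.write("\n")
    if tsv_handle is not None:
        keys = [k for k in d if k not in ("baselines", "warnings")]
        tsv_handle.write("\t".join(keys + ["baselines", "warnings"]) + "\n")
        row = [f"{d[k]:.6g}" if isinstance(d[k], float) else str(d[k]) for k in keys]
        row.append(",".join(f"{b:.6g}" for b in d["baselines"]))
        row.append(";".join(d["warnings"]))
        tsv_handle.write("\t".join(row) + "\n")
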