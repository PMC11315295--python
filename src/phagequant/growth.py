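"""Logistic growth-curve fitting for buffer-treated control cultures.

The control (SM-buffer-treated) culture is modelled with the logistic
equation

    N(t) = K / (1 + ((K - N0)/N0) * exp(-r t))

where ``N0`` is the population size (OD600) at the start of the plate run,
``K`` the carrying capacity, and ``r`` the intrinsic per-hour growth rate.
The fitted curve supplies the expansion-factor inputs ``N_tP`` and ``N_tV``
— the control culture's modelled OD at the times of the infected culture's
pre-lysis peak and post-lysis valley — used by :mod:`phagequant.lysogeny`.

Fits are nonlinear least squares (``scipy.optimize.curve_fit``, trust-region
reflective) with the carrying capacity parameterized as ``K = N0 + delta``,
``delta >= 0``, so ``K >= N0`` holds by construction and the expansion
factor is always well defined. The time origin is the first recorded
timepoint of the curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, NonIdentifiableError
from .io import GrowthCurve

__all__ = [
    "LogisticFitParams",
    "logistic_value",
    "fit_logistic",
    "expansion_factor",
]


@dataclass(frozen=True)
class LogisticFitParams:
    """Fitted logistic parameters for one control culture.

    ``t_origin`` is the clock time (hours) treated as t=0 of the logistic;
    it equals the first recorded timepoint of the fitted curve.
    """

    n0: float
    k: float
    r: float
    rss: float = 0.0
    converged: bool = True
    n_points: int = 0
    t_origin: float = 0.0
    warnings: tuple = ()

    def __post_init__(self):
        if not (self.n0 > 0):
            raise FitError(f"n0 must be positive, got {self.n0}")
        if self.k < self.n0:
            raise FitError(f"k ({self.k}) must be >= n0 ({self.n0})")
        if self.converged and not (self.r > 0):
            raise FitError(f"r must be positive for a converged fit, got {self.r}")
        if self.rss < 0:
            raise FitError("rss must be nonnegative")


def _logistic(t, n0, k, r):
    return k / (1.0 + ((k - n0) / n0) * np.exp(-r * np.asarray(t, dtype=float)))


def logistic_value(params: LogisticFitParams, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted logistic at time ``t`` (hours, plate clock).

    Returns ``N0`` exactly at ``t = t_origin`` and approaches ``K`` as
    ``t`` grows; the value lies in ``(0, K]`` for any ``t >= 0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = _logistic(t - params.t_origin, params.n0, params.k, params.r)
    return float(out) if out.ndim == 0 else out


def _initial_guess(t: np.ndarray, od: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting point: N0 from the first positive OD, K from
    the max OD, r from the log-slope of the 20-80%-of-max window."""
    pos = od[od > 0]
    n0 = float(pos[0]) if len(pos) else 1e-3
    k = float(od.max())
    lo, hi = 0.2 * k, 0.8 * k
    mask = (od >= lo) & (od <= hi) & (od > 0)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(od[mask]), 1)[0]
        r = float(slope) if slope > 0 else 0.5
    else:
        r = 0.5
    return n0, k, max(r, 1e-3)


def fit_logistic(curve: GrowthCurve, *, flat_tol: float = 1e-6) -> LogisticFitParams:
    """Fit the logistic equation to one control growth curve.

    Requires at least 5 timepoints and a rise of more than ``flat_tol``
    between the curve's min and max OD. Flat or strictly decreasing curves
    raise :class:`NonIdentifiableError`; optimizer failure raises
    :class:`FitError` carrying the last iterate and its RSS.
    """
    t_raw = curve.times
    od = curve.od600
    if len(t_raw) < 5:
        raise FitError(
            f"well {curve.well_id!r}: need >= 5 timepoints to fit, got {len(t_raw)}"
        )
    if od.max() - od.min() <= flat_tol:
        raise NonIdentifiableError(
            f"well {curve.well_id!r}: curve is flat (range {od.max() - od.min():g}); "
            "logistic parameters are not identifiable"
        )
    if np.all(np.diff(od) < 0):
        raise NonIdentifiableError(
            f"well {curve.well_id!r}: strictly decreasing curve cannot be "
            "described by logistic growth"
        )
    t0 = float(t_raw[0])
    t = t_raw - t0

    n0_init, k_init, r_init = _initial_guess(t, od)
    p0 = (n0_init, max(k_init - n0_init, 1e-6), r_init)

    def model(tt, n0, delta, r):
        return _logistic(tt, n0, n0 + delta, r)

    tiny = 1e-12
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                t,
                od,
                p0=p0,
                bounds=([tiny, 0.0, tiny], [np.inf, np.inf, np.inf]),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                maxfev=20000,
            )
    except RuntimeError as exc:
        rss = float(np.sum((model(t, *p0) - od) ** 2))
        raise FitError(
            f"well {curve.well_id!r}: logistic fit did not converge: {exc}",
            rss=rss,
            last_params=p0,
        ) from exc

    n0, delta, r = map(float, popt)
    k = n0 + delta
    rss = float(np.sum((model(t, n0, delta, r) - od) ** 2))
    notes = []
    od_max = float(od.max())
    if not (0.5 * od_max <= k <= 3.0 * od_max):
        notes.append(
            f"fitted carrying capacity k={k:.4g} outside sanity window "
            f"[{0.5 * od_max:.4g}, {3.0 * od_max:.4g}]"
        )
    return LogisticFitParams(
        n0=n0,
        k=k,
        r=r,
        rss=rss,
        converged=True,
        n_points=len(t),
        t_origin=t0,
        warnings=tuple(notes),
    )


def expansion_factor(
    params: LogisticFitParams, t_peak: float, t_valley: float
) -> float:
    """Base expansion factor N(t_valley)/N(t_peak) of the fitted control.

    This is the growth the uninfected control put on between the infected
    culture's peak and valley times; it is >= 1 for any valid logistic and
    equals 1 when the two times coincide (or when K = N0).
    """
    if t_valley < t_peak:
        raise ValueError(
            f"t_valley ({t_valley}) must be >= t_peak ({t_peak})"
        )
    return float(logistic_value(params, t_valley) / logistic_value(params, t_peak))
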