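"""Percent-lysogens estimation from Q-induction growth curves.

Inducing the phage lytic regulator Q kills only lysogenized cells, so the
OD600 drop of the phage-treated culture after induction measures the lysogen
fraction. The estimator reads the pre-lysis peak ``OD_P`` (maximum OD at or
before a condition-specific boundary: 4 h planktonic, 5 h surface) and the
post-lysis valley ``OD_V`` (minimum OD after the boundary) off the infected
curve, corrects ``OD_V`` for continued growth of the non-lysogens with an
expansion factor ``E`` derived from the logistic fit of the buffer-treated
control, and reports

    %L = (OD_P - OD_V / E) / OD_P * 100.

With ``N_tP``/``N_tV`` the control's fitted OD at the peak/valley times, the
expansion factor is piecewise: when the infected culture grew at least as
much as the control (``N_tV/N_tP <= OD_V/OD_P``) there was no net lysis and
``E = N_tV/N_tP`` (the raw %L is then provably <= 0); otherwise lysis
occurred, survivors are assumed to regrow faster on released nutrients, and
``E = N_tV/N_tP + (N_tV/OD_V - 1)``. Raw %L is kept for diagnostics and
clamped to [0, 100] for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Sequence

import numpy as np

from .errors import CoverageError
from .growth import LogisticFitParams, fit_logistic, logistic_value
from .io import GrowthCurve

__all__ = [
    "DEFAULT_BOUNDARIES",
    "PeakValley",
    "PercentLysogensResult",
    "LysogenyEstimate",
    "ReplicateSummary",
    "find_peak_valley",
    "percent_lysogens",
    "quantify_lysogeny",
    "aggregate_replicates",
]

#: Peak/valley split times (hours) per growth condition.
DEFAULT_BOUNDARIES = {"planktonic": 4.0, "surface": 5.0}

BRANCH_NO_NET_LYSIS = "no_net_lysis"
BRANCH_SCALED = "scaled"


@dataclass(frozen=True)
class PeakValley:
    """Pre-lysis peak and post-lysis valley of an infected culture."""

    od_p: float
    t_p: float
    od_v: float
    t_v: float
    boundary: float

    def __post_init__(self):
        if not (self.t_p <= self.boundary <= self.t_v):
            raise ValueError(
                f"peak/valley times must bracket the boundary: "
                f"t_p={self.t_p}, boundary={self.boundary}, t_v={self.t_v}"
            )
        if not (self.od_p > 0):
            raise ValueError("peak OD must be positive")


@dataclass(frozen=True)
class PercentLysogensResult:
    """Output of the piecewise %L formula for one (OD_P, OD_V, N_tP, N_tV)."""

    percent_lysogens_raw: float
    percent_lysogens: float
    expansion_factor: float
    branch: str


@dataclass(frozen=True)
class LysogenyEstimate:
    """Complete %L estimate for one phage/buffer curve pair."""

    percent_lysogens_raw: float
    percent_lysogens: float
    expansion_factor: float
    branch: str
    peakvalley: PeakValley
    n_tp: float
    n_tv: float
    fit: LogisticFitParams | None = None
    well_id: str = ""


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and sample SD of clamped %L across replicate estimates."""

    mean_percent: float
    sd_percent: float
    n: int
    sd_defined: bool


def find_peak_valley(curve: GrowthCurve, boundary: float) -> PeakValley:
    """Locate OD_P (max OD at t <= boundary) and OD_V (min OD at t > boundary).

    The split is half-open: a reading exactly at the boundary belongs to the
    peak side. Ties take the earliest timestamp. Raises
    :class:`CoverageError` if the curve lacks points on either side.
    """
    if boundary <= 0:
        raise ValueError(f"boundary must be positive, got {boundary}")
    t, od = curve.times, curve.od600
    before = t <= boundary
    after = t > boundary
    if not before.any() or not after.any():
        raise CoverageError(
            f"well {curve.well_id!r}: curve does not span the boundary "
            f"{boundary:g} h (range {t[0]:g}-{t[-1]:g} h)"
        )
    ip = int(np.argmax(od[before]))          # argmax -> first occurrence on ties
    iv = int(np.argmin(od[after]))
    t_p = float(t[before][ip])
    od_p = float(od[before][ip])
    t_v = float(t[after][iv])
    od_v = float(od[after][iv])
    return PeakValley(od_p=od_p, t_p=t_p, od_v=od_v, t_v=t_v, boundary=boundary)


def percent_lysogens(
    od_p: float, od_v: float, n_tp: float, n_tv: float
) -> PercentLysogensResult:
    """Apply the piecewise %L formula with expansion-factor correction.

    All four inputs must be positive: ``od_p``/``od_v`` are the infected
    culture's peak/valley ODs, ``n_tp``/``n_tv`` the control's fitted ODs at
    the same times.
    """
    for name, v in (("od_p", od_p), ("od_v", od_v), ("n_tp", n_tp), ("n_tv", n_tv)):
        if not (v > 0 and np.isfinite(v)):
            raise ValueError(f"{name} must be positive and finite, got {v}")
    control_ratio = n_tv / n_tp
    observed_ratio = od_v / od_p
    if control_ratio <= observed_ratio:
        branch = BRANCH_NO_NET_LYSIS
        e = control_ratio
    else:
        branch = BRANCH_SCALED
        e = control_ratio + (n_tv / od_v - 1.0)
    raw = (od_p - od_v / e) / od_p * 100.0
    clamped = float(min(max(raw, 0.0), 100.0))
    return PercentLysogensResult(
        percent_lysogens_raw=float(raw),
        percent_lysogens=clamped,
        expansion_factor=float(e),
        branch=branch,
    )


def quantify_lysogeny(
    phage_curve: GrowthCurve,
    buffer_curve: GrowthCurve,
    condition: str | None = None,
    boundary_override: float | None = None,
) -> LysogenyEstimate:
    """End-to-end %L for one phage-treated / buffer-treated curve pair.

    The boundary is 4 h (planktonic) or 5 h (surface) unless overridden.
    The peak and valley come from the phage-treated curve; ``N_tP``/``N_tV``
    are the buffer curve's fitted logistic evaluated exactly at those times
    (the continuous fit makes differing time grids a non-issue).
    """
    condition = condition or phage_curve.condition
    for field_ in ("inducer", "condition", "strain"):
        a, b = getattr(phage_curve, field_), getattr(buffer_curve, field_)
        if a != b:
            raise ValueError(
                f"phage and buffer curves disagree on {field_}: {a!r} vs {b!r}"
            )
    if boundary_override is not None:
        boundary = float(boundary_override)
    else:
        if condition not in DEFAULT_BOUNDARIES:
            raise ValueError(
                f"condition must be one of {sorted(DEFAULT_BOUNDARIES)} when no "
                f"boundary_override is given, got {condition!r}"
            )
        boundary = DEFAULT_BOUNDARIES[condition]

    try:
        pv = find_peak_valley(phage_curve, boundary)
    except CoverageError as exc:
        raise CoverageError(f"phage-treated curve: {exc}") from exc
    try:
        fit = fit_logistic(buffer_curve)
    except Exception as exc:
        raise type(exc)(f"buffer-treated curve: {exc}") from exc

    n_tp = logistic_value(fit, pv.t_p)
    n_tv = logistic_value(fit, pv.t_v)
    frag = percent_lysogens(pv.od_p, pv.od_v, n_tp, n_tv)
    return LysogenyEstimate(
        percent_lysogens_raw=frag.percent_lysogens_raw,
        percent_lysogens=frag.percent_lysogens,
        expansion_factor=frag.expansion_factor,
        branch=frag.branch,
        peakvalley=pv,
        n_tp=float(n_tp),
        n_tv=float(n_tv),
        fit=fit,
        well_id=phage_curve.well_id,
    )


def aggregate_replicates(
    estimates: Sequence[LysogenyEstimate] | Iterable[LysogenyEstimate],
) -> ReplicateSummary:
    """Arithmetic mean and sample SD of clamped %L across replicates.

    A single estimate has no sample SD; it is reported as 0 with
    ``sd_defined=False``.
    """
    values = [e.percent_lysogens for e in estimates]
    if not values:
        raise ValueError("need at least one estimate to aggregate")
    if len(values) == 1:
        return ReplicateSummary(values[0], 0.0, 1, sd_defined=False)
    return ReplicateSummary(mean(values), stdev(values), len(values), sd_defined=True)
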