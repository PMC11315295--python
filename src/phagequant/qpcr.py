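"""qPCR absolute quantitation and derived infection metrics.

A dilution series of plasmid DNA carrying the target (e.g. *gp69*) defines a
standard curve, the OLS line Cq = slope * log10(copies) + intercept with
slope < 0 and amplification efficiency 10^(-1/slope) - 1 (1.0 means perfect
doubling per cycle). Unknowns convert back through the inverse,
copies = 10^((Cq - intercept)/slope). Efficiency is reported but never used
to correct copy numbers (single-curve absolute quantitation).

Derived metrics:

- lysogen quantitation: the prophage is multi-copy, so *cos* counts are put
  on a per-cell basis with the host single-copy gene *ompW* and normalized
  to the cos-per-cell of a stable lysogen grown under the same conditions;
- percent adsorbed: 100 * (1 - free/control), phage particles removed from
  the medium by the cells;
- fold particle production: free-particle copies at 24 h over 0 h.

Below-LOD (censored) measurements never turn into silent numbers: they
propagate as flagged bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import FitError
from .io import QpcrRecord

__all__ = [
    "QpcrStandardCurve",
    "LysogenQpcrResult",
    "AdsorptionResult",
    "CopyBound",
    "FoldChange",
    "fit_standard_curve",
    "cq_to_copies",
    "copies_to_cq",
    "combine_technical_reps",
    "percent_lysogens_qpcr",
    "percent_adsorbed",
    "fold_particle_production",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QpcrStandardCurve:
    """OLS standard curve of Cq against log10(template copies)."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int

    def __post_init__(self):
        if not (self.slope < 0):
            raise FitError(
                f"standard-curve slope must be negative (got {self.slope}); "
                "Cq decreases with template amount"
            )
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise FitError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.n_points < 3:
            raise FitError("standard curve needs >= 3 points")


@dataclass(frozen=True)
class LysogenQpcrResult:
    """cos-per-cell normalized lysogen quantitation."""

    cos_per_cell: float
    reference_cos_per_cell: float
    percent_lysogens_qpcr: float


@dataclass(frozen=True)
class AdsorptionResult:
    """Percent of phage particles removed from the medium by cells."""

    percent: float
    over_recovery: bool = False


@dataclass(frozen=True)
class CopyBound:
    """LOD-equivalent copy number for a censored-below measurement."""

    value: float
    censored_below: bool = True


@dataclass(frozen=True)
class FoldChange:
    """Fold change in free particles; a lower bound when t0 was below LOD."""

    value: float
    lower_bound: bool = False


def fit_standard_curve(
    dilution_series: Iterable[tuple[float, float]]
) -> QpcrStandardCurve:
    """Fit Cq ~ log10(copies) by OLS over a standard dilution series.

    ``dilution_series`` is an iterable of (known copies, Cq) pairs with at
    least 3 distinct positive copy numbers.
    """
    pairs = [(float(c), float(q)) for c, q in dilution_series]
    if any(c <= 0 for c, _ in pairs):
        raise FitError("standard-curve copy numbers must all be positive")
    distinct = {c for c, _ in pairs}
    if len(distinct) < 3:
        raise FitError(
            f"standard curve needs >= 3 distinct copy levels, got {len(distinct)}"
        )
    x = np.log10([c for c, _ in pairs])
    y = np.array([q for _, q in pairs])
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope >= 0:
        raise FitError(f"fitted slope {slope:g} is nonnegative; not a valid series")
    return QpcrStandardCurve(
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rvalue**2),
        efficiency=float(10.0 ** (-1.0 / slope) - 1.0),
        n_points=len(pairs),
    )


def cq_to_copies(
    curve: QpcrStandardCurve, cq: float | None, *, censored: bool = False,
    lod_cq: float | None = None,
) -> float | CopyBound:
    """Convert a Cq value to template copies through the standard curve.

    For a censored measurement (``censored=True`` with a ``lod_cq``), the
    LOD-equivalent copy number is returned wrapped in a flagged bound.
    """
    if censored:
        if lod_cq is None:
            raise ValueError("censored conversion requires lod_cq")
        return CopyBound(
            value=float(10.0 ** ((lod_cq - curve.intercept) / curve.slope)),
        )
    if cq is None:
        raise ValueError("cq is None but censored flag not set")
    return float(10.0 ** ((float(cq) - curve.intercept) / curve.slope))


def copies_to_cq(curve: QpcrStandardCurve, copies: float) -> float:
    """Inverse of :func:`cq_to_copies` for positive copy numbers."""
    if copies <= 0:
        raise ValueError("copies must be positive")
    return float(curve.intercept + curve.slope * np.log10(copies))


def combine_technical_reps(records: Sequence[QpcrRecord]) -> dict:
    """Mean Cq per (sample_id, target) across technical replicates.

    Cq is the measured scale, so replicates are averaged in Cq space.
    Censored replicates are dropped when at least one replicate measured
    (with a log message); a group that is censored throughout stays
    censored (cq None).
    """
    groups: dict[tuple[str, str], list[QpcrRecord]] = {}
    for rec in records:
        groups.setdefault((rec.sample_id, rec.target), []).append(rec)
    out = {}
    for key, recs in groups.items():
        measured = [r.cq for r in recs if not r.censored]
        if measured:
            n_drop = len(recs) - len(measured)
            if n_drop:
                logger.info(
                    "sample %r target %r: dropped %d censored technical rep(s)",
                    key[0], key[1], n_drop,
                )
            out[key] = {"cq": float(np.mean(measured)), "censored": False,
                        "n_reps": len(measured)}
        else:
            out[key] = {"cq": None, "censored": True, "n_reps": len(recs)}
    return out


def percent_lysogens_qpcr(
    sample_cos: float,
    sample_ompw: float,
    ref_cos: float,
    ref_ompw: float,
) -> LysogenQpcrResult:
    """Percent lysogens from cos/ompW copies normalized to a stable lysogen.

    ``cos_per_cell = sample_cos / sample_ompw`` and likewise for the stable
    lysogen reference; the percent is 100 x the ratio of ratios, clamped to
    [0, 100]. Rescaling both sample targets by a common factor (different
    DNA extraction amounts) leaves the result unchanged.
    """
    if sample_ompw <= 0 or ref_ompw <= 0:
        raise ValueError("ompW copies must be positive (no cells detected)")
    if ref_cos <= 0:
        raise ValueError("reference cos copies must be positive")
    if sample_cos < 0:
        raise ValueError("sample cos copies must be >= 0")
    cos_per_cell = sample_cos / sample_ompw
    ref_per_cell = ref_cos / ref_ompw
    percent = 100.0 * cos_per_cell / ref_per_cell
    return LysogenQpcrResult(
        cos_per_cell=float(cos_per_cell),
        reference_cos_per_cell=float(ref_per_cell),
        percent_lysogens_qpcr=float(min(max(percent, 0.0), 100.0)),
    )


def percent_adsorbed(sample_free: float, control_free: float) -> AdsorptionResult:
    """Percent of particles adsorbed: 100 * (1 - free/control), in [0, 100].

    ``sample_free`` above the cell-free control means over-recovery; the
    value clamps to 0 and the result is flagged.
    """
    if control_free <= 0:
        raise ValueError("control_free must be positive")
    if sample_free < 0:
        raise ValueError("sample_free must be >= 0")
    raw = 100.0 * (1.0 - sample_free / control_free)
    over = sample_free > control_free
    return AdsorptionResult(percent=float(min(max(raw, 0.0), 100.0)),
                            over_recovery=bool(over))


def fold_particle_production(
    t0_copies: float,
    t24_copies: float,
    *,
    t0_censored: bool = False,
    lod_copies: float | None = None,
) -> FoldChange:
    """Fold change in free viral particles between 0 h and 24 h of infection.

    When the 0 h measurement was below the LOD, the LOD-equivalent copy
    number serves as denominator and the result is a flagged lower bound.
    """
    if t24_copies < 0:
        raise ValueError("t24_copies must be >= 0")
    if t0_censored:
        if lod_copies is None or lod_copies <= 0:
            raise ValueError("censored t0 requires a positive lod_copies")
        return FoldChange(value=float(t24_copies / lod_copies), lower_bound=True)
    if t0_copies <= 0:
        raise ValueError("t0_copies must be positive (or censored with an LOD)")
    return FoldChange(value=float(t24_copies / t0_copies), lower_bound=False)
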