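"""Calibration of the estimators against known mixtures, and reporter ratios.

The estimators are validated with known-mixture standard curves: cultures
assembled from a stable lysogen and naive cells at known ratios are run
through the quantitation, and the calculated percent lysogens is regressed
(OLS, estimated on known) against the known percent. A slope near 1 with
high R-squared certifies the estimator. Only induced (+arabinose) samples
belong in the fit; uninduced (+dextrose) samples show no lysis and carry no
calibration information.

Reporter arithmetic lives here too: relative light/fluorescence units are a
raw signal divided by a normalizer (OD600 or a constitutive fluorophore),
and percent-of-reference comparisons are unclamped (a sample can exceed its
reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, FormatError

__all__ = [
    "CalibrationResult",
    "calibration_regression",
    "normalized_signal",
    "percent_of_reference",
    "load_supplementary_pairs",
]


@dataclass(frozen=True)
class CalibrationResult:
    """OLS fit of estimated %lysogens on known %lysogens."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residuals: tuple

    def __post_init__(self):
        if self.n < 3:
            raise FitError("calibration needs >= 3 points")


def calibration_regression(
    known_percent: Sequence[float], estimated_percent: Sequence[float]
) -> CalibrationResult:
    """Regress estimated percent lysogens on the known mixture percent."""
    x = np.asarray(known_percent, dtype=float)
    y = np.asarray(estimated_percent, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("known and estimated vectors must be 1-D and equal length")
    if len(x) < 3:
        raise FitError(f"calibration needs >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise FitError("known percent values are degenerate (no variance)")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    return CalibrationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
        residuals=tuple(float(v) for v in (y - fitted)),
    )


def normalized_signal(numerator: float, denominator: float) -> float:
    """Reporter ratio: bioluminescence/OD600 (RLU) or RFP/constitutive (RFU)."""
    if not (denominator > 0):
        raise ValueError(f"denominator must be positive, got {denominator}")
    return float(numerator) / float(denominator)


def percent_of_reference(sample: float, reference: float) -> float:
    """Sample ratio as a percent of a reference ratio; deliberately unclamped."""
    if not (reference > 0):
        raise ValueError(f"reference must be positive, got {reference}")
    return 100.0 * float(sample) / float(reference)


def load_supplementary_pairs(
    path: str | Path,
    *,
    sheet: str | int = 0,
    known_col: str = "known_percent",
    estimated_col: str = "estimated_percent",
) -> pd.DataFrame:
    """Load (known %, estimated %) point pairs from a CSV or XLSX file.

    Intended for ingesting published supplementary data that tabulates
    known-mixture calibration points; returns a DataFrame with columns
    ``known_percent`` and ``estimated_percent`` ready for
    :func:`calibration_regression`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"supplementary data file not found: {path}")
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    for col in (known_col, estimated_col):
        if col not in df.columns:
            raise FormatError(f"supplementary table: missing column {col!r}")
    return pd.DataFrame(
        {
            "known_percent": df[known_col].astype(float),
            "estimated_percent": df[estimated_col].astype(float),
        }
    )
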