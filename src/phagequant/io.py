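"""Plate-reader and qPCR table input/output.

Growth curves come from plate readers as either *long* tables
(``well,time_h,od600`` plus optional metadata columns) or *wide* tables
(``time_h`` plus one OD column per well, metadata in a sidecar table keyed by
well). qPCR results come as ``sample_id,target,cq,technical_rep`` tables where
a configurable sentinel token marks reactions below the limit of detection.
Both CSV and XLSX files are accepted (XLSX for supplementary-data ingestion).

Times are stored in hours. Readers accept ``time_unit`` in ``{"h", "min"}``
and convert; the default is hours. Missing OD values are dropped per well
with a logged count rather than imputed, because the downstream lysogeny
estimator works on curve extrema that imputation would bias. OD readings are
not blank-corrected by default; pass ``blank`` to subtract a constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "GrowthCurve",
    "QpcrRecord",
    "KNOWN_TARGETS",
    "read_growth_table",
    "write_growth_table",
    "read_qpcr_table",
]

logger = logging.getLogger(__name__)

TREATMENTS = ("phage", "buffer")
INDUCERS = ("arabinose", "dextrose")
CONDITIONS = ("planktonic", "surface")

#: qPCR targets used in the assay: gp69 counts phage genomes, cos
#: distinguishes the prophage from packaged genomes, IRS marks the circular
#: replicative form (control channel only), ompW counts host genomes.
KNOWN_TARGETS = ("gp69", "cos", "IRS", "ompW")

_META_DEFAULTS = {
    "strain": "unknown",
    "treatment": "phage",
    "inducer": "arabinose",
    "condition": "planktonic",
    "replicate": 1,
}


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series plus its treatment metadata.

    Times are hours on the plate-run clock (t=0 is the first recorded
    timepoint, post-dilution). Invariants: strictly increasing times, at
    least 4 points, nonnegative ODs, equal-length arrays.
    """

    well_id: str
    times: np.ndarray
    od600: np.ndarray
    treatment: str = "phage"
    inducer: str = "arabinose"
    condition: str = "planktonic"
    strain: str = "unknown"
    replicate: int = 1

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od600", od)
        if times.ndim != 1 or od.ndim != 1 or len(times) != len(od):
            raise DataError(
                f"well {self.well_id!r}: times and od600 must be 1-D arrays "
                f"of equal length (got {len(times)} and {len(od)})"
            )
        if len(times) < 4:
            raise DataError(
                f"well {self.well_id!r}: need at least 4 timepoints, got {len(times)}"
            )
        if not np.all(np.diff(times) > 0):
            raise DataError(f"well {self.well_id!r}: times must be strictly increasing")
        if np.any(od < 0) or np.any(~np.isfinite(od)):
            t_bad = times[(od < 0) | ~np.isfinite(od)][0]
            raise DataError(
                f"well {self.well_id!r}: invalid OD600 at time {t_bad:g} h "
                "(must be finite and >= 0)"
            )
        if self.treatment not in TREATMENTS:
            raise DataError(
                f"well {self.well_id!r}: treatment must be one of {TREATMENTS}"
            )
        if self.inducer not in INDUCERS:
            raise DataError(f"well {self.well_id!r}: inducer must be one of {INDUCERS}")
        if self.condition not in CONDITIONS:
            raise DataError(
                f"well {self.well_id!r}: condition must be one of {CONDITIONS}"
            )
        if int(self.replicate) < 1:
            raise DataError(f"well {self.well_id!r}: replicate must be >= 1")
        object.__setattr__(self, "replicate", int(self.replicate))

    def with_metadata(self, **kwargs) -> "GrowthCurve":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR reaction: a Cq value or a censored (below-LOD) observation."""

    sample_id: str
    target: str
    cq: float | None
    technical_rep: int = 1
    censored: bool = False

    def __post_init__(self):
        if not self.censored:
            if self.cq is None or not np.isfinite(self.cq) or self.cq <= 0:
                raise DataError(
                    f"sample {self.sample_id!r} target {self.target!r}: "
                    f"cq must be positive when not censored (got {self.cq})"
                )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def _time_column(df: pd.DataFrame, time_unit: str | None) -> tuple[str, float]:
    """Locate the time column and return (name, factor-to-hours)."""
    for name in ("time_h", "time_min", "time"):
        if name in df.columns:
            if time_unit is None:
                time_unit = "min" if name == "time_min" else "h"
            break
    else:
        raise FormatError("growth table: missing required column(s) ['time_h']")
    if time_unit not in {"h", "min"}:
        raise FormatError(f"time_unit must be 'h' or 'min', got {time_unit!r}")
    return name, (1.0 / 60.0 if time_unit == "min" else 1.0)


def _metadata_for(well: str, meta: pd.DataFrame | None) -> dict:
    out = dict(_META_DEFAULTS)
    if meta is not None:
        rows = meta[meta["well"] == well]
        if len(rows) > 1:
            raise DataError(f"metadata: multiple rows for well {well!r}")
        if len(rows) == 1:
            row = rows.iloc[0]
            for key in _META_DEFAULTS:
                if key in meta.columns and not pd.isna(row[key]):
                    out[key] = row[key]
    return out


def _build_curve(well: str, sub: pd.DataFrame, meta: dict, blank: float) -> GrowthCurve:
    sub = sub.sort_values("_time_h", kind="stable")
    dup = sub["_time_h"].duplicated()
    if dup.any():
        t = sub.loc[dup, "_time_h"].iloc[0]
        raise DataError(f"well {well!r}: duplicate timepoint at {t:g} h")
    n_missing = int(sub["_od"].isna().sum())
    if n_missing:
        logger.info("well %r: dropped %d missing OD value(s)", well, n_missing)
        sub = sub.dropna(subset=["_od"])
    od = sub["_od"].to_numpy(dtype=float)
    if np.any(od < 0):
        t_bad = sub["_time_h"].to_numpy(dtype=float)[od < 0][0]
        raise DataError(f"well {well!r}: negative OD600 at time {t_bad:g} h")
    od = np.maximum(od - blank, 0.0) if blank else od
    return GrowthCurve(
        well_id=str(well), times=sub["_time_h"].to_numpy(dtype=float), od600=od, **meta
    )


def read_growth_table(
    path: str | Path,
    layout: str = "long",
    metadata: str | Path | pd.DataFrame | None = None,
    *,
    time_unit: str | None = None,
    blank: float = 0.0,
) -> list[GrowthCurve]:
    """Read a plate-reader table into a list of :class:`GrowthCurve`.

    Parameters
    ----------
    path:
        CSV or XLSX file. Long layout needs columns ``well,time_h,od600``
        (metadata columns ``strain,treatment,inducer,condition,replicate``
        are picked up inline when present); wide layout needs ``time_h``
        plus one numeric column per well.
    layout:
        ``"long"`` or ``"wide"``.
    metadata:
        Sidecar table (path or DataFrame) keyed by ``well``; required fields
        absent from it fall back to defaults (phage/arabinose/planktonic).
    time_unit:
        ``"h"`` or ``"min"``; inferred from the column name when omitted.
    blank:
        Constant blank OD subtracted from every reading (clipped at 0).
    """
    df = _read_table(path)
    meta_df = None
    if metadata is not None:
        meta_df = (
            metadata if isinstance(metadata, pd.DataFrame) else _read_table(metadata)
        )
        _require_columns(meta_df, ["well"], "metadata table")
        meta_df = meta_df.assign(well=meta_df["well"].astype(str))

    if layout == "long":
        _require_columns(df, ["well", "od600"], "growth table (long)")
        tcol, factor = _time_column(df, time_unit)
        df = df.assign(_time_h=df[tcol].astype(float) * factor, _od=df["od600"])
        curves = []
        for well, sub in df.groupby("well", sort=True):
            meta = _metadata_for(str(well), meta_df)
            # inline metadata columns override the defaults, sidecar wins last
            for key in _META_DEFAULTS:
                if key in sub.columns:
                    vals = sub[key].dropna().unique()
                    if len(vals) > 1:
                        raise DataError(
                            f"well {well!r}: conflicting values for {key!r}: {vals}"
                        )
                    if len(vals) == 1 and (
                        meta_df is None or key not in meta_df.columns
                    ):
                        meta[key] = vals[0]
            curves.append(_build_curve(str(well), sub, meta, blank))
        return curves

    if layout == "wide":
        tcol, factor = _time_column(df, time_unit)
        well_cols = [c for c in df.columns if c != tcol]
        if not well_cols:
            raise FormatError("growth table (wide): no well columns found")
        curves = []
        for well in well_cols:
            sub = pd.DataFrame(
                {"_time_h": df[tcol].astype(float) * factor, "_od": df[well]}
            )
            meta = _metadata_for(str(well), meta_df)
            curves.append(_build_curve(str(well), sub, meta, blank))
        return curves

    raise FormatError(f"unknown layout {layout!r}; expected 'long' or 'wide'")


def write_growth_table(
    curves: Sequence[GrowthCurve], path: str | Path, layout: str = "long"
) -> None:
    """Write curves to CSV at full float precision (round-trip safe)."""
    if layout != "long":
        raise FormatError("only the long layout is written")
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od600):
            rows.append(
                {
                    "well": c.well_id,
                    "time_h": repr(float(t)),
                    "od600": repr(float(od)),
                    "strain": c.strain,
                    "treatment": c.treatment,
                    "inducer": c.inducer,
                    "condition": c.condition,
                    "replicate": c.replicate,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_qpcr_table(
    path: str | Path,
    *,
    lod_token: str = "ND",
    strict: bool = True,
) -> list[QpcrRecord]:
    """Read a qPCR Cq table into records, flagging below-LOD reactions.

    A ``cq`` cell equal to ``lod_token`` (case-insensitive) or empty is read
    as a censored observation. In strict mode targets outside
    :data:`KNOWN_TARGETS` raise :class:`FormatError`.
    """
    df = _read_table(path)
    if df.empty:
        logger.warning("qPCR table %s is empty", path)
        return []
    _require_columns(df, ["sample_id", "target", "cq"], "qPCR table")
    records = []
    for _, row in df.iterrows():
        target = str(row["target"])
        if strict and target not in KNOWN_TARGETS:
            raise FormatError(
                f"unknown qPCR target {target!r}; known targets are {KNOWN_TARGETS} "
                "(pass strict=False to accept)"
            )
        raw = row["cq"]
        censored = (
            pd.isna(raw) or str(raw).strip().lower() == lod_token.strip().lower()
        )
        cq = None if censored else float(raw)
        rep = int(row["technical_rep"]) if "technical_rep" in df.columns else 1
        records.append(
            QpcrRecord(
                sample_id=str(row["sample_id"]),
                target=target,
                cq=cq,
                technical_rep=rep,
                censored=censored,
            )
        )
    return records
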