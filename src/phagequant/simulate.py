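"""Synthetic growth-curve and qPCR data for mixed lysogen/naive populations.

The generator emulates the Q-induction assay: a culture that is a mixture
of lysogens (true fraction ``f``) and naive cells grows logistically toward
a shared carrying capacity; at ``induction_time`` the lytic regulator is
induced, and after ``lysis_lag`` the lysing portion of the biomass
(``f * lysis_efficiency`` of the culture) decays exponentially at
``lysis_rate`` while the survivors keep growing logistically (optionally
faster by ``regrowth_boost``, modelling growth on nutrients released by
lysis). The measured OD is the biomass sum, multiplied by lognormal noise.

Three wells are produced per run: the induced mixture (the "phage-treated,
+arabinose" analog whose peak/valley the estimator reads), the uninduced
mixture (+dextrose control: no lysis), and the buffer-treated control (pure
logistic, used for the expansion-factor fit).

All randomness flows from the explicit ``seed``; identical configs give
bitwise-identical curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GrowthCurve, QpcrRecord
from .lysogeny import LysogenyEstimate, quantify_lysogeny
from .qpcr import QpcrStandardCurve

__all__ = [
    "SimulationConfig",
    "simulate_mixture",
    "simulate_standard_curve_experiment",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters for one simulated Q-induction run.

    Defaults mirror the assay conditions: cultures diluted 1:100 (start
    around OD 0.05) growing to carrying capacity 1.0 at 0.8/h, induced at
    mid-log (3 h, OD ~0.37), lysis starting after a 1 h regulatory lag —
    i.e. at the 4 h planktonic peak/valley boundary, so pre-lysis peaks
    fall at or before the boundary and post-lysis valleys after it — and
    clearing at 2.5/h, OD read every 5 min for 12 h, 1% multiplicative
    measurement noise. Q-induction is assumed to lyse every lysogen
    (``lysis_efficiency = 1``); survivors regrow at the shared rate
    (``regrowth_boost = 1``).
    """

    lysogen_fraction: float = 0.5
    n0_total: float = 0.05
    k: float = 1.0
    r: float = 0.8
    induction_time: float = 3.0
    lysis_lag: float = 1.0
    lysis_rate: float = 2.5
    lysis_efficiency: float = 1.0
    regrowth_boost: float = 1.0
    noise_sd: float = 0.01
    sampling_interval: float = 1.0 / 12.0
    duration: float = 12.0
    seed: int = 0
    condition: str = "planktonic"
    strain: str = "sim"

    def __post_init__(self):
        if not (0.0 <= self.lysogen_fraction <= 1.0):
            raise ValueError("lysogen_fraction must be in [0, 1]")
        if not (0.0 <= self.lysis_efficiency <= 1.0):
            raise ValueError("lysis_efficiency must be in [0, 1]")
        for name in ("n0_total", "k", "r", "lysis_rate", "sampling_interval"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        for name in ("induction_time", "lysis_lag", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.regrowth_boost < 1.0:
            raise ValueError("regrowth_boost must be >= 1")
        if self.duration <= self.induction_time:
            raise ValueError("duration must exceed induction_time")
        if self.k < self.n0_total:
            raise ValueError("k must be >= n0_total")


def _logistic(t, n0, k, r):
    return k / (1.0 + ((k - n0) / n0) * np.exp(-r * t))


def simulate_mixture(config: SimulationConfig) -> Mapping[str, GrowthCurve]:
    """Simulate one Q-induction run.

    Returns a dict with keys ``induced_phagelike``, ``uninduced`` and
    ``buffer_control``. At zero noise the induced OD never exceeds the
    uninduced OD (lysis only removes biomass, given
    ``lysis_rate >= r * regrowth_boost``), and with ``lysogen_fraction = 0``
    the induced and uninduced curves are identical.
    """
    c = config
    n_steps = int(np.floor(c.duration / c.sampling_interval)) + 1
    times = np.arange(n_steps) * c.sampling_interval

    mixture = _logistic(times, c.n0_total, c.k, c.r)
    buffer_biomass = mixture.copy()
    uninduced_biomass = mixture.copy()

    induced_biomass = mixture.copy()
    t_lyse = c.induction_time + c.lysis_lag
    lysing_frac = c.lysogen_fraction * c.lysis_efficiency
    if lysing_frac > 0:
        after = times >= t_lyse
        n_at_lysis = float(_logistic(t_lyse, c.n0_total, c.k, c.r))
        l0 = lysing_frac * n_at_lysis
        s0 = n_at_lysis - l0
        dt = times[after] - t_lyse
        lysing = l0 * np.exp(-c.lysis_rate * dt)
        if s0 > 0:
            survivors = _logistic(dt, s0, c.k, c.r * c.regrowth_boost)
        else:  # fully lysogenized culture: nothing survives induction
            survivors = np.zeros_like(dt)
        induced_biomass[after] = survivors + lysing

    rng = np.random.default_rng(c.seed)

    def measure(biomass: np.ndarray) -> np.ndarray:
        if c.noise_sd == 0:
            return biomass.copy()
        return biomass * np.exp(rng.normal(0.0, c.noise_sd, size=biomass.shape))

    common = dict(condition=c.condition, strain=c.strain, replicate=1)
    # fixed draw order keeps curves reproducible well by well
    buffer_curve = GrowthCurve(
        "buffer", times, measure(buffer_biomass),
        treatment="buffer", inducer="arabinose", **common,
    )
    uninduced_curve = GrowthCurve(
        "uninduced", times, measure(uninduced_biomass),
        treatment="phage", inducer="dextrose", **common,
    )
    induced_curve = GrowthCurve(
        "induced", times, measure(induced_biomass),
        treatment="phage", inducer="arabinose", **common,
    )
    return {
        "induced_phagelike": induced_curve,
        "uninduced": uninduced_curve,
        "buffer_control": buffer_curve,
    }


def _subseed(base_seed: int, index: int) -> int:
    # deterministic per-fraction stream, kept below 2**31
    return int((base_seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1))


def simulate_standard_curve_experiment(
    fractions: Sequence[float],
    base_config: SimulationConfig,
) -> pd.DataFrame:
    """Known-mixture experiment: simulate each fraction, then estimate it.

    For each true lysogen fraction a mixture run is simulated and the
    induced curve is quantified against the buffer control. Returns a
    DataFrame with columns ``known_percent``, ``estimated_percent``,
    ``estimated_raw_percent``, ``branch`` and ``expansion_factor``, ready
    for :func:`phagequant.validation.calibration_regression`.
    """
    fractions = list(fractions)
    if len(fractions) == 0:
        raise ValueError("need at least one lysogen fraction")
    rows = []
    for i, f in enumerate(fractions):
        cfg = replace(
            base_config,
            lysogen_fraction=float(f),
            seed=_subseed(base_config.seed, i),
        )
        curves = simulate_mixture(cfg)
        est: LysogenyEstimate = quantify_lysogeny(
            curves["induced_phagelike"], curves["buffer_control"], cfg.condition
        )
        rows.append(
            {
                "known_percent": 100.0 * float(f),
                "estimated_percent": est.percent_lysogens,
                "estimated_raw_percent": est.percent_lysogens_raw,
                "branch": est.branch,
                "expansion_factor": est.expansion_factor,
            }
        )
    return pd.DataFrame(rows)


def simulate_qpcr(
    true_copies: float,
    curve: QpcrStandardCurve,
    cq_noise_sd: float,
    seed: int,
    *,
    sample_id: str = "sim",
    target: str = "gp69",
    lod_cq: float | None = None,
) -> QpcrRecord:
    """Generate one qPCR record from a true copy number and a standard curve.

    Cq = intercept + slope * log10(copies) + N(0, cq_noise_sd); the record
    is censored when the Cq lands above ``lod_cq``.
    """
    if true_copies <= 0:
        raise ValueError("true_copies must be positive")
    rng = np.random.default_rng(seed)
    cq = curve.intercept + curve.slope * np.log10(true_copies)
    if cq_noise_sd > 0:
        cq += rng.normal(0.0, cq_noise_sd)
    if lod_cq is not None and cq > lod_cq:
        return QpcrRecord(sample_id=sample_id, target=target, cq=None, censored=True)
    return QpcrRecord(sample_id=sample_id, target=target, cq=float(cq))
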