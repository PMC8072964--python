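"""Instrument-side computations.

Covers the arithmetic between a detected extract level and a per-cigarette
content, calibration-curve fitting with the linearity gate, signal-to-noise
detection limits, spike recovery, relative standard deviation, and the
mg/kg ↔ percent conversion used for regulatory limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .core import (
    Compound,
    CompoundTable,
    ContentRecord,
    Matrix,
    PartQuantRecord,
    Status,
)

#: calibration acceptance gate on the coefficient of determination
R_SQUARED_GATE = 0.999
#: precision acceptance gate on the relative standard deviation (percent)
RSD_GATE_PCT = 10.0
#: regulatory limit for leave-on / oral products, in percent
LEAVE_ON_LIMIT_PCT = 0.0002


def concentration_from_level(
    level_ng_per_ml: float,
    volume_ml: float,
    weight_g: float,
    dilution_factor: float = 1.0,
) -> float:
    """Concentration (ng/g) of the sampled matrix from an extract level.

    The detected level refers to the injected (possibly diluted) extract,
    so the dilution factor scales it back to the undiluted extract:
    ``level × dilution × volume / weight``.
    """
    if volume_ml <= 0 or weight_g <= 0:
        raise ValueError("volume and weight must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be ≥ 1")
    if level_ng_per_ml < 0:
        raise ValueError("detected level must be non-negative")
    return level_ng_per_ml * dilution_factor * volume_ml / weight_g


def content_from_concentration(
    concentration_ng_per_g: float, weight_g: float
) -> float:
    """Content (µg/cigarette part) from a matrix concentration (ng/g)."""
    if weight_g <= 0:
        raise ValueError("weight must be positive")
    if concentration_ng_per_g < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_ng_per_g * weight_g / 1000.0


def quantify(
    records: Iterable[PartQuantRecord], compounds: CompoundTable
) -> list[ContentRecord]:
    """Convert instrument records to per-part content records (µg).

    Quantified levels go through the concentration and content equations;
    censored records (below LOQ or not detected) get a content of 0 here —
    censoring substitution is a separate, explicit step in the exposure
    stage.
    """
    out = []
    for r in records:
        compound = compounds[r.compound]
        r.validate_against(compound)
        if r.status is Status.QUANTIFIED:
            conc = concentration_from_level(
                r.detected_level_ng_per_ml,
                r.extract_volume_ml,
                r.sample_weight_g,
                r.dilution_factor,
            )
            content = content_from_concentration(conc, r.sample_weight_g)
        else:
            conc = 0.0
            content = 0.0
        out.append(
            ContentRecord(
                cigarette_id=r.cigarette_id,
                has_capsule=r.has_capsule,
                part=r.part,
                compound=r.compound,
                concentration_ng_per_g=conc,
                content_ug_per_cigarette=content,
                status=r.status,
                capsule_index=r.capsule_index,
                extract_volume_ml=r.extract_volume_ml,
            )
        )
    return out


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordinary-least-squares calibration line for one compound."""

    compound: str
    levels_ng_per_ml: tuple[float, ...]
    responses: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float

    @property
    def passes_linearity(self) -> bool:
        return self.r_squared > R_SQUARED_GATE


def fit_calibration(
    levels: Sequence[float],
    responses: Sequence[float],
    compound: str = "",
) -> CalibrationCurve:
    """Fit an unweighted linear calibration curve by OLS.

    Requires at least three distinct levels; a flat response is rejected
    as a degenerate fit.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and responses must be 1-D and equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    if np.any(x <= 0):
        raise ValueError("calibration levels must be positive")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate fit: responses are constant")
    res = _sps.linregress(x, y)
    return CalibrationCurve(
        compound=compound,
        levels_ng_per_ml=tuple(float(v) for v in x),
        responses=tuple(float(v) for v in y),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def lod_loq_from_noise(
    noise_level: float, slope: float
) -> tuple[float, float]:
    """(LOD, LOQ) in ng/mL from baseline noise and calibration slope.

    LOD and LOQ are the levels producing a signal-to-noise ratio of 3 and
    10 respectively, so LOQ/LOD is 10/3 by construction.
    """
    if noise_level <= 0 or slope <= 0:
        raise ValueError("noise level and slope must be positive")
    lod = 3.0 * noise_level / slope
    loq = 10.0 * noise_level / slope
    return lod, loq


def recovery_pct(measured: float, spiked: float) -> float:
    """Spike recovery in percent: 100 × measured / spiked."""
    if spiked <= 0:
        raise ValueError("spiked concentration must be positive")
    return 100.0 * measured / spiked


def rsd_pct(values: Sequence[float]) -> float:
    """Relative standard deviation in percent (sample SD / mean × 100)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least two replicates")
    mean = v.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * v.std(ddof=1) / abs(mean)


def mg_per_kg_to_pct(conc_mg_per_kg: float) -> float:
    """Convert a mass fraction from mg/kg to percent (1 mg/kg = 0.0001%)."""
    if conc_mg_per_kg < 0:
        raise ValueError("concentration must be non-negative")
    return conc_mg_per_kg / 10_000.0


def exceeds_leave_on_limit(pct: float) -> bool:
    """Whether a mass fraction (percent) exceeds the 0.0002% leave-on limit."""
    return pct > LEAVE_ON_LIMIT_PCT


@dataclass(frozen=True)
class ValidationResult:
    """Method-validation summary for one compound in one matrix."""

    compound: str
    matrix: Matrix
    lod_ng_per_ml: float
    loq_ng_per_ml: float
    recovery_pct_by_level: dict[float, float] = field(default_factory=dict)
    rsd_pct_by_level: dict[float, float] = field(default_factory=dict)

    def __post_init__(self):
        if not math.isclose(
            self.loq_ng_per_ml, self.lod_ng_per_ml * 10.0 / 3.0,
            rel_tol=1e-12,
        ):
            raise ValueError("LOQ must equal (10/3) × LOD under the S/N definition")
        for lvl, rec in self.recovery_pct_by_level.items():
            if not 0 < rec < 200:
                raise ValueError(f"recovery {rec}% at {lvl} out of (0, 200)")
        for lvl, rsd in self.rsd_pct_by_level.items():
            if rsd < 0:
                raise ValueError("RSD cannot be negative")

    @property
    def passes_precision(self) -> bool:
        return all(r < RSD_GATE_PCT for r in self.rsd_pct_by_level.values())


def validate_method(
    spike_frame,
    noise_level: float,
    slope: float,
    matrix: Matrix,
) -> list[ValidationResult]:
    """Aggregate a spiked-replicate table into per-compound validation rows.

    ``spike_frame`` must carry columns ``compound``, ``spike_ug_per_g`` and
    ``measured_ug_per_g`` (triplicates per spike level as in a standard
    fortification experiment). The S/N-based LOD/LOQ are computed from the
    supplied blank-baseline noise and calibration slope.
    """
    lod, loq = lod_loq_from_noise(noise_level, slope)
    results = []
    for compound, grp in spike_frame.groupby("compound", sort=False):
        rec, rsd = {}, {}
        for spike, reps in grp.groupby("spike_ug_per_g"):
            measured = reps["measured_ug_per_g"].to_numpy()
            rec[float(spike)] = recovery_pct(float(measured.mean()), float(spike))
            rsd[float(spike)] = rsd_pct(measured)
        results.append(
            ValidationResult(
                compound=str(compound),
                matrix=Matrix(matrix),
                lod_ng_per_ml=lod,
                loq_ng_per_ml=loq,
                recovery_pct_by_level=rec,
                rsd_pct_by_level=rsd,
            )
        )
    return results
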