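"""Censoring substitution, per-cigarette totals, inhalation exposure and RCR.

The exposure model assumes the entire flavor load of a cigarette transfers
to the smoker (no pyrolysis, mouth-spill or filter-retention corrections):

    EC (mg/m³) = C × N × ED × EF / (IR × AT) / 1000

with C the per-cigarette content in µg, N the cigarettes smoked per day,
ED the exposure duration in years, EF the exposure frequency in days/year,
IR the daily inhalation rate in m³/day and AT the averaging time in days
(ED × 365). With AT in days the ED·EF/AT factor is exactly 1 under the
default parameters, so EC reduces to C × N / IR µg/m³.

Risk is characterized as RCR = EC / DNEL; RCR > 1 means the exposure
exceeds the derived no-effect level and RCR > 0.1 is flagged as warranting
attention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Optional

from pydantic import BaseModel, model_validator

from .core import CompoundTable, ContentRecord, Part, RiskRow, Status
from .quant import concentration_from_level, content_from_concentration

Denominator = Literal["detected_cigarettes", "all_cigarettes"]
StatName = Literal["average", "maximum"]

#: RCR above which a compound warrants attention
ATTENTION_RCR = 0.1


class ExposureParams(BaseModel):
    """Parameters of the inhalation exposure equation.

    Defaults describe an adult Korean smoker: smoking onset at 13.2 years,
    life expectancy 82.7 years (hence ED = 69.5 years and AT = 25,367.5
    days), 13.2 cigarettes/day, 14.25 m³/day inhalation rate and daily
    exposure (EF = 365 days/year).
    """

    n_cigs_per_day: float = 13.2
    exposure_duration_years: float = 69.5
    exposure_frequency_days_per_year: float = 365.0
    inhalation_rate_m3_per_day: float = 14.25
    averaging_time_days: float = 25_367.5
    life_expectancy_years: float = 82.7
    smoking_onset_age_years: float = 13.2

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _consistent(self) -> "ExposureParams":
        if self.smoking_onset_age_years >= self.life_expectancy_years:
            raise ValueError("smoking onset must precede life expectancy")
        for name in (
            "n_cigs_per_day",
            "exposure_duration_years",
            "exposure_frequency_days_per_year",
            "inhalation_rate_m3_per_day",
            "averaging_time_days",
            "life_expectancy_years",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ed = self.life_expectancy_years - self.smoking_onset_age_years
        if not math.isclose(self.exposure_duration_years, ed, rel_tol=1e-9):
            raise ValueError("ED must equal life expectancy − onset age")
        if not math.isclose(
            self.averaging_time_days,
            self.exposure_duration_years * 365.0,
            rel_tol=1e-9,
        ):
            raise ValueError("AT must equal ED × 365 days/year")
        return self


def derive_exposure_params(
    life_expectancy_years: float = 82.7,
    smoking_onset_age_years: float = 13.2,
    n_cigs_per_day: float = 13.2,
    inhalation_rate_m3_per_day: float = 14.25,
    exposure_frequency_days_per_year: float = 365.0,
) -> ExposureParams:
    """Derive ED and AT from life expectancy and smoking-onset age."""
    if smoking_onset_age_years >= life_expectancy_years:
        raise ValueError("smoking onset must precede life expectancy")
    ed = life_expectancy_years - smoking_onset_age_years
    return ExposureParams(
        n_cigs_per_day=n_cigs_per_day,
        exposure_duration_years=ed,
        exposure_frequency_days_per_year=exposure_frequency_days_per_year,
        inhalation_rate_m3_per_day=inhalation_rate_m3_per_day,
        averaging_time_days=ed * 365.0,
        life_expectancy_years=life_expectancy_years,
        smoking_onset_age_years=smoking_onset_age_years,
    )


@dataclass(frozen=True)
class SubstitutionResult:
    """Outcome of censoring substitution.

    ``excluded_compounds`` lists analytes never detected in any product;
    they are not subject to exposure estimation at all.
    """

    records: list[ContentRecord]
    excluded_compounds: frozenset[str]


def substitute_censored(
    records: Iterable[ContentRecord], compounds: CompoundTable
) -> SubstitutionResult:
    """Apply the censoring policy to content records.

    Below-LOQ records are replaced by the LOQ-equivalent content (the LOQ
    level in ng/mL pushed through the concentration and content equations
    at dilution 1); not-detected records contribute 0; quantified records
    pass through unchanged. Compounds with no detection anywhere are
    flagged for exclusion from exposure estimation.
    """
    records = list(records)
    detected: set[str] = set()
    out: list[ContentRecord] = []
    for r in records:
        if r.status is not Status.NOT_DETECTED:
            detected.add(r.compound)
        if r.status is Status.BELOW_LOQ:
            compound = compounds[r.compound]
            _, loq = compound.limits_for_part(r.part)
            # weight cancels between the two equations; any positive value works
            conc = concentration_from_level(loq, r.extract_volume_ml, 1.0, 1.0)
            content = content_from_concentration(conc, 1.0)
            out.append(
                replace(
                    r,
                    concentration_ng_per_g=conc,
                    content_ug_per_cigarette=content,
                )
            )
        else:
            out.append(r)
    seen = {r.compound for r in records}
    return SubstitutionResult(
        records=out, excluded_compounds=frozenset(seen - detected)
    )


def per_cigarette_total(
    records: Iterable[ContentRecord], compound: str
) -> dict[str, float]:
    """Total content of *compound* per cigarette (µg).

    Sums tobacco, filter tip and every capsule of each cigarette; duplicate
    (cigarette, part, capsule index) rows are rejected. Cigarettes whose
    parts are all censored keep a total of 0 so the averaging-denominator
    policy stays explicit downstream.
    """
    totals: dict[str, float] = {}
    seen: set[tuple] = set()
    for r in records:
        if r.compound != compound:
            continue
        key = (r.cigarette_id, r.part, r.capsule_index)
        if key in seen:
            raise ValueError(
                f"duplicate record for {compound} at {key}"
            )
        seen.add(key)
        totals[r.cigarette_id] = (
            totals.get(r.cigarette_id, 0.0) + r.content_ug_per_cigarette
        )
    return totals


def content_stat(
    totals: Mapping[str, float],
    stat: StatName = "average",
    denominator: Denominator = "detected_cigarettes",
) -> float:
    """Average or maximum per-cigarette total content.

    Under ``detected_cigarettes`` the mean is taken over cigarettes where
    the compound was detected (total > 0); under ``all_cigarettes`` every
    cigarette enters the denominator.
    """
    if not totals:
        raise ValueError("no per-cigarette totals supplied")
    values = list(totals.values())
    if stat == "maximum":
        return max(values)
    if stat != "average":
        raise ValueError(f"unknown stat {stat!r}")
    if denominator == "all_cigarettes":
        return sum(values) / len(values)
    if denominator != "detected_cigarettes":
        raise ValueError(f"unknown denominator {denominator!r}")
    detected = [v for v in values if v > 0]
    if not detected:
        return 0.0
    return sum(detected) / len(detected)


def exposure_concentration(
    content_ug_per_cigarette: float, params: ExposureParams
) -> float:
    """Inhalation exposure concentration (mg/m³) for a per-cigarette content."""
    if content_ug_per_cigarette < 0:
        raise ValueError("content must be non-negative")
    p = params
    return (
        content_ug_per_cigarette
        * p.n_cigs_per_day
        * p.exposure_duration_years
        * p.exposure_frequency_days_per_year
        / (p.inhalation_rate_m3_per_day * p.averaging_time_days)
        / 1000.0  # µg → mg
    )


def risk_characterization(exposure_mg_per_m3: float, dnel_mg_per_m3: float) -> float:
    """Risk characterization ratio: exposure divided by the DNEL."""
    if dnel_mg_per_m3 <= 0:
        raise ValueError("DNEL must be positive")
    if exposure_mg_per_m3 < 0:
        raise ValueError("exposure must be non-negative")
    return exposure_mg_per_m3 / dnel_mg_per_m3


def build_risk_table(
    records: Iterable[ContentRecord],
    params: ExposureParams,
    compounds: CompoundTable,
    denominator: Denominator = "detected_cigarettes",
) -> list[RiskRow]:
    """Full pipeline from content records to the per-compound risk table.

    One average and one maximum row per compound that (a) was detected in
    at least one product and (b) has a registered DNEL. Compounds without a
    DNEL are silently skipped — there is nothing to characterize against.
    """
    sub = substitute_censored(records, compounds)
    by_compound: dict[str, list[ContentRecord]] = {}
    for r in sub.records:
        by_compound.setdefault(r.compound, []).append(r)
    rows: list[RiskRow] = []
    for name in sorted(by_compound):
        if name in sub.excluded_compounds:
            continue
        dnel = compounds[name].dnel_mg_per_m3
        if dnel is None:
            continue
        totals = per_cigarette_total(by_compound[name], name)
        for stat in ("average", "maximum"):
            content = content_stat(totals, stat, denominator)
            ec = exposure_concentration(content, params)
            rows.append(
                RiskRow(
                    compound=name,
                    stat=stat,
                    content_ug_per_cigarette=content,
                    exposure_mg_per_m3=ec,
                    dnel_mg_per_m3=dnel,
                    rcr=risk_characterization(ec, dnel),
                )
            )
    return rows


def risk_rows_from_content_stats(
    stats: Iterable[tuple[str, str, float]],
    params: ExposureParams,
    compounds: CompoundTable,
) -> list[RiskRow]:
    """Risk rows from already-aggregated (compound, stat, content) triples.

    Entry point for feeding published per-compound content summaries
    directly, bypassing raw per-cigarette records.
    """
    rows = []
    for name, stat, content in stats:
        dnel = compounds[name].dnel_mg_per_m3
        if dnel is None:
            continue
        ec = exposure_concentration(float(content), params)
        rows.append(
            RiskRow(
                compound=name,
                stat=str(stat),
                content_ug_per_cigarette=float(content),
                exposure_mg_per_m3=ec,
                dnel_mg_per_m3=dnel,
                rcr=risk_characterization(ec, dnel),
            )
        )
    return rows


def round_sig(x: float, sig: int = 2) -> float:
    """Round to *sig* significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def format_rcr(rcr: float) -> str:
    """Render an RCR at two significant figures in scientific notation.

    Matches report style, e.g. ``1.8 × 10^-1``.
    """
    if rcr == 0:
        return "0"
    exp = math.floor(math.log10(abs(rcr)))
    mant = rcr / 10**exp
    mant = round(mant, 1)
    if mant >= 10:  # rounding rolled the mantissa over
        mant /= 10
        exp += 1
    return f"{mant:.1f} × 10^{exp}"


def format_exposure(ec: float) -> str:
    """Render an exposure concentration at five decimal places."""
    return f"{ec:.5f}"
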