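"""Domain types shared by every stage of the pipeline.

The unit conventions follow analytical practice for extract-based
quantification of cigarette parts:

* instrument levels are in ng/mL of extract,
* matrix concentrations in ng/g of sampled material,
* per-part and per-cigarette contents in µg/cigarette,
* inhalation exposure concentrations in mg/m³.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from pydantic import BaseModel, field_validator, model_validator


class Part(str, Enum):
    """Physical part of a cigarette that is extracted separately."""

    TOBACCO = "tobacco"
    FILTER_TIP = "filter_tip"
    CAPSULE = "capsule"


class Matrix(str, Enum):
    """Matrix in which detection/quantification limits were established.

    Capsule extracts are quantified against pure-solvent limits because no
    blank (flavor-free) capsule exists to spike.
    """

    SOLVENT = "solvent"
    TOBACCO = "tobacco"
    FILTER_TIP = "filter_tip"


class Status(str, Enum):
    """Three-way censoring state of a single measurement."""

    QUANTIFIED = "quantified"
    BELOW_LOQ = "below_loq"
    NOT_DETECTED = "not_detected"


#: matrix whose LOD/LOQ governs each cigarette part
MATRIX_FOR_PART = {
    Part.TOBACCO: Matrix.TOBACCO,
    Part.FILTER_TIP: Matrix.FILTER_TIP,
    Part.CAPSULE: Matrix.SOLVENT,
}

#: acetone extraction volumes (mL); the whole capsule is extracted in 10 mL
DEFAULT_EXTRACT_VOLUME_ML = {
    Part.TOBACCO: 25.0,
    Part.FILTER_TIP: 25.0,
    Part.CAPSULE: 10.0,
}

#: aliquot weighed for tobacco / filter-tip extraction (g)
DEFAULT_SAMPLE_WEIGHT_G = 0.25


_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def validate_cas_rn(cas_rn: str) -> bool:
    """Return True iff *cas_rn* matches the CAS pattern and its check digit.

    The check digit is the weighted sum of the preceding digits (weights
    1, 2, 3, ... from the right) modulo 10.
    """
    m = _CAS_RE.match(cas_rn)
    if m is None:
        return False
    digits = [int(d) for d in (m.group(1) + m.group(2))]
    check = sum(w * d for w, d in enumerate(reversed(digits), start=1)) % 10
    return check == int(m.group(3))


class Compound(BaseModel):
    """One analyte with its regulatory and method-validation constants.

    ``dnel_mg_per_m3`` is the long-term systemic inhalation DNEL for the
    general population; it is absent for analytes without a registered
    inhalation DNEL, which are therefore excluded from risk output.
    LOD/LOQ are per matrix in ng/mL of extract; for tobacco and filter-tip
    matrices the LOD is the method detection limit (MDL) determined in a
    spiked blank matrix.
    """

    name: str
    cas_rn: str
    dnel_mg_per_m3: Optional[float] = None
    lod_ng_per_ml: dict[Matrix, float]
    loq_ng_per_ml: dict[Matrix, float]

    model_config = {"frozen": True}

    @field_validator("cas_rn")
    @classmethod
    def _cas_valid(cls, v: str) -> str:
        if not validate_cas_rn(v):
            raise ValueError(f"invalid CAS RN {v!r} (pattern or check digit)")
        return v

    @field_validator("dnel_mg_per_m3")
    @classmethod
    def _dnel_positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("DNEL must be positive when present")
        return v

    @model_validator(mode="after")
    def _limits_consistent(self) -> "Compound":
        for matrix, loq in self.loq_ng_per_ml.items():
            lod = self.lod_ng_per_ml.get(matrix)
            if lod is None:
                raise ValueError(f"{self.name}: LOQ without LOD for {matrix}")
            if not (loq > lod > 0):
                raise ValueError(
                    f"{self.name}: need LOQ > LOD > 0 in {matrix}, "
                    f"got LOD={lod}, LOQ={loq}"
                )
        return self

    def limits_for_part(self, part: Part) -> tuple[float, float]:
        """(LOD, LOQ) in ng/mL governing measurements of *part*."""
        matrix = MATRIX_FOR_PART[Part(part)]
        try:
            return self.lod_ng_per_ml[matrix], self.loq_ng_per_ml[matrix]
        except KeyError:
            raise KeyError(
                f"{self.name}: no detection limits for matrix {matrix.value}"
            ) from None


class CompoundTable:
    """Lookup of compounds by name with uniqueness guarantees."""

    def __init__(self, compounds: list[Compound]):
        self._by_name: dict[str, Compound] = {}
        seen_cas: dict[str, str] = {}
        for c in compounds:
            if c.name in self._by_name:
                raise ValueError(f"duplicate compound name {c.name!r}")
            if c.cas_rn in seen_cas:
                raise ValueError(
                    f"CAS RN {c.cas_rn} shared by {seen_cas[c.cas_rn]!r} "
                    f"and {c.name!r}"
                )
            self._by_name[c.name] = c
            seen_cas[c.cas_rn] = c.name

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self):
        return iter(self._by_name.values())

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Compound:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown compound {name!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self._by_name)


@dataclass(frozen=True)
class PartQuantRecord:
    """One compound × one cigarette-part measurement off the instrument.

    ``detected_level_ng_per_ml`` is the level read from the calibration
    curve of the (possibly diluted) extract; ``dilution_factor`` scales it
    back to the undiluted extract in Eq.-style concentration computation.
    """

    cigarette_id: str
    has_capsule: bool
    part: Part
    compound: str
    detected_level_ng_per_ml: Optional[float]
    status: Status
    capsule_index: Optional[int] = None
    dilution_factor: float = 1.0
    extract_volume_ml: Optional[float] = None
    sample_weight_g: float = DEFAULT_SAMPLE_WEIGHT_G

    def __post_init__(self):
        part = Part(self.part)
        object.__setattr__(self, "part", part)
        object.__setattr__(self, "status", Status(self.status))
        if self.extract_volume_ml is None:
            object.__setattr__(
                self, "extract_volume_ml", DEFAULT_EXTRACT_VOLUME_ML[part]
            )
        if self.extract_volume_ml <= 0:
            raise ValueError("extract_volume_ml must be positive")
        if self.sample_weight_g <= 0:
            raise ValueError("sample_weight_g must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be ≥ 1")
        if (self.capsule_index is not None) != (part is Part.CAPSULE):
            raise ValueError("capsule_index present iff part is capsule")
        if self.capsule_index is not None and self.capsule_index < 1:
            raise ValueError("capsule_index must be ≥ 1")
        if part is Part.CAPSULE and not self.has_capsule:
            raise ValueError("capsule part on a non-capsule cigarette")
        lvl = self.detected_level_ng_per_ml
        if lvl is not None and lvl < 0:
            raise ValueError("detected level must be non-negative")
        if self.status is Status.QUANTIFIED and lvl is None:
            raise ValueError("quantified record requires a detected level")

    def validate_against(self, compound: Compound) -> None:
        """Check the censoring status against the compound's matrix limits."""
        lod, loq = compound.limits_for_part(self.part)
        lvl = self.detected_level_ng_per_ml
        if self.status is Status.QUANTIFIED and (lvl is None or lvl < loq):
            raise ValueError(
                f"{self.cigarette_id}/{self.compound}: quantified but level "
                f"{lvl} < LOQ {loq}"
            )
        if self.status is Status.BELOW_LOQ and lvl is not None and lvl >= loq:
            raise ValueError(
                f"{self.cigarette_id}/{self.compound}: below_loq but level "
                f"{lvl} ≥ LOQ {loq}"
            )


def status_from_level(
    level: Optional[float], lod: float, loq: float
) -> Status:
    """Censoring status implied by a detected level and matrix limits."""
    if level is None or level < lod:
        return Status.NOT_DETECTED
    if level < loq:
        return Status.BELOW_LOQ
    return Status.QUANTIFIED


@dataclass(frozen=True)
class ContentRecord:
    """Content of one compound in one part, in µg/cigarette.

    ``status`` keeps the three-way censoring distinction alive after unit
    conversion; ``content_ug_per_cigarette`` of a ``below_loq`` record is 0
    until censoring substitution replaces it with the LOQ-equivalent
    content, and a ``not_detected`` record always contributes 0.
    """

    cigarette_id: str
    has_capsule: bool
    part: Part
    compound: str
    concentration_ng_per_g: float
    content_ug_per_cigarette: float
    status: Status
    capsule_index: Optional[int] = None
    extract_volume_ml: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "part", Part(self.part))
        object.__setattr__(self, "status", Status(self.status))
        if self.extract_volume_ml is None:
            object.__setattr__(
                self, "extract_volume_ml", DEFAULT_EXTRACT_VOLUME_ML[self.part]
            )
        if self.content_ug_per_cigarette < 0 or self.concentration_ng_per_g < 0:
            raise ValueError("contents and concentrations are non-negative")

    @property
    def censored(self) -> bool:
        return self.status is not Status.QUANTIFIED


@dataclass(frozen=True)
class RiskRow:
    """One line of the risk table: per-compound content → exposure → RCR."""

    compound: str
    stat: str  # "average" | "maximum"
    content_ug_per_cigarette: float
    exposure_mg_per_m3: float
    dnel_mg_per_m3: float
    rcr: float

    @property
    def attention(self) -> bool:
        """Exposure above one tenth of the DNEL warrants attention."""
        return self.rcr > 0.1

    @property
    def exceeds(self) -> bool:
        return self.rcr > 1.0
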