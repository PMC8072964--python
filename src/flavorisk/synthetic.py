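"""Synthetic study generator.

Emulates the shape of the underlying survey: 24 non-capsule and 30 capsule
cigarettes (12 of the capsule cigarettes carrying two capsules, for 42
capsules in total), per-compound detection frequencies, and right-skewed
per-part content distributions. Contents are drawn from log-normal
distributions parameterized per compound × part × cigarette class from the
published class-wise means, SDs and detection counts; instrument levels are
then back-computed through the concentration/content equations and censored
against the per-matrix LOD/LOQ, so generated datasets exercise exactly the
same code paths as real quantification tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core import (
    DEFAULT_EXTRACT_VOLUME_ML,
    DEFAULT_SAMPLE_WEIGHT_G,
    CompoundTable,
    Matrix,
    Part,
    Status,
)

#: default whole-capsule weight (g); content values are weight-independent
DEFAULT_CAPSULE_WEIGHT_G = 0.021

CigaretteClass = Literal["non_capsule", "capsule"]


def lognormal_params_from_mean_sd(
    mean: float, sd: Optional[float], default_cv: float = 0.2
) -> tuple[float, float]:
    """(log-mean, log-sd) of a log-normal matching an arithmetic mean and SD.

    σ² = ln(1 + CV²), µ = ln(mean) − σ²/2. Cells observed once (or with a
    printed SD of 0) get a small default CV rather than a degenerate
    distribution.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    cv = default_cv if not sd or sd <= 0 else sd / mean
    sigma2 = math.log1p(cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


class CellParams(BaseModel):
    """Sampling law for one compound × part × cigarette-class cell."""

    compound: str
    part: Part
    cigarette_class: CigaretteClass
    detection_probability: float = Field(ge=0.0, le=1.0)
    log_mean: float
    log_sd: float = Field(ge=0.0)
    censor_fraction: float = Field(default=0.0, ge=0.0, le=1.0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _capsule_class(self) -> "CellParams":
        if self.part is Part.CAPSULE and self.cigarette_class != "capsule":
            raise ValueError("capsule parts exist only in capsule cigarettes")
        return self

    @property
    def mean_content(self) -> float:
        """Arithmetic mean (µg) of the content distribution."""
        return math.exp(self.log_mean + self.log_sd**2 / 2.0)


@dataclass(frozen=True)
class CellObservables:
    """What a cell's law implies for the *observable* data after censoring.

    ``detection_frequency`` is the probability a unit yields a detected
    record (content above the LOD-equivalent content); ``quantified_fraction``
    additionally requires clearing the LOQ; ``mean_quantified_content`` is
    the LOQ-truncated mean E[X | X ≥ LOQ-content] in µg.
    """

    detection_frequency: float
    quantified_fraction: float
    mean_quantified_content: float


def cell_observables(
    cell: "CellParams", compounds: CompoundTable
) -> CellObservables:
    """Closed-form observables implied by a cell under LOD/LOQ censoring."""
    from scipy.stats import norm

    lod, loq = compounds[cell.compound].limits_for_part(cell.part)
    volume = DEFAULT_EXTRACT_VOLUME_ML[cell.part]
    t_lod = lod * volume / 1000.0
    t_loq = loq * volume / 1000.0
    p = cell.detection_probability
    if cell.log_sd == 0:
        x = math.exp(cell.log_mean)
        f_lod = 1.0 if x < t_lod else 0.0
        f_loq = 1.0 if x < t_loq else 0.0
        mean_q = x if x >= t_loq else math.nan
    else:
        mu, s = cell.log_mean, cell.log_sd
        f_lod = float(norm.cdf((math.log(t_lod) - mu) / s))
        f_loq = float(norm.cdf((math.log(t_loq) - mu) / s))
        if f_loq < 1.0:
            upper = float(norm.cdf((mu + s * s - math.log(t_loq)) / s))
            mean_q = cell.mean_content * upper / (1.0 - f_loq)
        else:
            mean_q = math.nan
    return CellObservables(
        detection_frequency=p * (1.0 - f_lod),
        quantified_fraction=p * (1.0 - f_loq) * (1.0 - cell.censor_fraction),
        mean_quantified_content=mean_q,
    )


class SyntheticStudyConfig(BaseModel):
    """Study layout plus the per-cell content laws."""

    n_noncapsule: int = Field(default=24, ge=0)
    n_capsule: int = Field(default=30, ge=0)
    two_capsule_fraction: float = Field(default=0.4, ge=0.0, le=1.0)
    cells: tuple[CellParams, ...] = ()
    calibration_max_ng_per_ml: float = Field(default=500.0, gt=0)
    seed: int = 0

    model_config = {"frozen": True}

    def scaled(self, n_total: int) -> "SyntheticStudyConfig":
        """Same composition at a different total number of cigarettes."""
        frac = self.n_noncapsule / max(1, self.n_noncapsule + self.n_capsule)
        n_nc = round(n_total * frac)
        return self.model_copy(
            update={"n_noncapsule": n_nc, "n_capsule": n_total - n_nc}
        )


# (mean µg, sd µg or None, detected count) per compound; denominators are
# 24 non-capsule cigarettes, 30 capsule cigarettes and 42 capsules.
_NONCAP_TOBACCO = {
    "Linalool": (0.05, 0.01, 8),
    "Citral": (0.22, 0.06, 24),
    "α-Isomethyl ionone": (0.02, 0.0, 3),
    "Benzyl alcohol": (3.63, 7.14, 22),
    "Eugenol": (0.11, 0.03, 2),
    "Anise alcohol": (0.41, None, 1),
    "Isoeugenol": (0.22, 0.04, 3),
    "Benzyl benzoate": (1.08, 1.90, 9),
    "Benzyl salicylate": (0.51, 0.04, 2),
    "Menthol": (0.75, 0.77, 23),
}
_NONCAP_FILTER = {
    "D-Limonene": (0.47, 0.31, 4),
    "Linalool": (0.07, 0.03, 17),
    "Citral": (0.10, 0.02, 10),
    "Geraniol": (0.57, None, 1),
    "Benzyl alcohol": (8.40, 13.27, 24),
    "Benzyl benzoate": (0.06, None, 1),
    "Menthol": (1.35, 1.04, 23),
}
_CAP_TOBACCO = {
    "D-Limonene": (8.50, 10.93, 7),
    "Linalool": (0.94, 2.06, 13),
    "Citral": (0.35, 0.66, 30),
    "α-Isomethyl ionone": (0.02, 0.0, 9),
    "Benzyl alcohol": (2.19, 3.81, 30),
    "Eugenol": (0.16, 0.07, 2),
    "Anise alcohol": (0.35, 0.16, 3),
    "Isoeugenol": (0.53, 0.14, 2),
    "Benzyl benzoate": (0.13, 0.17, 22),
    "Menthol": (336.98, 553.89, 30),
}
_CAP_FILTER = {
    "D-Limonene": (13.64, 16.60, 7),
    "Linalool": (3.08, 8.54, 27),
    "Citral": (20.30, 43.83, 6),
    "Citronellol": (1.89, 1.36, 2),
    "Geraniol": (1.45, 1.13, 5),
    "α-Isomethyl ionone": (0.03, 0.01, 8),
    "Benzyl alcohol": (26.46, 45.49, 30),
    "Methyl eugenol": (0.03, None, 1),
    "Cinnamaldehyde": (0.36, 0.40, 7),
    "Eugenol": (1.00, None, 1),
    "Anise alcohol": (0.46, 0.05, 2),
    "Benzyl cinnamate": (1.18, None, 1),
    "Menthol": (735.76, 1040.40, 30),
}
_CAPSULE = {
    "D-Limonene": (265.07, 379.35, 40),
    "Linalool": (33.31, 63.04, 41),
    "Citral": (24.62, 64.42, 29),
    "Citronellol": (2.81, 5.45, 25),
    "Geraniol": (9.74, 25.91, 26),
    "α-Isomethyl ionone": (0.02, 0.0, 1),
    "Benzyl alcohol": (30.78, 93.53, 21),
    "Methyl eugenol": (0.06, 0.09, 12),
    "Cinnamaldehyde": (43.56, 69.30, 10),
    "Eugenol": (0.24, 0.17, 27),
    "Cinnamyl alcohol": (0.25, 0.13, 3),
    "Isoeugenol": (0.37, 0.43, 5),
    "Farnesol": (0.22, 0.0, 2),
    "Benzyl benzoate": (0.20, 0.14, 7),
    "Benzyl cinnamate": (2.08, 2.91, 6),
    "Menthol": (1518.22, 450.78, 42),
}


def default_study_config(seed: int = 0) -> SyntheticStudyConfig:
    """Default configuration emulating the published study conditions."""
    cells: list[CellParams] = []

    def add(table, part: Part, klass: CigaretteClass, denom: int):
        for compound, (mean, sd, n) in table.items():
            mu, sigma = lognormal_params_from_mean_sd(mean, sd)
            cells.append(
                CellParams(
                    compound=compound,
                    part=part,
                    cigarette_class=klass,
                    detection_probability=n / denom,
                    log_mean=mu,
                    log_sd=sigma,
                )
            )

    add(_NONCAP_TOBACCO, Part.TOBACCO, "non_capsule", 24)
    add(_NONCAP_FILTER, Part.FILTER_TIP, "non_capsule", 24)
    add(_CAP_TOBACCO, Part.TOBACCO, "capsule", 30)
    add(_CAP_FILTER, Part.FILTER_TIP, "capsule", 30)
    add(_CAPSULE, Part.CAPSULE, "capsule", 42)
    return SyntheticStudyConfig(cells=tuple(cells), seed=seed)


def _units(config: SyntheticStudyConfig):
    """Sampling units: one per cigarette part instance."""
    nc_ids = [f"NC{i+1:03d}" for i in range(config.n_noncapsule)]
    cap_ids = [f"C{i+1:03d}" for i in range(config.n_capsule)]
    n_two = round(config.two_capsule_fraction * config.n_capsule)
    units = []  # (cigarette_id, has_capsule, part, capsule_index, class)
    for cid in nc_ids:
        units.append((cid, False, Part.TOBACCO, None, "non_capsule"))
        units.append((cid, False, Part.FILTER_TIP, None, "non_capsule"))
    for k, cid in enumerate(cap_ids):
        units.append((cid, True, Part.TOBACCO, None, "capsule"))
        units.append((cid, True, Part.FILTER_TIP, None, "capsule"))
        n_caps = 2 if k < n_two else 1
        for ci in range(1, n_caps + 1):
            units.append((cid, True, Part.CAPSULE, ci, "capsule"))
    return units


def generate_study(
    config: Optional[SyntheticStudyConfig] = None,
    seed: Optional[int] = None,
    compounds: Optional[CompoundTable] = None,
) -> pd.DataFrame:
    """Generate a quantification table (one row per unit × compound).

    Deterministic for a given seed. For every compound with a configured
    cell, a unit detects it with the cell's probability and draws a content
    from the cell's log-normal; the instrument level is back-computed as
    content × 1000 / volume and censored against the compound's per-matrix
    LOD/LOQ (levels above the calibration range are diluted in decades and
    re-quantified, mirroring re-analysis of over-range extracts). Compounds
    without a cell for a unit yield a not-detected row, so every compound
    appears for every unit and detection frequencies are well defined.
    """
    from .io import load_compound_table  # local import to avoid a cycle

    if config is None:
        config = default_study_config()
    if compounds is None:
        compounds = load_compound_table()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    units = _units(config)
    cells = {
        (c.compound, c.part, c.cigarette_class): c for c in config.cells
    }
    unit_df = pd.DataFrame(
        units,
        columns=["cigarette_id", "has_capsule", "part", "capsule_index", "klass"],
    )
    frames = []
    for name in compounds.names:
        for (part, klass), idx in unit_df.groupby(
            ["part", "klass"], sort=False
        ).groups.items():
            sub = unit_df.loc[idx]
            n = len(sub)
            cell = cells.get((name, part, klass))
            level = np.full(n, np.nan)
            status = np.full(n, Status.NOT_DETECTED.value, dtype=object)
            dilution = np.ones(n)
            volume = DEFAULT_EXTRACT_VOLUME_ML[part]
            if cell is not None and cell.detection_probability > 0:
                detected = rng.random(n) < cell.detection_probability
                content = np.zeros(n)
                content[detected] = rng.lognormal(
                    cell.log_mean, cell.log_sd, detected.sum()
                )
                raw_level = content * 1000.0 / volume  # undiluted extract
                lod, loq = compounds[name].limits_for_part(part)
                over = raw_level > config.calibration_max_ng_per_ml
                with np.errstate(divide="ignore"):
                    decades = np.where(
                        over,
                        np.ceil(
                            np.log10(
                                np.maximum(raw_level, 1e-300)
                                / config.calibration_max_ng_per_ml
                            )
                        ),
                        0.0,
                    )
                dilution = np.power(10.0, decades)
                measured = raw_level / dilution
                quant = detected & (raw_level >= loq)
                below = detected & (raw_level >= lod) & (raw_level < loq)
                if cell.censor_fraction > 0:
                    flip = quant & (rng.random(n) < cell.censor_fraction)
                    quant &= ~flip
                    below |= flip
                    measured[flip] = lod + 0.5 * (loq - lod)
                    dilution[flip] = 1.0
                status[quant] = Status.QUANTIFIED.value
                status[below] = Status.BELOW_LOQ.value
                level = np.where(quant | below, measured, np.nan)
                dilution = np.where(quant | below, dilution, 1.0)
            weight = (
                DEFAULT_CAPSULE_WEIGHT_G
                if part is Part.CAPSULE
                else DEFAULT_SAMPLE_WEIGHT_G
            )
            frames.append(
                pd.DataFrame(
                    {
                        "cigarette_id": sub["cigarette_id"].to_numpy(),
                        "has_capsule": sub["has_capsule"].to_numpy(),
                        "part": part.value,
                        "capsule_index": sub["capsule_index"].to_numpy(),
                        "compound": name,
                        "detected_level_ng_per_ml": level,
                        "status": status,
                        "dilution_factor": dilution,
                        "extract_volume_ml": volume,
                        "sample_weight_g": weight,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    order = ["cigarette_id", "part", "capsule_index", "compound"]
    return df.sort_values(order, kind="stable").reset_index(drop=True)


def study_records(df: pd.DataFrame, compounds: CompoundTable):
    """Materialize a generated table as validated PartQuantRecord objects."""
    from .core import PartQuantRecord

    records = []
    for row in df.to_dict("records"):
        level = row["detected_level_ng_per_ml"]
        level = None if pd.isna(level) else float(level)
        cap = row["capsule_index"]
        cap = None if pd.isna(cap) else int(cap)
        rec = PartQuantRecord(
            cigarette_id=row["cigarette_id"],
            has_capsule=bool(row["has_capsule"]),
            part=Part(row["part"]),
            compound=row["compound"],
            detected_level_ng_per_ml=level,
            status=Status(row["status"]),
            capsule_index=cap,
            dilution_factor=float(row["dilution_factor"]),
            extract_volume_ml=float(row["extract_volume_ml"]),
            sample_weight_g=float(row["sample_weight_g"]),
        )
        rec.validate_against(compounds[rec.compound])
        records.append(rec)
    return records


class ValidationFixtureConfig(BaseModel):
    """Settings for synthetic method-validation data."""

    spike_levels_ug_per_g: tuple[float, ...] = (2.5, 5.0, 50.0)
    n_replicates: int = Field(default=3, ge=2)
    recovery_bias: Optional[float] = None  # None → per-compound U(0.85, 1.05)
    noise_cv: float = Field(default=0.03, ge=0.0)
    calibration_levels_ng_per_ml: tuple[float, ...] = (
        5.0, 10.0, 50.0, 100.0, 250.0, 500.0,
    )
    response_noise_cv: float = Field(default=0.003, ge=0.0)
    matrices: tuple[Matrix, ...] = (Matrix.TOBACCO, Matrix.FILTER_TIP)

    model_config = {"frozen": True}


def generate_validation_fixture(
    config: Optional[ValidationFixtureConfig] = None,
    seed: int = 0,
    compounds: Optional[CompoundTable] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic calibration points and spiked triplicates.

    Returns (calibration frame, spike frame). Measured spike values are
    spiked × bias × (1 + noise); calibration responses are a per-compound
    true slope with small proportional noise, so fitted curves clear the
    linearity gate unless the noise is raised deliberately.
    """
    from .io import load_compound_table

    if config is None:
        config = ValidationFixtureConfig()
    if compounds is None:
        compounds = load_compound_table()
    rng = np.random.default_rng(seed)
    calib_rows, spike_rows = [], []
    levels = np.asarray(config.calibration_levels_ng_per_ml)
    for name in compounds.names:
        slope = rng.uniform(0.5, 2.0)
        responses = slope * levels * (
            1.0 + config.response_noise_cv * rng.standard_normal(levels.size)
        )
        for lvl, resp in zip(levels, responses):
            calib_rows.append(
                {"compound": name, "level_ng_per_ml": float(lvl),
                 "response": float(resp)}
            )
        for matrix in config.matrices:
            bias = (
                config.recovery_bias
                if config.recovery_bias is not None
                else rng.uniform(0.85, 1.05)
            )
            for spike in config.spike_levels_ug_per_g:
                noise = config.noise_cv * rng.standard_normal(
                    config.n_replicates
                )
                for rep, eps in enumerate(noise, start=1):
                    spike_rows.append(
                        {
                            "compound": name,
                            "matrix": matrix.value,
                            "spike_ug_per_g": float(spike),
                            "replicate": rep,
                            "measured_ug_per_g": float(
                                spike * bias * (1.0 + eps)
                            ),
                        }
                    )
    return pd.DataFrame(calib_rows), pd.DataFrame(spike_rows)
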