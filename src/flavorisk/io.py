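"""CSV readers/writers and the bundled compound reference table.

All exchange formats are plain comma-separated UTF-8 text with a ``.``
decimal and one record per (cigarette, part, capsule index, compound).
Censoring travels as the literal status column ``quantified | below_loq |
not_detected`` so the three-way distinction survives I/O.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .core import (
    Compound,
    CompoundTable,
    ContentRecord,
    Matrix,
    Part,
    PartQuantRecord,
    RiskRow,
    Status,
    status_from_level,
)
from .exposure import ExposureParams, derive_exposure_params


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable layout."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def _data_path(name: str):
    return resources.files("flavorisk").joinpath("data", name)


def load_compound_table(
    compounds_path: Optional[str] = None,
    limits_path: Optional[str] = None,
) -> CompoundTable:
    """Load the compound reference (names, CAS RNs, DNELs, detection limits).

    Without arguments the bundled tables are used: real CAS RNs and DNELs,
    and synthetic per-compound detection limits spanning the validated
    method's published ranges (per-compound limits were never published).
    Users supply their own CSVs to override either.
    """
    cpath = compounds_path or _data_path("compounds.csv")
    lpath = limits_path or _data_path("detection_limits_synthetic.csv")
    cdf = pd.read_csv(cpath, comment="#")
    ldf = pd.read_csv(lpath, comment="#").set_index("name")
    _require_columns(cdf, ["name", "cas_rn"], "compound table")
    _require_columns(
        ldf.reset_index(),
        ["name", "lod_solvent", "loq_solvent", "mdl_tobacco",
         "loq_tobacco", "mdl_filter_tip", "loq_filter_tip"],
        "detection-limit table",
    )
    compounds = []
    for row in cdf.to_dict("records"):
        name = row["name"]
        if name not in ldf.index:
            raise SchemaError(f"no detection limits for compound {name!r}")
        lim = ldf.loc[name]
        dnel = row.get("dnel_mg_per_m3")
        if dnel is not None and pd.isna(dnel):
            dnel = None
        compounds.append(
            Compound(
                name=name,
                cas_rn=row["cas_rn"],
                dnel_mg_per_m3=dnel,
                lod_ng_per_ml={
                    Matrix.SOLVENT: float(lim["lod_solvent"]),
                    Matrix.TOBACCO: float(lim["mdl_tobacco"]),
                    Matrix.FILTER_TIP: float(lim["mdl_filter_tip"]),
                },
                loq_ng_per_ml={
                    Matrix.SOLVENT: float(lim["loq_solvent"]),
                    Matrix.TOBACCO: float(lim["loq_tobacco"]),
                    Matrix.FILTER_TIP: float(lim["loq_filter_tip"]),
                },
            )
        )
    return CompoundTable(compounds)


def load_study_content_summary() -> pd.DataFrame:
    """Published per-compound average/maximum contents (µg/cigarette)."""
    return pd.read_csv(_data_path("study_content_summary.csv"))


_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(v, line: int, col: str) -> bool:
    if isinstance(v, bool):
        return v
    try:
        return _BOOL[str(v).strip().lower()]
    except KeyError:
        raise ValueError(f"line {line}: column {col!r} has non-boolean {v!r}")


def read_quant_table(
    path, compounds: CompoundTable
) -> list[PartQuantRecord]:
    """Read and validate a per-part quantification table.

    Rows are validated against the record invariants and the compound's
    matrix limits; the censoring status is derived from the detected level
    when the ``status`` column is absent. Errors cite 1-based file line
    numbers (header is line 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df,
        ["cigarette_id", "has_capsule", "part", "compound"],
        "quant table",
    )
    has_status = "status" in df.columns
    records = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2
        name = row["compound"]
        if name not in compounds:
            raise ValueError(f"line {line}: unknown compound {name!r}")
        compound = compounds[name]
        level = row.get("detected_level_ng_per_ml")
        if level is not None and pd.isna(level):
            level = None
        if level is not None:
            level = float(level)
            if level < 0:
                raise ValueError(
                    f"line {line}: negative detected level {level}"
                )
        part = Part(row["part"])
        cap_idx = row.get("capsule_index")
        if cap_idx is not None and pd.isna(cap_idx):
            cap_idx = None
        if cap_idx is not None:
            cap_idx = int(cap_idx)
        if part is Part.CAPSULE and cap_idx is None:
            raise ValueError(f"line {line}: capsule row without capsule_index")
        kwargs = {}
        for field, default in (
            ("dilution_factor", 1.0),
            ("extract_volume_ml", None),
            ("sample_weight_g", None),
        ):
            v = row.get(field)
            if v is None or pd.isna(v):
                v = default
            if v is not None:
                kwargs[field] = float(v)
        volume = kwargs.get("extract_volume_ml")
        if has_status and not pd.isna(row["status"]):
            status = Status(row["status"])
        else:
            lod, loq = compound.limits_for_part(part)
            status = status_from_level(level, lod, loq)
        try:
            rec = PartQuantRecord(
                cigarette_id=str(row["cigarette_id"]),
                has_capsule=_parse_bool(row["has_capsule"], line, "has_capsule"),
                part=part,
                compound=name,
                detected_level_ng_per_ml=level,
                status=status,
                capsule_index=cap_idx,
                **kwargs,
            )
            rec.validate_against(compound)
        except ValueError as exc:
            raise ValueError(f"line {line}: {exc}") from None
        records.append(rec)
    return records


def _frame_from_records(rows: Iterable, columns: Sequence[str]) -> pd.DataFrame:
    data = [dataclasses.asdict(r) for r in rows]
    df = pd.DataFrame(data, columns=list(columns))
    for col in df.columns:
        if df[col].map(lambda v: isinstance(v, (Part, Status))).any():
            df[col] = df[col].map(lambda v: v.value if v is not None else v)
    return df


_QUANT_COLUMNS = [
    "cigarette_id", "has_capsule", "part", "capsule_index", "compound",
    "detected_level_ng_per_ml", "status", "dilution_factor",
    "extract_volume_ml", "sample_weight_g",
]

_CONTENT_COLUMNS = [
    "cigarette_id", "has_capsule", "part", "capsule_index", "compound",
    "concentration_ng_per_g", "content_ug_per_cigarette", "status",
    "extract_volume_ml",
]

_RISK_COLUMNS = [
    "compound", "stat", "content_ug_per_cigarette", "exposure_mg_per_m3",
    "dnel_mg_per_m3", "rcr",
]


def write_quant_table(records: Iterable[PartQuantRecord], path) -> None:
    _frame_from_records(records, _QUANT_COLUMNS).to_csv(path, index=False)


def write_content_table(records: Iterable[ContentRecord], path) -> None:
    _frame_from_records(records, _CONTENT_COLUMNS).to_csv(path, index=False)


def read_content_table(path) -> list[ContentRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _CONTENT_COLUMNS[:3] + _CONTENT_COLUMNS[4:8], "content table")
    out = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2
        cap_idx = row.get("capsule_index")
        if cap_idx is not None and pd.isna(cap_idx):
            cap_idx = None
        try:
            out.append(
                ContentRecord(
                    cigarette_id=str(row["cigarette_id"]),
                    has_capsule=_parse_bool(row["has_capsule"], line, "has_capsule"),
                    part=Part(row["part"]),
                    compound=row["compound"],
                    concentration_ng_per_g=float(row["concentration_ng_per_g"]),
                    content_ug_per_cigarette=float(row["content_ug_per_cigarette"]),
                    status=Status(row["status"]),
                    capsule_index=int(cap_idx) if cap_idx is not None else None,
                    extract_volume_ml=float(row["extract_volume_ml"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {line}: {exc}") from None
    return out


def write_risk_table(rows: Iterable[RiskRow], path) -> None:
    """Numeric risk table; round-trips losslessly through read_risk_table."""
    _frame_from_records(rows, _RISK_COLUMNS).to_csv(path, index=False)


def read_risk_table(path) -> list[RiskRow]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _RISK_COLUMNS, "risk table")
    return [
        RiskRow(
            compound=r["compound"],
            stat=r["stat"],
            content_ug_per_cigarette=float(r["content_ug_per_cigarette"]),
            exposure_mg_per_m3=float(r["exposure_mg_per_m3"]),
            dnel_mg_per_m3=float(r["dnel_mg_per_m3"]),
            rcr=float(r["rcr"]),
        )
        for r in df.to_dict("records")
    ]


def write_report_table(rows: Iterable, path) -> None:
    """Write any homogeneous list of report dataclasses as CSV."""
    rows = list(rows)
    if not rows:
        # header cannot be inferred from an empty generic list
        Path(path).write_text("")
        return
    columns = [f.name for f in dataclasses.fields(rows[0])]
    _frame_from_records(rows, columns).to_csv(path, index=False)


def read_exposure_config(path) -> ExposureParams:
    """Exposure parameters from a YAML or JSON mapping.

    Recognized keys: ``life_expectancy``, ``onset_age``, ``n_cigs_per_day``,
    ``inhalation_rate``, ``exposure_frequency``. Missing keys fall back to
    the defaults; ED and AT are always derived, never read.
    """
    text = Path(path).read_text()
    cfg = (
        json.loads(text)
        if str(path).endswith(".json")
        else yaml.safe_load(text)
    ) or {}
    known = {
        "life_expectancy": "life_expectancy_years",
        "onset_age": "smoking_onset_age_years",
        "n_cigs_per_day": "n_cigs_per_day",
        "inhalation_rate": "inhalation_rate_m3_per_day",
        "exposure_frequency": "exposure_frequency_days_per_year",
    }
    unknown = set(cfg) - set(known)
    if unknown:
        raise SchemaError(f"exposure config: unknown key(s) {sorted(unknown)}")
    kwargs = {known[k]: float(v) for k, v in cfg.items()}
    return derive_exposure_params(**kwargs)
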