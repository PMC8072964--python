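"""End-to-end orchestration: generate/read → quantify → summarize → compare → risk.

Every output is plain CSV plus one JSON manifest recording the seed,
parameters, package version and a SHA-256 per file; nothing time-dependent
is written, so identical configuration and seed reproduce every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .core import CompoundTable, Part
from .exposure import (
    ExposureParams,
    Denominator,
    build_risk_table,
    format_exposure,
    format_rcr,
    risk_rows_from_content_stats,
    substitute_censored,
)
from .io import (
    load_compound_table,
    read_quant_table,
    write_content_table,
    write_report_table,
    write_risk_table,
)
from .quant import quantify
from .stats import (
    content_matrix,
    kruskal_wallis_with_posthoc,
    mann_whitney,
    pca_scores,
    summarize,
)
from .synthetic import SyntheticStudyConfig, default_study_config, generate_study, study_records

log = logging.getLogger("flavorisk")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_risk_report(rows) -> pd.DataFrame:
    """Report-style risk table: exposures at 5 decimals, RCR at 2 sig figs."""
    return pd.DataFrame(
        {
            "compound": [r.compound for r in rows],
            "stat": [r.stat for r in rows],
            "content_ug_per_cigarette": [
                f"{r.content_ug_per_cigarette:.2f}" for r in rows
            ],
            "exposure_mg_per_m3": [format_exposure(r.exposure_mg_per_m3) for r in rows],
            "dnel_mg_per_m3": [r.dnel_mg_per_m3 for r in rows],
            "rcr": [format_rcr(r.rcr) for r in rows],
            "attention": [r.attention for r in rows],
        }
    )


def _comparisons_by_part(content_records) -> pd.DataFrame:
    """Kruskal–Wallis across parts with Dunn–Bonferroni post hoc, per compound."""
    detected: dict[str, dict[str, list[float]]] = {}
    for r in content_records:
        if not r.censored:
            detected.setdefault(r.compound, {}).setdefault(
                r.part.value, []
            ).append(r.content_ug_per_cigarette)
    rows = []
    for compound, groups in sorted(detected.items()):
        if len(groups) < 3 or sum(len(v) for v in groups.values()) < 5:
            continue
        labels = sorted(groups)
        res = kruskal_wallis_with_posthoc(
            [groups[g] for g in labels], labels
        )
        for pw in res.pairwise:
            rows.append(
                {
                    "compound": compound,
                    "H": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "group_a": pw.group_a,
                    "group_b": pw.group_b,
                    "mean_rank_difference": pw.mean_rank_difference,
                    "adjusted_p": pw.adjusted_p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["compound", "H", "df", "p_value", "group_a", "group_b",
                 "mean_rank_difference", "adjusted_p"],
    )


def _comparisons_by_class(content_records) -> pd.DataFrame:
    """Mann–Whitney U between capsule and non-capsule cigarettes per compound × part."""
    detected: dict[tuple[str, str], dict[bool, list[float]]] = {}
    for r in content_records:
        if r.part is Part.CAPSULE or r.censored:
            continue
        detected.setdefault((r.compound, r.part.value), {}).setdefault(
            r.has_capsule, []
        ).append(r.content_ug_per_cigarette)
    rows = []
    for (compound, part), groups in sorted(detected.items()):
        if len(groups) < 2:
            continue
        res = mann_whitney(groups[False], groups[True])
        rows.append(
            {
                "compound": compound,
                "part": part,
                "n_non_capsule": len(groups[False]),
                "n_capsule": len(groups[True]),
                "U": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["compound", "part", "n_non_capsule", "n_capsule", "U", "p_value"],
    )


def run_pipeline(
    output_dir,
    seed: int = 0,
    study_config: Optional[SyntheticStudyConfig] = None,
    quant_table_path: Optional[str] = None,
    content_stats_path: Optional[str] = None,
    params: Optional[ExposureParams] = None,
    denominator: Denominator = "detected_cigarettes",
    compounds: Optional[CompoundTable] = None,
) -> dict:
    """Run the full analysis and write the report bundle.

    Input is one of: a synthetic study (default; *study_config*/*seed*), a
    quantification table CSV, or — bypassing raw records — an aggregated
    content table CSV with columns ``compound, stat,
    content_ug_per_cigarette``. Returns the manifest dict.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or ExposureParams()
    compounds = compounds or load_compound_table()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    files: list[Path] = []
    try:
        stage = "input"
        if content_stats_path is not None:
            log.info("stage=input content-table bypass from %s", content_stats_path)
            stats_df = pd.read_csv(content_stats_path)
            triples = list(
                stats_df[["compound", "stat", "content_ug_per_cigarette"]]
                .itertuples(index=False, name=None)
            )
            stage = "risk"
            risk_rows = risk_rows_from_content_stats(triples, params, compounds)
            write_risk_table(risk_rows, out / "risk.csv")
            render_risk_report(risk_rows).to_csv(out / "risk_report.csv", index=False)
            files += [out / "risk.csv", out / "risk_report.csv"]
        else:
            if quant_table_path is not None:
                log.info("stage=input reading %s", quant_table_path)
                records = read_quant_table(quant_table_path, compounds)
            else:
                cfg = study_config or default_study_config(seed)
                log.info(
                    "stage=input generating synthetic study seed=%d "
                    "(%d non-capsule, %d capsule)",
                    seed, cfg.n_noncapsule, cfg.n_capsule,
                )
                df = generate_study(cfg, seed=seed, compounds=compounds)
                df.to_csv(out / "quant_table.csv", index=False)
                files.append(out / "quant_table.csv")
                records = study_records(df, compounds)

            stage = "quantify"
            content = quantify(records, compounds)
            write_content_table(content, out / "content_table.csv")
            files.append(out / "content_table.csv")

            stage = "summarize"
            write_report_table(
                summarize(content, "part"), out / "summary_by_part.csv"
            )
            write_report_table(
                summarize(content, "cigarette_class"),
                out / "summary_by_class.csv",
            )
            files += [out / "summary_by_part.csv", out / "summary_by_class.csv"]

            stage = "compare"
            _comparisons_by_part(content).to_csv(
                out / "comparisons_parts.csv", index=False
            )
            _comparisons_by_class(content).to_csv(
                out / "comparisons_classes.csv", index=False
            )
            files += [out / "comparisons_parts.csv", out / "comparisons_classes.csv"]

            stage = "pca"
            X, ids, names, flags = content_matrix(
                substitute_censored(content, compounds).records
            )
            if X.shape[0] >= 2 and X.shape[1] >= 2:
                pca = pca_scores(X, 2, ids, names)
                pd.DataFrame(
                    {
                        "cigarette_id": ids,
                        "has_capsule": flags,
                        "pc1": pca.scores[:, 0],
                        "pc2": pca.scores[:, 1] if pca.scores.shape[1] > 1 else 0.0,
                    }
                ).to_csv(out / "pca_scores.csv", index=False)
                files.append(out / "pca_scores.csv")

            stage = "risk"
            risk_rows = build_risk_table(content, params, compounds, denominator)
            write_risk_table(risk_rows, out / "risk.csv")
            render_risk_report(risk_rows).to_csv(out / "risk_report.csv", index=False)
            files += [out / "risk.csv", out / "risk_report.csv"]

        stage = "manifest"
        manifest = {
            "package": "flavorisk",
            "version": __version__,
            "seed": seed,
            "denominator": denominator,
            "exposure_params": params.model_dump(),
            "files": {f.name: _sha256(f) for f in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        log.info("pipeline complete: %d files", len(files) + 1)
        return manifest
    except Exception:
        log.error("pipeline failed at stage=%s", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
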