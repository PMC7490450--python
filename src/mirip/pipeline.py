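"""End-to-end analysis: quantify → score → stratify → test → survival.

``run_pipeline`` takes a cohort (CSV path, in-memory table, or a generator
config for a synthetic cohort), applies the scoring and stratification
rules, computes every cohort statistic, and assembles a JSON-serializable
report. All analysis stages are deterministic; randomness enters only
through the generator seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .exceptions import MiripError
from .io import CohortTable, read_cohort_table, write_report
from .scoring import (
    FTO_AKG_LOW,
    ScoringThresholds,
    fto_akg_subgroup,
    score_cohort,
)
from .simulate import GeneratorConfig, generate_cohort
from .stats import (
    KmCurve,
    TestResult,
    km_estimate,
    logrank_test,
    pearson_test,
    student_t_test,
)

logger = logging.getLogger(__name__)

#: Correlations computed against percent-m6A in every report.
CORRELATION_COLUMNS = (
    "mir_exp",
    "fto_level",
    "akg_level",
    "mettl3_level",
    "afm_score",
)


def _test_to_dict(t: TestResult | None, note: str | None = None) -> dict | None:
    if t is None:
        return {"error": note or "not computable"}
    d = {
        "statistic": t.statistic,
        "p_value": t.p_value,
        "df": t.df,
        "n": list(t.n),
    }
    if t.estimate is not None:
        d["estimate"] = t.estimate
    return d


def _km_to_dict(curve: KmCurve) -> dict:
    return {
        "times": list(curve.times),
        "survival": list(curve.survival),
        "at_risk": list(curve.at_risk),
        "n_events": list(curve.n_events),
    }


@dataclass
class AnalysisReport:
    """Everything one pipeline run computed, JSON-serializable.

    Every statistic here is recomputable from ``per_patient`` alone.
    """

    per_patient: list[dict]
    thresholds: dict
    group_summaries: dict
    correlations: dict
    t_tests: dict
    survival: dict
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "per_patient": self.per_patient,
            "thresholds": self.thresholds,
            "group_summaries": self.group_summaries,
            "correlations": self.correlations,
            "t_tests": self.t_tests,
            "survival": self.survival,
            "metadata": self.metadata,
        }


def _group_summary(df: pd.DataFrame, mask: pd.Series) -> dict:
    sub = df[mask]
    out: dict[str, Any] = {"n": int(len(sub))}
    for col in ("xiap_level", "devdase_activity"):
        if len(sub) == 0:
            out[col] = {"mean": None, "sd": None}
        else:
            out[col] = {
                "mean": float(sub[col].mean()),
                "sd": float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0,
            }
    return out


def _config_hash(obj: Mapping | None) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str) if obj else "file-input"
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    cohort_source: str | Path | CohortTable | GeneratorConfig,
    m6a_cutoff: float = 10.0,
) -> AnalysisReport:
    """Run the full analysis and return the assembled report.

    ``cohort_source`` may be a cohort CSV path, an in-memory
    :class:`CohortTable`, or a :class:`GeneratorConfig` (a synthetic cohort
    is drawn first).
    """
    config_dict: dict | None = None
    seed: int | None = None
    if isinstance(cohort_source, GeneratorConfig):
        cohort, _truth = generate_cohort(cohort_source)
        config_dict = cohort_source.to_dict()
        seed = cohort_source.seed
        source_name = "synthetic"
    elif isinstance(cohort_source, CohortTable):
        cohort = cohort_source
        source_name = "in-memory"
    else:
        cohort = read_cohort_table(cohort_source)
        source_name = str(cohort_source)

    logger.info("scoring stage: %d patients, m6A cutoff %.3f%%", len(cohort), m6a_cutoff)
    thresholds = score_cohort(cohort, m6a_cutoff=m6a_cutoff)
    subgroups = fto_akg_subgroup(cohort, thresholds)
    logger.info(
        "thresholds: medians=%s cutoff=%.3f", thresholds.medians, thresholds.m6a_cutoff
    )

    df = cohort.to_frame()
    df["fto_akg_subgroup"] = subgroups

    correlations: dict[str, dict] = {}
    for col in CORRELATION_COLUMNS:
        key = f"pct_m6a_vs_{col}"
        try:
            correlations[key] = _test_to_dict(
                pearson_test(df["pct_m6a"], df[col].astype(float))
            )
        except MiripError as exc:
            correlations[key] = {"error": str(exc)}

    t_tests: dict[str, dict] = {}
    low_mask = df["fto_akg_subgroup"] == FTO_AKG_LOW
    try:
        t_tests["pct_m6a_fto_akg_low_vs_other"] = _test_to_dict(
            student_t_test(df.loc[low_mask, "pct_m6a"], df.loc[~low_mask, "pct_m6a"])
        )
    except MiripError as exc:
        t_tests["pct_m6a_fto_akg_low_vs_other"] = {"error": str(exc)}
    poor_mask = df["signature"] == "poor"
    try:
        t_tests["devdase_poor_vs_standard"] = _test_to_dict(
            student_t_test(
                df.loc[poor_mask, "devdase_activity"],
                df.loc[~poor_mask, "devdase_activity"],
            )
        )
    except MiripError as exc:
        t_tests["devdase_poor_vs_standard"] = {"error": str(exc)}

    group_summaries = {
        str(g): _group_summary(df, df["group"] == g) for g in (1, 2, 3)
    }

    survival: dict[str, Any] = {}
    for label, mask in (("poor", poor_mask), ("standard", ~poor_mask)):
        sub = df[mask]
        if len(sub) == 0:
            survival[f"km_{label}"] = {"times": [], "survival": [],
                                       "at_risk": [], "n_events": []}
        else:
            survival[f"km_{label}"] = _km_to_dict(
                km_estimate(sub["surv_time"], sub["event"])
            )
    try:
        survival["logrank_poor_vs_standard"] = _test_to_dict(
            logrank_test(
                df.loc[poor_mask, "surv_time"], df.loc[poor_mask, "event"],
                df.loc[~poor_mask, "surv_time"], df.loc[~poor_mask, "event"],
            )
        )
    except MiripError as exc:
        survival["logrank_poor_vs_standard"] = {"error": str(exc)}

    per_patient = df.to_dict("records")
    for row in per_patient:
        row["event"] = bool(row["event"])
        row["group"] = int(row["group"])
        row["afm_score"] = int(row["afm_score"])

    metadata = {
        "source": source_name,
        "n_patients": len(cohort),
        "seed": seed,
        "config_hash": _config_hash(config_dict),
        "mirip_version": __version__,
        "multiple_testing_correction": "none (raw p-values, as in source study)",
    }

    return AnalysisReport(
        per_patient=per_patient,
        thresholds={
            "m6a_cutoff": thresholds.m6a_cutoff,
            "medians": dict(thresholds.medians),
        },
        group_summaries=group_summaries,
        correlations=correlations,
        t_tests=t_tests,
        survival=survival,
        metadata=metadata,
    )


def save_report(report: AnalysisReport, report_path: str | Path,
                per_patient_path: str | Path | None = None) -> None:
    """Write the JSON report and, optionally, the per-patient CSV."""
    write_report(report.to_dict(), report_path)
    if per_patient_path is not None:
        pd.DataFrame(report.per_patient).to_csv(per_patient_path, index=False)
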