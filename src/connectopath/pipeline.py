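"""End-to-end orchestration of the three research questions.

Q1: diagnostic group differences (univariate + classification SVM).
Q2: treatment-response prediction (univariate regressions + regression SVM
    + responder / non-responder / control contrasts).
Q3: baseline symptom-severity associations.

Every univariate p is FDR-adjusted within its research-question family
(fixed family sizes m=63 for ADHD-vs-TDC, m=37 for ADHD-only analyses by
default) and reported alongside its q.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome_io import CohortTable, ParcellationAtlas, ValidationError
from .inferential_stats import (
    bh_fdr,
    linear_regression,
    pearson_correlation,
    percent_change,
    responder_flag,
    two_sample_t,
)
from .network_metrics import (
    DEFAULT_THRESHOLDS,
    GraphMetricsResult,
    metrics_to_row,
    sweep_metrics,
)
from .predictive_models import (
    DEFAULT_C_GRID,
    SMALL_C_GRID,
    assemble_features,
    loocv_evaluate,
    summarize_top_regions,
)

logger = logging.getLogger(__name__)

GLOBAL_MEASURES = ("global_efficiency_auc", "char_path_length_auc", "mean_clustering_auc")


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    normalize: bool = True
    path_mode: str = "weighted"
    fdr_family_diagnostic: int = 63
    fdr_family_adhd_only: int = 37
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    permutation_c_grid: tuple[float, ...] = SMALL_C_GRID
    permutations: int = 200
    tuning_metric: str = "auto"
    include_covariates: bool = True
    responder_threshold_pct: float = 25.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("thresholds", "c_grid", "permutation_c_grid"):
            if key in raw:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["c_grid"] = list(self.c_grid)
        d["permutation_c_grid"] = list(self.permutation_c_grid)
        return d


def compute_all_metrics(
    cohort: CohortTable, config: RunConfig
) -> dict[str, GraphMetricsResult]:
    """Run the sparsity sweep for every subject in the cohort."""
    out = {}
    for s in cohort.subjects:
        out[s.subject_id] = sweep_metrics(
            cohort.matrices[s.subject_id],
            thresholds=config.thresholds,
            normalize=config.normalize,
            path_mode=config.path_mode,
        )
    return out


def metrics_table(metrics: dict[str, GraphMetricsResult]) -> pd.DataFrame:
    return pd.DataFrame([metrics_to_row(r) for r in metrics.values()])


def _measure_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.endswith("_auc")]


def _attach_q(results: list, m: int) -> None:
    qs = bh_fdr([r.p for r in results], m=max(m, len(results)))
    for r, q in zip(results, qs):
        r.q = float(q)


# ---------------------------------------------------------------------------
# Research questions
# ---------------------------------------------------------------------------


def run_question1(
    cohort: CohortTable,
    metrics: dict[str, GraphMetricsResult],
    atlas: ParcellationAtlas,
    config: RunConfig,
) -> dict:
    """Diagnostic group comparison: univariate tests + classification SVM."""
    adhd = cohort.group("ADHD")
    tdc = cohort.group("TDC")
    if not adhd or not tdc:
        raise ValidationError("both diagnostic groups are required for question 1")
    df = metrics_table(metrics).set_index("subject_id")
    adhd_ids = [s.subject_id for s in adhd]
    tdc_ids = [s.subject_id for s in tdc]
    results = []
    for col in _measure_columns(df):
        results.append(
            two_sample_t(
                df.loc[adhd_ids, col].to_numpy(),
                df.loc[tdc_ids, col].to_numpy(),
                name=col,
            )
        )
    _attach_q(results, config.fdr_family_diagnostic)

    evaluations = {}
    for label, use_cov in (("local_efficiency", False), ("local_efficiency_covariates", True)):
        if use_cov and not config.include_covariates:
            continue
        table = assemble_features(metrics, cohort, task="diagnosis", include_covariates=use_cov)
        ev = loocv_evaluate(
            table,
            C_grid=config.c_grid,
            tuning_metric=config.tuning_metric,
            permutations=config.permutations,
            seed=config.seed,
            permutation_C_grid=config.permutation_c_grid,
        )
        k = min(10, sum(e["feature"].startswith("leff_") for e in ev.importance))
        evaluations[label] = {
            "evaluation": ev.to_dict(),
            "top_regions": summarize_top_regions(ev.importance, atlas, k=k),
        }
    return {
        "question": "diagnostic_group_differences",
        "n_adhd": len(adhd),
        "n_tdc": len(tdc),
        "univariate": [r.to_dict() for r in results],
        "fdr_family_size": config.fdr_family_diagnostic,
        "svm": evaluations,
    }


def run_question2(
    cohort: CohortTable,
    metrics: dict[str, GraphMetricsResult],
    atlas: ParcellationAtlas,
    config: RunConfig,
) -> dict:
    """Treatment-response prediction from baseline topology."""
    treated = cohort.treatment_subjects()
    if len(treated) < 5:
        raise ValidationError("too few ADHD subjects with week-6 outcomes")
    df = metrics_table(metrics).set_index("subject_id")
    ids = [s.subject_id for s in treated]
    changes = {
        "total": [percent_change(s.adhdrs_total_w0, s.adhdrs_total_w6) for s in treated],
        "inattention": [
            percent_change(max(s.adhdrs_inatt_w0, 1), s.adhdrs_inatt_w6) for s in treated
        ],
        "hyperactivity": [
            percent_change(max(s.adhdrs_hyper_w0, 1), s.adhdrs_hyper_w6) for s in treated
        ],
    }
    cov = pd.DataFrame(
        {
            "age": [s.age for s in treated],
            "gender": [s.gender for s in treated],
            "mph_dose_mg_per_kg": [s.mph_dose_mg_per_kg for s in treated],
            "adhd_subtype": [s.adhd_subtype for s in treated],
            "prior_stimulant_6mo": [s.prior_stimulant_6mo for s in treated],
            "prior_stimulant_duration": [s.prior_stimulant_duration for s in treated],
        }
    )
    regressions = {}
    for outcome_name, y in changes.items():
        plain = []
        for col in _measure_columns(df):
            x = df.loc[ids, col].to_numpy()
            try:
                plain.append(linear_regression(y, x, name=col))
            except ValidationError:
                continue
        _attach_q(plain, config.fdr_family_adhd_only)
        entry = {"unadjusted": [r.to_dict() for r in plain]}
        if config.include_covariates:
            adjusted = []
            for col in _measure_columns(df):
                x = df.loc[ids, col].to_numpy()
                try:
                    adjusted.append(linear_regression(y, x, covariates=cov, name=col))
                except ValidationError:
                    continue
            _attach_q(adjusted, config.fdr_family_adhd_only)
            entry["covariate_adjusted"] = [r.to_dict() for r in adjusted]
        regressions[outcome_name] = entry

    svm = {}
    for label, use_cov in (("local_efficiency", False), ("local_efficiency_covariates", True)):
        if use_cov and not config.include_covariates:
            continue
        table = assemble_features(metrics, cohort, task="response", include_covariates=use_cov)
        ev = loocv_evaluate(
            table,
            C_grid=config.c_grid,
            tuning_metric=config.tuning_metric,
            permutations=config.permutations,
            seed=config.seed,
            permutation_C_grid=config.permutation_c_grid,
        )
        k = min(10, sum(e["feature"].startswith("leff_") for e in ev.importance))
        svm[label] = {
            "evaluation": ev.to_dict(),
            "top_regions": summarize_top_regions(ev.importance, atlas, k=k),
        }

    responder_section = _responder_contrasts(cohort, df, config)
    return {
        "question": "treatment_response_prediction",
        "n_treated": len(treated),
        "regressions": regressions,
        "fdr_family_size": config.fdr_family_adhd_only,
        "svm": svm,
        "responder_contrasts": responder_section,
    }


def _responder_contrasts(
    cohort: CohortTable, df: pd.DataFrame, config: RunConfig
) -> dict:
    """Responders vs non-responders vs TDC on global efficiency."""
    responders, non_responders = [], []
    for s in cohort.treatment_subjects():
        pct = percent_change(s.adhdrs_total_w0, s.adhdrs_total_w6)
        (responders if pct < -config.responder_threshold_pct else non_responders).append(
            s.subject_id
        )
    tdc_ids = [s.subject_id for s in cohort.group("TDC")]
    out = {
        "n_responders": len(responders),
        "n_non_responders": len(non_responders),
        "n_tdc": len(tdc_ids),
        "contrasts": {},
    }
    col = "global_efficiency_auc"
    pairs = {
        "responder_vs_tdc": (responders, tdc_ids),
        "non_responder_vs_tdc": (non_responders, tdc_ids),
        "responder_vs_non_responder": (responders, non_responders),
    }
    for name, (a, b) in pairs.items():
        if len(a) >= 2 and len(b) >= 2:
            out["contrasts"][name] = two_sample_t(
                df.loc[a, col].to_numpy(), df.loc[b, col].to_numpy(), name=f"{name}:{col}"
            ).to_dict()
    return out


def run_question3(
    cohort: CohortTable,
    metrics: dict[str, GraphMetricsResult],
    atlas: ParcellationAtlas,
    config: RunConfig,
) -> dict:
    """Baseline symptom severity vs graph measures (ADHD group only)."""
    adhd = cohort.group("ADHD")
    if len(adhd) < 3:
        raise ValidationError("too few ADHD subjects for severity correlations")
    df = metrics_table(metrics).set_index("subject_id")
    ids = [s.subject_id for s in adhd]
    severities = {
        "total": [float(s.adhdrs_total_w0) for s in adhd],
        "inattention": [float(s.adhdrs_inatt_w0) for s in adhd],
        "hyperactivity": [float(s.adhdrs_hyper_w0) for s in adhd],
    }
    out = {}
    for name, y in severities.items():
        results = []
        for col in _measure_columns(df):
            x = df.loc[ids, col].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            results.append(pearson_correlation(x, y, name=col))
        _attach_q(results, config.fdr_family_adhd_only)
        out[name] = [r.to_dict() for r in results]
    return {
        "question": "baseline_severity_associations",
        "n_adhd": len(adhd),
        "correlations": out,
        "fdr_family_size": config.fdr_family_adhd_only,
    }


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_TABLE_ROWS = (
    ("Cost", lambda ev: ev["evaluation"]["tuned_cost"]),
    ("Accuracy %", lambda ev: ev["evaluation"]["accuracy_stats"]["accuracy_pct"]),
    ("CI 95% (lower, upper)", lambda ev: tuple(ev["evaluation"]["accuracy_stats"]["ci95_pct"])),
    ("Accuracy null %", lambda ev: ev["evaluation"]["accuracy_stats"]["nir_pct"]),
    ("Sensitivity", lambda ev: ev["evaluation"]["accuracy_stats"]["sensitivity"]),
    ("Specificity", lambda ev: ev["evaluation"]["accuracy_stats"]["specificity"]),
    ("PPV", lambda ev: ev["evaluation"]["accuracy_stats"]["ppv"]),
    ("NPV", lambda ev: ev["evaluation"]["accuracy_stats"]["npv"]),
    ("p value", lambda ev: ev["evaluation"]["accuracy_stats"]["p_vs_nir"]),
    ("Permutation p value", lambda ev: ev["evaluation"]["permutation_p"]),
)


def _fmt(v) -> str:
    if v is None:
        return "-"
    if isinstance(v, tuple):
        return "(" + ", ".join(f"{x:.1f}" for x in v) + ")"
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def render_report(
    sections: dict[str, dict], out_dir: str | Path, config: RunConfig
) -> tuple[Path, Path]:
    """Write report.json + report.md; returns both paths."""
    if not sections:
        raise ValidationError("at least one completed section is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "software_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "sections": sections,
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))

    lines = ["# Structural connectome analysis report", ""]
    lines.append(f"software version: {__version__}; seed: {config.seed}")
    lines.append("")
    for key, section in sections.items():
        lines.append(f"## {section.get('question', key)}")
        lines.append("")
        svm = section.get("svm", {})
        class_models = {
            lbl: ev
            for lbl, ev in svm.items()
            if ev["evaluation"].get("accuracy_stats")
        }
        if class_models:
            labels = list(class_models)
            lines.append("| Performance measure | " + " | ".join(labels) + " |")
            lines.append("|---" * (len(labels) + 1) + "|")
            for row_name, getter in _TABLE_ROWS:
                cells = [_fmt(getter(class_models[lbl])) for lbl in labels]
                lines.append(f"| {row_name} | " + " | ".join(cells) + " |")
            lines.append("")
        for lbl, ev in svm.items():
            if ev["evaluation"].get("obs_pred_r") is not None:
                lines.append(
                    f"- {lbl}: observed-vs-predicted r = "
                    f"{_fmt(ev['evaluation']['obs_pred_r'])}, "
                    f"p = {_fmt(ev['evaluation']['obs_pred_p'])}, "
                    f"permutation p = {_fmt(ev['evaluation']['permutation_p'])}"
                )
        for lbl, ev in svm.items():
            top = ev.get("top_regions", {})
            if top:
                regions = ", ".join(t["region"] for t in top["top_regions"])
                lines.append(f"- {lbl} top-10 regions: {regions}")
                lines.append(
                    f"  (fraction subcortical: {top['fraction_subcortical']:.2f})"
                )
        uni = section.get("univariate")
        if uni:
            sig = [u for u in uni if u["q"] < 0.05]
            lines.append(
                f"- univariate tests: {len(uni)} run, {len(sig)} with q < 0.05 "
                f"(family size {section['fdr_family_size']})"
            )
        lines.append("")
    md_path = out_dir / "report.md"
    md_path.write_text("\n".join(lines))
    (out_dir / "resolved_config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True)
    )
    return json_path, md_path


def run_full_analysis(
    cohort: CohortTable,
    atlas: ParcellationAtlas,
    config: RunConfig,
    out_dir: Optional[str | Path] = None,
    questions: Sequence[int] = (1, 2, 3),
) -> dict:
    """Compute metrics once and run the requested research questions."""
    metrics = compute_all_metrics(cohort, config)
    sections = {}
    if 1 in questions:
        sections["q1"] = run_question1(cohort, metrics, atlas, config)
    if 2 in questions:
        sections["q2"] = run_question2(cohort, metrics, atlas, config)
    if 3 in questions:
        sections["q3"] = run_question3(cohort, metrics, atlas, config)
    if out_dir is not None:
        render_report(sections, out_dir, config)
    return sections
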