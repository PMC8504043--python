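"""End-to-end orchestration: assess → score → compare → model → patterns.

:func:`run_pipeline` reproduces the study's analysis plan on any input pair
of ``patients.csv`` / ``prescriptions.csv``: cohort description, criterion
assessment, fulfilment scores with the boundary transformation, univariate
pre/post comparisons (Mann–Whitney for scores, chi-squared per criterion),
the beta GLMM with patient random intercepts, odds ratios with the derived
reference-ward effect, net interventional effects, the E-value for the
intervention estimate, and ward-level change patterns.  The report is a
plain dict (JSON-serialisable) carrying provenance: seeds, config hash,
ruleset version and package versions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .criteria import (
    DEFAULT_RULESET_VERSION,
    assess_cohort,
    count_not_applicable,
    default_ruleset,
)
from .glmm import (
    ModelSpec,
    evalue,
    fit,
    net_interventional_effect,
    odds_ratios,
)
from .patterns import (
    DEFAULT_FLAT_TOLERANCE,
    DEFAULT_SAME_TOLERANCE,
    classify_all_criteria,
)
from .prescriptions import (
    PatientRecord,
    Prescription,
    TimePoint,
    categorize_prescription,
    summarize_cohort,
)
from .scoring import (
    compare_criterion,
    compare_fscores,
    criterion_summaries,
    prescription_fscore,
    round_percent,
    transform_to_open_interval,
)

__all__ = ["PipelineConfig", "run_pipeline", "score_table", "observation_table"]


@dataclass
class PipelineConfig:
    ruleset_version: str = DEFAULT_RULESET_VERSION
    chi2_continuity_correction: bool = False
    pattern_tolerance: float = DEFAULT_SAME_TOLERANCE
    pattern_flat_tolerance: float = DEFAULT_FLAT_TOLERANCE
    model: ModelSpec = field(default_factory=ModelSpec)
    fit_model: bool = True
    seed: int | None = None

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        model = ModelSpec.from_dict(raw.pop("model", {}))
        return cls(model=model, **raw)


def score_table(
    prescriptions: Sequence[Prescription],
    results,
    n_total: int | None = None,
) -> pd.DataFrame:
    """Per-prescription met/applicable counts, fscore and transformed fscore."""
    n_total = n_total if n_total is not None else len(results)
    rows = []
    for p, r in zip(prescriptions, results):
        s = prescription_fscore(r)
        rows.append({
            "prescription_id": p.prescription_id,
            "patient_id": p.patient_id,
            "met": s.met,
            "applicable": s.applicable,
            "fscore": s.value,
            "transformed_fscore": transform_to_open_interval(s.value, n_total),
        })
    return pd.DataFrame(rows)


def observation_table(
    patients: Sequence[PatientRecord],
    prescriptions: Sequence[Prescription],
    scores: pd.DataFrame,
) -> pd.DataFrame:
    """Model-ready observation table (one row per prescription)."""
    pat = {p.patient_id: p for p in patients}
    rows = []
    for p, (_, srow) in zip(prescriptions, scores.iterrows()):
        patient = pat[p.patient_id]
        rows.append({
            "y": srow["transformed_fscore"],
            "patient_id": p.patient_id,
            "ward_id": patient.ward_id,
            "time_point": patient.time_point.value,
            "category": categorize_prescription(p).value,
            "n_comedications": patient.n_comedications,
        })
    return pd.DataFrame(rows)


def _cohort_block(summary) -> dict:
    return {
        "n_patients": summary.n_patients,
        "total_prescriptions": summary.total_prescriptions,
        "mean_prescriptions_per_patient": summary.mean_prescriptions_per_patient,
        "sd_prescriptions_per_patient": summary.sd_prescriptions_per_patient,
        "counts_by_category": {c.value: n for c, n in summary.counts_by_category.items()},
        "percent_by_category": {
            c.value: round_percent(n / summary.total_prescriptions)
            for c, n in summary.counts_by_category.items()
        },
    }


def _mw_block(res) -> dict:
    return {
        "u_statistic": res.u_statistic,
        "z": res.z,
        "p_value": res.p_value,
        "effect_size_r": res.effect_size_r,
        "pre_mean_percent": round_percent(res.mean_a),
        "pre_sd_percent": round_percent(res.sd_a),
        "post_mean_percent": round_percent(res.mean_b),
        "post_sd_percent": round_percent(res.sd_b),
        "n_pre": res.n_a,
        "n_post": res.n_b,
    }


def run_pipeline(
    patients: Sequence[PatientRecord],
    prescriptions: Sequence[Prescription],
    config: PipelineConfig | None = None,
) -> dict:
    """Execute the full analysis and return the report dict."""
    config = config or PipelineConfig()
    if not prescriptions:
        raise ValueError("no prescriptions supplied")
    if not patients:
        raise ValueError("no patients supplied")

    pre_pat = [p for p in patients if p.time_point is TimePoint.PRE]
    post_pat = [p for p in patients if p.time_point is TimePoint.POST]
    pat_index = {p.patient_id: p for p in patients}
    pre_rx = [p for p in prescriptions if pat_index[p.patient_id].time_point is TimePoint.PRE]
    post_rx = [p for p in prescriptions if pat_index[p.patient_id].time_point is TimePoint.POST]

    report: dict = {
        "provenance": {
            "rxqual_version": __version__,
            "ruleset_version": config.ruleset_version,
            "seed": config.seed,
            "n_patients": len(patients),
            "n_prescriptions": len(prescriptions),
        }
    }

    report["cohorts"] = {}
    if pre_pat:
        report["cohorts"]["pre"] = _cohort_block(summarize_cohort(pre_pat, pre_rx))
    if post_pat:
        report["cohorts"]["post"] = _cohort_block(summarize_cohort(post_pat, post_rx))

    rules = default_ruleset()
    results = assess_cohort(prescriptions, patients, rules, config.ruleset_version)
    na_mean, na_sd = count_not_applicable(results)
    report["not_applicable_per_prescription"] = {"mean": na_mean, "sd": na_sd}

    n_total = len(prescriptions)
    scores = score_table(prescriptions, results, n_total)
    obs = observation_table(patients, prescriptions, scores)

    # univariate comparisons, overall and per category
    pre_mask = obs["time_point"] == "pre"
    fsc = scores["fscore"].to_numpy()
    comparisons = {}
    if pre_mask.any() and (~pre_mask).any():
        comparisons["all"] = _mw_block(
            compare_fscores(fsc[pre_mask.to_numpy()], fsc[~pre_mask.to_numpy()])
        )
        for cat in obs["category"].unique():
            m = (obs["category"] == cat).to_numpy()
            a = fsc[m & pre_mask.to_numpy()]
            b = fsc[m & ~pre_mask.to_numpy()]
            if a.size and b.size:
                comparisons[cat] = _mw_block(compare_fscores(a, b))
    report["fscore_comparisons"] = comparisons

    # criterion-level table
    res_by_id = dict(zip([r.prescription_id for r in results], results))
    pre_results = [res_by_id[p.prescription_id] for p in pre_rx]
    post_results = [res_by_id[p.prescription_id] for p in post_rx]
    pre_sum = {s.criterion: s for s in criterion_summaries(pre_results, "pre")}
    post_sum = {s.criterion: s for s in criterion_summaries(post_results, "post")}
    patterns = classify_all_criteria(
        results, prescriptions, patients,
        config.pattern_tolerance, config.pattern_flat_tolerance,
    )
    criteria_rows = []
    for c in range(1, 21):
        row: dict = {"criterion": c}
        if c in pre_sum:
            row["pre"] = {
                "met": pre_sum[c].met, "applicable": pre_sum[c].applicable,
                "criteria_fscore_percent": round_percent(pre_sum[c].criteria_fscore),
            }
        if c in post_sum:
            row["post"] = {
                "met": post_sum[c].met, "applicable": post_sum[c].applicable,
                "criteria_fscore_percent": round_percent(post_sum[c].criteria_fscore),
            }
        if c in pre_sum and c in post_sum:
            test = compare_criterion(
                pre_sum[c].met, pre_sum[c].applicable,
                post_sum[c].met, post_sum[c].applicable,
                continuity_correction=config.chi2_continuity_correction,
            )
            row["chi2"] = {"statistic": test.statistic, "p_value": test.p_value,
                           "degenerate": test.degenerate}
        pattern, trajectories = patterns[c]
        if pattern is not None:
            row["change_pattern"] = pattern.name
            row["ward_trajectories"] = [
                {"ward_id": t.ward_id,
                 "fscore_pre_percent": round_percent(t.fscore_pre),
                 "fscore_post_percent": round_percent(t.fscore_post)}
                for t in trajectories
            ]
        criteria_rows.append(row)
    report["criteria"] = criteria_rows

    # multivariable model
    if config.fit_model and pre_mask.any() and (~pre_mask).any():
        fit_result = fit(obs, config.model)
        ors = odds_ratios(fit_result)
        report["model"] = {
            "converged": fit_result.converged,
            "loglik": fit_result.loglik,
            "sigma_b": fit_result.sigma_b,
            "sigma_b_ci": list(fit_result.sigma_b_ci),
            "phi": fit_result.phi,
            "n_obs": fit_result.n_obs,
            "n_patients": fit_result.design.n_patients,
            "reference_ward": fit_result.design.reference_ward,
            "effects": [
                {"term": e.term, "odds_ratio": e.odds_ratio,
                 "ci_low": e.ci_low, "ci_high": e.ci_high, "p_value": e.p}
                for e in ors
            ],
        }
        or_time = next(e.odds_ratio for e in ors if e.term == "time_post")
        report["model"]["evalue_time_post"] = evalue(or_time)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report["model"]["net_interventional_effect_percent"] = {
                k: v for k, v in net_interventional_effect(fit_result, obs).items()
            }
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Serialise the report as JSON plus a short human-readable text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    rows = []
    for row in report.get("criteria", []):
        for cohort in ("pre", "post"):
            if cohort in row:
                rows.append({
                    "criterion": row["criterion"],
                    "cohort": cohort,
                    "met": row[cohort]["met"],
                    "applicable": row[cohort]["applicable"],
                    "criteria_fscore_percent": row[cohort]["criteria_fscore_percent"],
                    "comparison_p": row.get("chi2", {}).get("p_value", ""),
                    "change_pattern": row.get("change_pattern", ""),
                })
    if rows:
        pd.DataFrame(rows).to_csv(out / "criteria_summary.csv", index=False)
    lines = ["rxqual analysis report", "======================"]
    for tp, block in report.get("cohorts", {}).items():
        lines.append(
            f"{tp}: {block['n_patients']} patients, "
            f"{block['total_prescriptions']} prescriptions "
            f"(mean {block['mean_prescriptions_per_patient']:.1f} per patient)"
        )
    if "all" in report.get("fscore_comparisons", {}):
        c = report["fscore_comparisons"]["all"]
        lines.append(
            f"prescription-Fscore: {c['pre_mean_percent']}% -> "
            f"{c['post_mean_percent']}% (p={c['p_value']:.3g}, r={c['effect_size_r']:.2f})"
        )
    if "model" in report:
        m = report["model"]
        t = next(e for e in m["effects"] if e["term"] == "time_post")
        lines.append(
            f"GLMM time-point OR {t['odds_ratio']:.2f} "
            f"[{t['ci_low']:.2f}; {t['ci_high']:.2f}], sigma_b={m['sigma_b']:.3f}, "
            f"E-value {m['evalue_time_post']:.1f}"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialise {type(o)}")
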