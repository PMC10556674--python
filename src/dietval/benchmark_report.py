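"""Nine-step validity benchmark for a dietary-assessment tool.

The benchmark standardises how a new intake instrument is reported against
a reference expenditure method: (1) Bland–Altman agreement, (2) Pearson
correlation between methods, (3) absolute and percentage measurement
differences, (4) over/under-estimation split, (5) Goldberg cut-off
classification of misreporters, (6) correlation of intake with body
composition (FM and FFM), (7) correlation of energy-store changes with the
measurement differences, (8) correlation of expenditure with the
measurement differences, and (9) the intraclass correlation of daily
intake as a diet-stability index.

``run_benchmark`` delegates each step to the statistics modules and never
re-rounds: report numbers equal the module outputs bit-for-bit, and display
rounding happens only at render time.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import agreement_stats as ag
from . import energy_goldberg as eg
from . import intake_metrics as im
from .cohort_io import (Participant, Recall24Record, StudyConfig,
                        report_to_jsonable)
from .dlw_engine import TwoPointResult
from .errors import DomainError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["CohortBundle", "BenchmarkReport", "SkippedStep",
           "bundle_from_inputs", "run_benchmark", "render_report"]


@dataclass
class CohortBundle:
    """Everything the benchmark consumes, aligned by participant id."""

    participants: list[Participant]
    app_series: Mapping[str, im.IntakeSeries]
    recalls: list[Recall24Record]
    tdee_kcal: Mapping[str, float]
    fm_kg: Mapping[str, float] | None = None
    ffm_kg: Mapping[str, float] | None = None
    d_fm_kg: Mapping[str, float] | None = None
    d_ffm_kg: Mapping[str, float] | None = None
    study_days: float = 7.0

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.participants]


def bundle_from_inputs(
    participants: list[Participant],
    occasions,
    recalls: list[Recall24Record],
    dlw_results: list[TwoPointResult],
    weight_by_id: Mapping[str, float] | None = None,
) -> CohortBundle:
    """Assemble a benchmark bundle from raw tables and DLW engine output."""
    daily = im.aggregate_daily(occasions)
    series = im.build_series(daily)
    tdee = {r.participant_id: r.tdee_kcal for r in dlw_results}
    fm = {r.participant_id: r.body_composition.fm_kg for r in dlw_results}
    ffm = {r.participant_id: r.body_composition.ffm_kg for r in dlw_results}
    return CohortBundle(participants=participants, app_series=series,
                        recalls=recalls, tdee_kcal=tdee, fm_kg=fm, ffm_kg=ffm)


@dataclass
class SkippedStep:
    skipped: bool
    reason: str


@dataclass
class BenchmarkReport:
    step1_bland_altman: dict[str, Any]
    step2_correlation: dict[str, Any]
    step3_differences: dict[str, Any]
    step4_over_under: dict[str, Any]
    step5_goldberg: dict[str, Any]
    step6_body_composition_correlations: dict[str, Any]
    step7_energy_stores: dict[str, Any]
    step8_expenditure: dict[str, Any]
    step9_icc: Any
    provenance: dict[str, Any] = field(default_factory=dict)


def _pairs(ids, a, b, label_a, label_b) -> ag.PairedEstimates:
    return ag.PairedEstimates(participant_ids=list(ids),
                              value_a=np.asarray(a, dtype=float),
                              value_b=np.asarray(b, dtype=float),
                              label_a=label_a, label_b=label_b)


def _skip(reason: str) -> SkippedStep:
    logger.warning("benchmark step skipped: %s", reason)
    return SkippedStep(skipped=True, reason=reason)


def run_benchmark(bundle: CohortBundle, config: StudyConfig | None = None
                  ) -> BenchmarkReport:
    """Execute the nine benchmark steps over the bundle.

    Tool comparisons are app vs reference, recall vs reference, and app vs
    recall; all correlation and paired-test p-values carry the configured
    Bonferroni factor.  A missing input block marks the dependent steps
    skipped with a reason and the run continues.
    """
    cfg = config or StudyConfig()
    ids = bundle.ids
    missing_tdee = [i for i in ids if i not in bundle.tdee_kcal]
    if missing_tdee:
        raise ValidationError(f"TDEE missing for participants: {missing_tdee}")
    missing_app = [i for i in ids if i not in bundle.app_series]
    if missing_app:
        raise ValidationError(f"app intake missing for participants: {missing_app}")

    recall_by_id = {r.participant_id: r for r in bundle.recalls}
    app = np.array([bundle.app_series[i].mean_tdei for i in ids])
    tdee = np.array([bundle.tdee_kcal[i] for i in ids])
    have_recall = all(i in recall_by_id for i in ids)
    recall = (np.array([recall_by_id[i].tdei_kcal for i in ids])
              if have_recall else None)

    comparisons: dict[str, ag.PairedEstimates] = {
        "app_vs_dlw": _pairs(ids, app, tdee, "app", "dlw"),
    }
    if recall is not None:
        comparisons["recall_vs_dlw"] = _pairs(ids, recall, tdee, "recall", "dlw")
        comparisons["app_vs_recall"] = _pairs(ids, app, recall, "app", "recall")
    else:
        logger.warning("24HR records incomplete; recall comparisons skipped")

    bf = cfg.bonferroni_factor

    step1 = {k: ag.bland_altman(p, alpha=cfg.alpha) for k, p in comparisons.items()}
    step2 = {k: ag.pearson(p, bonferroni_factor=bf) for k, p in comparisons.items()}
    step3 = {}
    for k, p in comparisons.items():
        d = p.differences
        pct = 100.0 * d / p.value_b
        step3[k] = {
            "mean_difference_kcal": float(np.mean(d)),
            "sd_difference_kcal": float(np.std(d, ddof=1)),
            "mean_percentage_difference": float(np.mean(pct)),
            "sd_percentage_difference": float(np.std(pct, ddof=1)),
            "paired_test": ag.paired_difference_test(p, cfg.alpha, bf),
        }
    step4 = {k: ag.over_under_summary(p) for k, p in comparisons.items()
             if k.endswith("_vs_dlw")}

    # step 5: Goldberg classification per tool, study-specific S by default
    bmr = {p.id: eg.bmr_mifflin(p.weight_start_kg, p.height_cm, p.age_y, p.sex)
           for p in bundle.participants}
    bmr_v = np.array([bmr[i] for i in ids])
    pal_i = tdee / bmr_v
    cv_tp = 100.0 * float(np.std(pal_i, ddof=1)) / float(np.mean(pal_i))
    cv_wtdei = im.pooled_cv([bundle.app_series[i].cv_i for i in ids])
    gcfg = cfg.goldberg
    if gcfg.cv_wtdei is None or gcfg.cv_tp is None:
        gcfg = dataclasses.replace(gcfg,
                                   cv_wtdei=gcfg.cv_wtdei or cv_wtdei,
                                   cv_tp=gcfg.cv_tp or cv_tp)
    step5 = {
        "cv_wtdei_study": cv_wtdei,
        "cv_tp_study": cv_tp,
        "d_days": gcfg.d_days,
        "app": eg.classify_cohort(app, bmr_v, tdee, gcfg),
    }
    if recall is not None:
        step5["recall"] = eg.classify_cohort(recall, bmr_v, tdee, gcfg)

    # step 6: intake vs body composition
    if bundle.fm_kg is None or bundle.ffm_kg is None:
        step6: Any = _skip("body composition (FM/FFM) not provided")
        have_comp = False
    else:
        fm = np.array([bundle.fm_kg[i] for i in ids])
        ffm = np.array([bundle.ffm_kg[i] for i in ids])
        step6 = {"app_vs_fm": ag.pearson(_pairs(ids, app, fm, "app", "fm"), bf),
                 "app_vs_ffm": ag.pearson(_pairs(ids, app, ffm, "app", "ffm"), bf)}
        if recall is not None:
            step6["recall_vs_fm"] = ag.pearson(_pairs(ids, recall, fm, "recall", "fm"), bf)
            step6["recall_vs_ffm"] = ag.pearson(_pairs(ids, recall, ffm, "recall", "ffm"), bf)
        have_comp = True

    # step 7: energy-store change vs measurement differences; falls back to
    # raw body-weight change when FM/FFM changes are unavailable
    if bundle.d_fm_kg is not None and bundle.d_ffm_kg is not None:
        es = np.array([eg.delta_energy_stores(bundle.d_fm_kg[i],
                                              bundle.d_ffm_kg[i],
                                              bundle.study_days) for i in ids])
        es_label, fallback = "delta_energy_stores_kcal_per_day", False
    else:
        es = np.array([p.weight_change_kg for p in bundle.participants])
        es_label, fallback = "weight_change_kg", True
    step7 = {"basis": es_label, "fallback_to_weight_change": fallback}
    if float(np.std(es)) == 0:
        step7["correlations"] = _skip("no variation in energy-store change")
    else:
        step7["correlations"] = {
            k: ag.pearson(_pairs(ids, es, p.differences, es_label, f"diff_{k}"), bf)
            for k, p in comparisons.items() if k.endswith("_vs_dlw")
        }

    # step 8: expenditure vs measurement differences
    step8 = {
        k: ag.pearson(_pairs(ids, tdee, p.differences, "tdee", f"diff_{k}"), bf)
        for k, p in comparisons.items() if k.endswith("_vs_dlw")
    }

    # step 9: diet stability over the week
    daily = pd.DataFrame(
        [(i, v) for i in ids for v in bundle.app_series[i].daily_tdei],
        columns=["participant_id", "value"])
    step9 = ag.icc_random_intercept(daily, alpha=cfg.alpha)

    provenance = {
        "n_participants": len(ids),
        "config": report_to_jsonable(cfg),
        "seed": cfg.seed,
        "goldberg_d_days": gcfg.d_days,
        "bonferroni_factor": bf,
    }
    return BenchmarkReport(
        step1_bland_altman=step1, step2_correlation=step2,
        step3_differences=step3, step4_over_under=step4, step5_goldberg=step5,
        step6_body_composition_correlations=step6, step7_energy_stores=step7,
        step8_expenditure=step8, step9_icc=step9, provenance=provenance,
    )


# ---------------------------------------------------------------------------
# rendering

def _fmt(x: Any, nd: int = 1) -> str:
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def _ba_table(step1: dict[str, ag.BlandAltmanResult]) -> list[str]:
    lines = ["| comparison | bias | lCI bias | uCI bias | SD | SE bias | lLoA | uLoA | SE LoA |",
             "|---|---|---|---|---|---|---|---|---|"]
    for name, r in step1.items():
        lines.append(
            f"| {name} | {_fmt(r.bias)} | {_fmt(r.bias_ci[0])} | {_fmt(r.bias_ci[1])} "
            f"| {_fmt(r.sd_diff)} | {_fmt(r.se_bias)} | {_fmt(r.loa[0])} "
            f"| {_fmt(r.loa[1])} | {_fmt(r.se_loa)} |")
    return lines


def render_report(report: BenchmarkReport, format: str = "json") -> str:
    """Serialize the report: deterministic JSON or a markdown summary."""
    if format == "json":
        import json
        return json.dumps(report_to_jsonable(report), indent=2, sort_keys=True)
    if format != "markdown":
        raise DomainError(f"unknown report format {format!r}")

    lines = ["# Validity benchmark report", ""]
    lines.append("## Step 1 — Bland–Altman agreement")
    lines.extend(_ba_table(report.step1_bland_altman))
    lines.append("")
    lines.append("## Step 2 — Pearson correlation between methods")
    lines.append("| comparison | r | r² | p (adj) |")
    lines.append("|---|---|---|---|")
    for name, r in report.step2_correlation.items():
        lines.append(f"| {name} | {r.r:.3f} | {r.r_squared:.3f} | {r.p_adj:.3g} |")
    lines.append("")
    lines.append("## Step 3 — Measurement differences")
    lines.append("| comparison | Δ kcal/day (SD) | MPD % (SD) | test | p (adj) |")
    lines.append("|---|---|---|---|---|")
    for name, d in report.step3_differences.items():
        t = d["paired_test"]
        p_adj = "—" if t.p_adj is None else f"{t.p_adj:.3g}"
        lines.append(
            f"| {name} | {_fmt(d['mean_difference_kcal'])} ({_fmt(d['sd_difference_kcal'])}) "
            f"| {_fmt(d['mean_percentage_difference'])} ({_fmt(d['sd_percentage_difference'])}) "
            f"| {t.test_used} | {p_adj} |")
    lines.append("")
    lines.append("## Step 4 — Over- and underestimation")
    lines.append("| comparison | n over | n under | MPD over | MPD under |")
    lines.append("|---|---|---|---|---|")
    for name, s in report.step4_over_under.items():
        lines.append(
            f"| {name} | {s.n_over} | {s.n_under} "
            f"| {_fmt(s.mpd_over) if s.mpd_over is not None else '—'} "
            f"| {_fmt(s.mpd_under) if s.mpd_under is not None else '—'} |")
    lines.append("")
    lines.append("## Step 5 — Goldberg cut-off classification")
    g = report.step5_goldberg
    lines.append(f"CVwTDEI (study) {_fmt(g['cv_wtdei_study'], 2)}%, "
                 f"CVtP (study) {_fmt(g['cv_tp_study'], 2)}%, d = {g['d_days']} days")
    lines.append("")
    lines.append("| tool | S % | PAL | lower | upper | under | plausible | over |")
    lines.append("|---|---|---|---|---|---|---|---|")
    for tool in ("app", "recall"):
        if tool in g:
            r = g[tool]
            lines.append(
                f"| {tool} | {r.s_factor:.2f} | {r.pal:.2f} | {r.lower_limit:.2f} "
                f"| {r.upper_limit:.2f} | {r.n_under} | {r.n_plausible} | {r.n_over} |")
    for title, step in (
        ("## Step 6 — Intake vs body composition", report.step6_body_composition_correlations),
        ("## Step 7 — Energy stores vs measurement differences", report.step7_energy_stores),
        ("## Step 8 — Expenditure vs measurement differences", report.step8_expenditure),
    ):
        lines.append("")
        lines.append(title)
        if isinstance(step, SkippedStep):
            lines.append(f"*skipped: {step.reason}*")
            continue
        entries = step.get("correlations", step) if isinstance(step, dict) else step
        if isinstance(entries, SkippedStep):
            lines.append(f"*skipped: {entries.reason}*")
            continue
        lines.append("| comparison | r | r² | p (adj) |")
        lines.append("|---|---|---|---|")
        for name, r in entries.items():
            if isinstance(r, ag.PearsonResult):
                lines.append(f"| {name} | {r.r:.3f} | {r.r_squared:.3f} | {r.p_adj:.3g} |")
    lines.append("")
    lines.append("## Step 9 — Diet stability (ICC)")
    icc = report.step9_icc
    if isinstance(icc, SkippedStep):
        lines.append(f"*skipped: {icc.reason}*")
    else:
        lines.append(
            f"ICC {icc.icc:.3f} (95% CI {icc.ci[0]:.3f}–{icc.ci[1]:.3f}), "
            f"F = {icc.f_stat:.3f} on ({icc.df[0]:.0f}, {icc.df[1]:.0f}) df, "
            f"within-subject SD {icc.within_sd:.1f} kcal/day")
    lines.append("")
    return "\n".join(lines)
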