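"""Pipeline orchestration: simulate or load -> filter -> trim -> classify ->
analyze -> write CSVs, a Markdown report, and a reproducibility sidecar.

Every number in the Markdown report is a render-time rounding (one decimal,
half away from zero) of a value already written to a CSV; the CSVs keep full
precision.  Identical config + seed give a byte-identical output bundle (the
metadata sidecar carries a config hash and seed, never a timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import adherence_metrics as am
from . import bp_outcomes as bp
from . import transition_analysis as ta
from . import unmet_need as un
from .io_model import (
    EVENTS,
    ObservationTable,
    apply_washout,
    classify_events,
    filter_eligible,
    read_daily_records,
    read_patients,
    write_daily_records,
    write_patients,
)
from .stats_util import round_half_away
from .synthetic_data import SimulationConfig, generate_cohort, save_config

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

COHORT_ORDER = ["adherent", "nonadherent"]


@dataclass
class RunConfig:
    """Inputs and conventions for one pipeline run.

    Either ``daily_path``+``patients_path`` (measured data) or ``sim_config``
    (synthetic data) must be provided.
    """

    out_dir: str
    daily_path: str | None = None
    patients_path: str | None = None
    sim_config: SimulationConfig | None = None
    washout_days: int = 30
    analysis_days: int = 150
    cohort_threshold: float = 0.8
    min_monitored_days: int | None = None  # default: washout + analysis window

    def __post_init__(self) -> None:
        have_files = self.daily_path is not None and self.patients_path is not None
        if have_files == (self.sim_config is not None):
            raise ValueError("provide either input paths or a simulation config, not both")
        if self.min_monitored_days is None:
            self.min_monitored_days = self.washout_days + self.analysis_days


@dataclass
class PipelineResult:
    out_dir: Path
    cohorts: pd.Series
    metadata: dict


def _fmt(x, nd: int = 1) -> str:
    if x is None or (isinstance(x, float) and x != x):
        return "--"
    return f"{round_half_away(float(x), nd):.{nd}f}"


def _config_hash(config: SimulationConfig | None, run: RunConfig) -> str:
    payload = {
        "run": {
            k: v
            for k, v in dataclasses.asdict(run).items()
            if k not in ("sim_config", "out_dir")
        },
        "sim": config.to_dict() if config is not None else None,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _weekday_csv(wt: am.WeekdayTable) -> pd.DataFrame:
    df = wt.by_month.copy()
    df.insert(0, "month", [str(m) for m in df.index])
    df = df.reset_index(drop=True)
    df.loc[len(df)] = ["mean"] + list(wt.mean)
    df.loc[len(df)] = ["sd"] + list(wt.sd)
    return df


def adherence_outputs(table: ObservationTable, cohorts: pd.Series) -> dict[str, pd.DataFrame]:
    """Monthly summaries per cohort/overall plus weekday tables and labels."""
    out: dict[str, pd.DataFrame] = {}
    rows = []
    scopes = [("overall", None)] + [
        (c, cohorts.index[cohorts == c]) for c in COHORT_ORDER if (cohorts == c).any()
    ]
    for name, ids in scopes:
        s = am.overall_summary(table, patient_ids=ids, scope=name)
        rows.append({"cohort": name, "month": "all", **_summary_row(s)})
        mr = am.monthly_rates(table, patient_ids=ids)
        for month, r in mr.summaries.iterrows():
            rows.append({"cohort": name, "month": str(month), **r.to_dict()})
        rows.append(
            {
                "cohort": name,
                "month": "drop_1_to_5",
                "rate_pre": mr.pre_drop,
                "rate_post": mr.post_drop,
            }
        )
    out["summary"] = pd.DataFrame(rows)
    for c in COHORT_ORDER:
        if (cohorts == c).any():
            out[f"weekday_{c}"] = _weekday_csv(
                am.weekday_table(table, patient_ids=cohorts.index[cohorts == c])
            )
    out["cohorts"] = cohorts.rename_axis("patient_id").reset_index()
    return out


def _summary_row(s: am.AdherenceSummary) -> dict:
    return {
        "n_patients": s.n_patients,
        "rate_pre": s.rate_pre,
        "rate_post": s.rate_post,
        "call_gain": s.call_gain,
        "pct_no_transmit_after_call": s.pct_no_transmit_after_call,
        "pct_missed_call": s.pct_missed_call,
    }


def transition_outputs(table: ObservationTable, cohorts: pd.Series) -> dict[str, pd.DataFrame]:
    sequences = ta.event_sequences(table)
    counts_rows, probs_rows, cond_rows, gap_rows = [], [], [], []
    for c in COHORT_ORDER:
        if not (cohorts == c).any():
            continue
        ids = cohorts.index[cohorts == c]
        m = ta.estimate_transition_matrix(sequences, patient_ids=ids)
        for ev in EVENTS:
            counts_rows.append({"cohort": c, "from": ev, **m.counts.loc[ev].to_dict()})
            probs_rows.append({"cohort": c, "from": ev, **m.probs.loc[ev].to_dict()})
            cond_rows.append(
                {
                    "cohort": c,
                    "from": ev,
                    "conditional_adherence": ta.conditional_adherence(m, ev),
                    "conditional_in_range": ta.conditional_in_range(m, ev),
                    "analytic_hitting_days_to_IRT": ta.analytic_hitting_time(m, ev),
                }
            )
        subset = {p: s for p, s in sequences.items() if p in set(ids)}
        for ev in ("ORT", "NT"):
            try:
                g = ta.mean_gap_to_in_range(subset, from_event=ev)
            except ValueError:
                continue
            gap_rows.append(
                {
                    "cohort": c,
                    "from": ev,
                    "mean_gap_days": g.mean_days,
                    "n_gaps": g.n_gaps,
                    "n_censored": g.n_censored,
                }
            )
    return {
        "transition_counts": pd.DataFrame(counts_rows),
        "transition_probs": pd.DataFrame(probs_rows),
        "conditionals": pd.DataFrame(cond_rows),
        "gaps": pd.DataFrame(gap_rows),
    }


def bp_outputs(table: ObservationTable, cohorts: pd.Series) -> dict[str, pd.DataFrame]:
    means = bp.monthly_bp_means(table)
    rows, excl_rows = [], []
    for vital in ("sbp", "dbp"):
        cmp = bp.bp_change_analysis(means, cohorts, vital=vital)
        for c, r in cmp.results.items():
            rows.append(
                {
                    "analysis": "all",
                    "vital": vital,
                    "cohort": c,
                    "n": r.n_included,
                    "mean_change": r.mean_change,
                    "sd_change": r.sd_change,
                    "p_paired": r.p_paired,
                    "p_between": cmp.p_between,
                }
            )
            excl_rows.append(
                {"vital": vital, "cohort": c, "n_excluded_missing_month": r.n_excluded_missing_month}
            )
        sub = bp.uncontrolled_subgroup(means, cohorts, vital=vital)
        for c, r in sub.results.items():
            rows.append(
                {
                    "analysis": "uncontrolled_gt_140_90",
                    "vital": vital,
                    "cohort": c,
                    "n": r.n_included,
                    "mean_change": r.mean_change,
                    "sd_change": r.sd_change,
                    "p_paired": r.p_paired,
                    "p_between": sub.p_between,
                }
            )
    return {"bp_changes": pd.DataFrame(rows), "bp_exclusions": pd.DataFrame(excl_rows)}


def unmet_outputs(table: ObservationTable, cohorts: pd.Series) -> dict[str, pd.DataFrame]:
    est = un.estimate_unmet_need(table, cohorts)
    df = est.per_cohort.copy()
    total = pd.DataFrame(
        [
            {
                "cohort": "total",
                "n_patients": int(df["n_patients"].sum()),
                "per_patient_days": est.total_days / df["n_patients"].sum(),
                "per_patient_days_reported": float("nan"),
                "post_rate": float("nan"),
                "oor_fraction": float("nan"),
            }
        ]
    )
    out = pd.concat([df, total], ignore_index=True)
    out["total_days"] = [r * n for r, n in zip(out["per_patient_days_reported"], out["n_patients"])][
        :-1
    ] + [est.total_days]
    out["overall_pct"] = [float("nan")] * (len(out) - 1) + [est.overall_pct]
    return {"unmet_need": out}


def _markdown_report(outputs: dict[str, pd.DataFrame], meta: dict) -> str:
    lines = ["# Telemonitoring adherence report", ""]
    lines.append(
        f"Cohorting: adherent = transmitted on >= {meta['adherent_threshold_days']} of "
        f"{meta['analysis_days']} analysis days (threshold {meta['cohort_threshold']:.0%})."
    )
    lines.append(
        f"Patients: {meta['n_patients_input']} with daily records, "
        f"{meta['n_eligible']} eligible ({meta['n_excluded_eligibility']} excluded), "
        f"{meta['n_adherent']} adherent / {meta['n_nonadherent']} nonadherent."
    )
    lines.append("")

    lines.append("## Transmission rates (percent of patient-days)")
    lines.append("")
    lines.append("| Cohort | Month | Pre-call | Post-call | Call gain | No transmit after call | Missed call |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, r in outputs["summary"].iterrows():
        if r["month"] == "drop_1_to_5":
            lines.append(
                f"| {r['cohort']} | month 1->5 drop | {_fmt(r['rate_pre'])} | {_fmt(r['rate_post'])} | | | |"
            )
        else:
            lines.append(
                f"| {r['cohort']} | {r['month']} | {_fmt(r['rate_pre'])} | {_fmt(r['rate_post'])} "
                f"| {_fmt(r['call_gain'])} | {_fmt(r['pct_no_transmit_after_call'])} "
                f"| {_fmt(r['pct_missed_call'])} |"
            )
    lines.append("")

    for c in COHORT_ORDER:
        key = f"weekday_{c}"
        if key not in outputs:
            continue
        lines.append(f"## Weekday adherence by month, {c} cohort (percent)")
        lines.append("")
        wd = outputs[key]
        lines.append("| Month | " + " | ".join(wd.columns[1:]) + " |")
        lines.append("|" + "---|" * (len(wd.columns)))
        for _, r in wd.iterrows():
            lines.append(
                "| " + str(r.iloc[0]) + " | " + " | ".join(_fmt(v) for v in r.iloc[1:]) + " |"
            )
        lines.append("")

    lines.append("## Next-day transition probabilities (row percent)")
    lines.append("")
    lines.append("| Cohort | From | NT | ORT | IRT |")
    lines.append("|---|---|---|---|---|")
    for _, r in outputs["transition_probs"].iterrows():
        lines.append(
            f"| {r['cohort']} | {r['from']} | {_fmt(r['NT'])} | {_fmt(r['ORT'])} | {_fmt(r['IRT'])} |"
        )
    lines.append("")

    lines.append("## Conditional statistics by prior-day event")
    lines.append("")
    lines.append("| Cohort | From | Next-day adherence | Next-day in-range (of transmissions) | Analytic days to next in-range |")
    lines.append("|---|---|---|---|---|")
    for _, r in outputs["conditionals"].iterrows():
        lines.append(
            f"| {r['cohort']} | {r['from']} | {_fmt(r['conditional_adherence'])} "
            f"| {_fmt(r['conditional_in_range'])} | {_fmt(r['analytic_hitting_days_to_IRT'], 2)} |"
        )
    lines.append("")

    lines.append("## Blood-pressure change, month 1 vs month 5 (mm Hg, positive = improvement)")
    lines.append("")
    lines.append("| Analysis | Vital | Cohort | n | Mean change (SD) | p (paired) | p (between) |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, r in outputs["bp_changes"].iterrows():
        p_paired = "--" if pd.isna(r["p_paired"]) else f"{r['p_paired']:.3g}"
        p_between = "--" if pd.isna(r["p_between"]) else f"{r['p_between']:.3g}"
        lines.append(
            f"| {r['analysis']} | {r['vital']} | {r['cohort']} | {int(r['n'])} "
            f"| {_fmt(r['mean_change'])} ({_fmt(r['sd_change'])}) | {p_paired} | {p_between} |"
        )
    lines.append("")

    lines.append("## Unmet need (estimated missed out-of-range days)")
    lines.append("")
    um = outputs["unmet_need"]
    per = um[um["cohort"] != "total"]
    tot = um[um["cohort"] == "total"].iloc[0]
    for _, r in per.iterrows():
        lines.append(
            f"- {r['cohort']}: (1 - {r['post_rate']:.3f}) x {r['oor_fraction']:.3f} x "
            f"{meta['analysis_days']} = {_fmt(r['per_patient_days'])} days per patient"
        )
    lines.append(
        f"- total: {int(tot['total_days'])} days over {int(tot['n_patients'])} patients "
        f"({_fmt(tot['overall_pct'])}% of all patient-days)"
    )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(run: RunConfig) -> PipelineResult:
    """Execute all stages and write the report bundle to ``run.out_dir``."""
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if run.sim_config is not None:
            patients, table = generate_cohort(run.sim_config)
            write_patients(patients, out / "patients.csv")
            write_daily_records(table, out / "daily.csv")
            save_config(run.sim_config, out / "config.yaml")
        else:
            patients = read_patients(run.patients_path)
            table = read_daily_records(run.daily_path)
        n_input = table.n_patients
        n_enrolled = len(patients)

        stage = "eligibility"
        table, n_excluded = filter_eligible(table, min_days=run.min_monitored_days)

        stage = "washout"
        table = apply_washout(table, run.washout_days, run.analysis_days)

        stage = "classification"
        table = classify_events(table, patients)
        cohorts = am.classify_cohorts(table, threshold=run.cohort_threshold)

        stage = "adherence"
        outputs = adherence_outputs(table, cohorts)
        stage = "transitions"
        outputs.update(transition_outputs(table, cohorts))
        stage = "blood-pressure"
        outputs.update(bp_outputs(table, cohorts))
        stage = "unmet-need"
        outputs.update(unmet_outputs(table, cohorts))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, df in outputs.items():
        df.to_csv(out / f"{name}.csv", index=False)

    meta = {
        "config_hash": _config_hash(run.sim_config, run),
        "seed": run.sim_config.seed if run.sim_config is not None else None,
        "n_patients_enrolled": int(n_enrolled),
        "n_patients_input": int(n_input),
        "n_eligible": int(table.n_patients),
        "n_excluded_eligibility": int(n_excluded),
        "n_adherent": int((cohorts == "adherent").sum()),
        "n_nonadherent": int((cohorts == "nonadherent").sum()),
        "washout_days": run.washout_days,
        "analysis_days": run.analysis_days,
        "cohort_threshold": run.cohort_threshold,
        "adherent_threshold_days": am.adherence_threshold_days(
            run.cohort_threshold, run.analysis_days
        ),
        "bp_exclusions": {
            f"{r['vital']}_{r['cohort']}": int(r["n_excluded_missing_month"])
            for _, r in outputs["bp_exclusions"].iterrows()
        },
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    (out / "report.md").write_text(_markdown_report(outputs, meta))
    logger.info(
        "pipeline complete: %d eligible patients (%d excluded), bundle in %s",
        meta["n_eligible"], n_excluded, out,
    )
    return PipelineResult(out_dir=out, cohorts=cohorts, metadata=meta)
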