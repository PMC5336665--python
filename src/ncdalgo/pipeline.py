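"""End-to-end pipeline: simulate -> normalize -> screen -> diagnose -> evaluate.

The pipeline mirrors the study flow: norms are built from the whole cohort at
wave 4, every participant is screened, screen-positive participants are
evaluated against all four nosologies, and screen-negative participants are
classified normal. Agreement with the (real or simulated) expert is then
summarized per diagnostic category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .criteria import DiagnosisSet, classify
from .evaluation import (
    cohen_kappa,
    criteria_logit_roc,
    criterion_ppv_npv,
    crosstab,
    kappa_bootstrap_ci,
    overlap_stats,
)
from .norms import CutoffConfig, DomainScores, NormTable, build_norms, domain_scores
from .records import BatteryConfig, ParticipantRecord, default_battery, write_cohort
from .screening import ScreenResult, screen1
from .simulate import SimConfig, simulate_cohort, simulate_expert

__all__ = [
    "RunConfig",
    "ParticipantOutcome",
    "apply_algorithm",
    "three_class_label",
    "evaluate_against_expert",
    "run_pipeline",
]

NOSOLOGIES = ("dsm5_major", "dsm5_mild", "dsm4_dementia", "iwg_mci")


@dataclass
class ParticipantOutcome:
    participant_id: str
    scores: DomainScores
    screen: ScreenResult
    labels: set[str]
    diagnosis: Optional[DiagnosisSet] = None

    def has(self, label: str) -> bool:
        return label in self.labels


def three_class_label(labels: set[str]) -> str:
    """Collapse a label set to the severity scale normal < mild < major."""
    if "dsm5_major" in labels or "dsm4_dementia" in labels:
        return "major"
    if "dsm5_mild" in labels or "iwg_mci" in labels:
        return "mild"
    return "normal"


def apply_algorithm(
    records: Sequence[ParticipantRecord],
    battery: Optional[BatteryConfig] = None,
    cutoffs: CutoffConfig = CutoffConfig(),
    policy: str = "permissive",
    classify_all: bool = False,
    min_stratum_n: int = 10,
    norms: Optional[NormTable] = None,
) -> tuple[list[ParticipantOutcome], NormTable]:
    """Run norming, screening and classification over a cohort.

    Screen-negative participants are labelled normal without evaluating the
    nosologies, unless ``classify_all`` forces full-cohort classification.
    """
    battery = battery or default_battery()
    if norms is None:
        norms = build_norms(records, battery, min_stratum_n=min_stratum_n)
    outcomes = []
    for rec in records:
        sc = domain_scores(rec, norms, battery)
        scr = screen1(rec, sc)
        if scr.selected or classify_all:
            ds = classify(rec, sc, cutoffs, policy)
            labels = set(ds.labels)
        else:
            ds = None
            labels = {"normal"}
        outcomes.append(
            ParticipantOutcome(
                participant_id=rec.participant_id,
                scores=sc,
                screen=scr,
                labels=labels,
                diagnosis=ds,
            )
        )
    return outcomes, norms


def _binary(flags: Sequence[bool]) -> list[int]:
    return [1 if f else 0 for f in flags]


def evaluate_against_expert(
    outcomes: Sequence[ParticipantOutcome],
    expert_labels: Sequence[str],
    seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Agreement and ROC of the algorithm against a three-class expert."""
    if len(outcomes) != len(expert_labels):
        raise ValueError("outcomes and expert labels differ in length")
    report: dict = {"n": len(outcomes)}
    expert_major = _binary([e == "major" for e in expert_labels])
    expert_mild = _binary([e == "mild" for e in expert_labels])
    alg3 = [three_class_label(o.labels) for o in outcomes]
    alg_major = _binary([a == "major" for a in alg3])
    alg_mild = _binary([a == "mild" for a in alg3])

    for name, alg, exp in (
        ("major", alg_major, expert_major),
        ("mild", alg_mild, expert_mild),
    ):
        if sum(alg) == 0 and sum(exp) == 0:
            report[f"kappa_{name}"] = None
            continue
        stats = kappa_bootstrap_ci(exp, alg, n_boot=n_boot, seed=seed)
        ct = crosstab(exp, alg)
        report[f"kappa_{name}"] = {
            "kappa": stats.kappa,
            "se": stats.se,
            "ci_low": stats.ci_low,
            "ci_high": stats.ci_high,
            "n_algorithm_positive": ct.cmp_positive,
            "n_expert_positive": ct.ref_positive,
        }

    # criteria-based logistic ROC for DSM-5 major NCD, over participants that
    # were actually evaluated (screen-positive), as criteria exist only there
    evaluated = [
        (o, e) for o, e in zip(outcomes, expert_labels) if o.diagnosis is not None
    ]
    if evaluated:
        rows = []
        y = []
        for o, e in evaluated:
            prof = o.diagnosis.profiles["dsm5_major"]
            rows.append({k: 1 if v == "met" else 0 for k, v in prof.criteria.items()})
            y.append(1 if e == "major" else 0)
        X = pd.DataFrame(rows)
        if 0 < sum(y) < len(y) and any(X[c].nunique() > 1 for c in X.columns):
            roc = criteria_logit_roc(X, y, seed=seed)
            report["roc_major"] = {
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "penalized": roc.penalized,
            }
            alg_flags = _binary(
                [o.has("dsm5_major") for o, _ in evaluated]
            )
            report["ppv_npv_major_criteria"] = {}
            for crit in X.columns:
                pv = criterion_ppv_npv(X[crit].tolist(), alg_flags)
                report["ppv_npv_major_criteria"][crit] = {
                    "ppv": pv.ppv,
                    "npv": pv.npv,
                }

    # overlap of DSM-5 vs the older nosology, as classified by the algorithm
    dem = _binary([o.has("dsm4_dementia") for o in outcomes])
    major = _binary([o.has("dsm5_major") for o in outcomes])
    if sum(dem) > 0:
        ct = crosstab(dem, major)
        report["overlap_dementia_vs_major"] = {
            "table": [ct.n_nn, ct.n_ny, ct.n_yn, ct.n_yy],
            "kappa": cohen_kappa(ct),
            **overlap_stats(ct),
        }
    mci = _binary([o.has("iwg_mci") for o in outcomes])
    mild = _binary([o.has("dsm5_mild") for o in outcomes])
    if sum(mci) > 0:
        ct = crosstab(mci, mild)
        report["overlap_mci_vs_mild"] = {
            "table": [ct.n_nn, ct.n_ny, ct.n_yn, ct.n_yy],
            "kappa": cohen_kappa(ct),
            **overlap_stats(ct),
        }

    counts: dict[str, int] = {}
    for o in outcomes:
        for label in o.labels:
            counts[label] = counts.get(label, 0) + 1
    report["label_counts"] = dict(sorted(counts.items()))
    report["n_screen_positive"] = sum(o.screen.selected for o in outcomes)
    return report


@dataclass
class RunConfig:
    """Settings for one end-to-end run."""

    out_dir: str = "."
    n: int = 500
    seed: int = 7
    cutoff_variant: str = "sd1_0"
    missing_policy: str = "permissive"
    battery_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    min_stratum_n: int = 10


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort, run every stage and write the report bundle.

    Writes cohort.csv, truth.csv, expert.csv, norms.csv, screen.csv,
    diagnoses.csv and report.json under ``out_dir``. Deterministic given the
    seed: running twice produces byte-identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    battery = (
        BatteryConfig.from_yaml(config.battery_path)
        if config.battery_path
        else default_battery()
    )
    sim = config.sim or SimConfig(n=config.n, seed=config.seed)
    records, truth = simulate_cohort(sim, battery)
    expert = simulate_expert(truth, sim.expert_confusion, seed=sim.seed + 1)
    cutoffs = CutoffConfig(mild_variant=config.cutoff_variant)

    outcomes, norms = apply_algorithm(
        records,
        battery,
        cutoffs,
        policy=config.missing_policy,
        min_stratum_n=config.min_stratum_n,
    )

    write_cohort(records, out / "cohort.csv", battery)
    pd.DataFrame({"participant_id": [r.participant_id for r in records], "true_class": truth}).to_csv(
        out / "truth.csv", index=False, lineterminator="\n"
    )
    pd.DataFrame({"participant_id": [r.participant_id for r in records], "expert_class": expert}).to_csv(
        out / "expert.csv", index=False, lineterminator="\n"
    )
    norms.to_csv(out / "norms.csv")
    pd.DataFrame(
        {
            "participant_id": [o.participant_id for o in outcomes],
            "selected": ["yes" if o.screen.selected else "no" for o in outcomes],
            "reasons": [";".join(sorted(o.screen.reasons)) for o in outcomes],
        }
    ).to_csv(out / "screen.csv", index=False, lineterminator="\n")

    diag_rows = []
    for o in outcomes:
        row: dict = {
            "participant_id": o.participant_id,
            "labels": ";".join(sorted(o.labels)),
            "class": three_class_label(o.labels),
        }
        if o.diagnosis is not None:
            for nos in NOSOLOGIES:
                prof = o.diagnosis.profiles[nos]
                for crit, status in prof.criteria.items():
                    row[f"{nos}_{crit}"] = status
        diag_rows.append(row)
    pd.DataFrame(diag_rows).fillna("").to_csv(
        out / "diagnoses.csv", index=False, lineterminator="\n"
    )

    report = evaluate_against_expert(outcomes, expert, seed=sim.seed)
    report["config"] = {
        "n": sim.n,
        "seed": sim.seed,
        "cutoff_variant": config.cutoff_variant,
        "missing_policy": config.missing_policy,
        "severe_cutoff": cutoffs.severe_cutoff,
        "mild_upper": cutoffs.mild_upper,
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
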