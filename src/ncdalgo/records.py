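"""Participant records, battery configuration and cohort CSV I/O.

The cohort file is a wide CSV: one row per participant, raw test scores in
``<test>_w3`` / ``<test>_w4`` columns, tristate fields encoded ``yes``/``no``
with the empty cell meaning *unknown* (distinct from ``no``, which matters for
the missing-data policy of the criteria engine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

__all__ = [
    "Tristate",
    "DOMAINS",
    "BEHAVIOR_FLAGS",
    "SOCIAL_BEHAVIOR_FLAGS",
    "PRAXIS_GNOSIS_FLAGS",
    "BAYER_ITEMS",
    "DEXQ_ITEMS",
    "BatteryConfig",
    "ParticipantRecord",
    "ValidationError",
    "default_battery",
    "validate_record",
    "read_cohort",
    "write_cohort",
    "cohort_columns",
]

#: ``True`` = yes, ``False`` = no, ``None`` = unknown/missing.
Tristate = Optional[bool]

DOMAINS = (
    "complex_attention",
    "executive",
    "learning_memory",
    "language",
    "perceptual_motor",
    "social_cognition",
)

# Informant-endorsed behavioural changes. The first four index social/emotional
# change (used when only social cognition is impaired); the last three index
# everyday praxis/gnosis difficulty (used when only praxis/gnosis is impaired).
SOCIAL_BEHAVIOR_FLAGS = (
    "behave_out_of_character",
    "unaware_others_feelings",
    "less_social_participation",
    "lost_skills_hobbies",
)
PRAXIS_GNOSIS_FLAGS = (
    "difficulty_familiar_tasks",
    "difficulty_familiar_tools",
    "lost_in_familiar_places",
)
BEHAVIOR_FLAGS = SOCIAL_BEHAVIOR_FLAGS + PRAXIS_GNOSIS_FLAGS

BAYER_ITEMS = (2, 4, 11)
DEXQ_ITEMS = (9, 11, 13, 20)

PRIOR_DIAGNOSES = ("none", "mci_like", "dementia")


class ValidationError(ValueError):
    """A record or file violates the cohort schema."""


@dataclass(frozen=True)
class BatteryConfig:
    """Maps cognitive tests to DSM-5 domains and fixes score direction.

    ``direction`` is ``higher_better`` for accuracy-like scores and
    ``lower_better`` for timed scores (Trails, reaction time, Stroop), so that
    after standardization a low z always means impairment.
    """

    domain_map: Mapping[str, tuple[str, ...]]
    decline_tests: tuple[str, ...]
    direction: Mapping[str, str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for domain, tests in self.domain_map.items():
            if domain not in DOMAINS:
                raise ValidationError(f"unknown domain {domain!r}")
            for t in tests:
                if t in seen:
                    raise ValidationError(
                        f"test {t!r} assigned to both {seen[t]!r} and {domain!r}"
                    )
                seen[t] = domain
        for t in self.decline_tests:
            if t not in seen:
                raise ValidationError(f"decline test {t!r} not in any domain")
        for t, d in self.direction.items():
            if d not in ("higher_better", "lower_better"):
                raise ValidationError(f"bad direction {d!r} for test {t!r}")
        missing = [t for t in seen if t not in self.direction]
        if missing:
            raise ValidationError(f"tests without direction: {missing}")

    @property
    def tests(self) -> tuple[str, ...]:
        out: list[str] = []
        for domain in DOMAINS:
            out.extend(self.domain_map.get(domain, ()))
        return tuple(out)

    def domain_of(self, test: str) -> str:
        for domain, tests in self.domain_map.items():
            if test in tests:
                return domain
        raise KeyError(test)

    def to_yaml(self, path: str) -> None:
        payload = {
            "domain_map": {d: list(t) for d, t in self.domain_map.items()},
            "decline_tests": list(self.decline_tests),
            "direction": dict(self.direction),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "BatteryConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(
            domain_map={d: tuple(t) for d, t in payload["domain_map"].items()},
            decline_tests=tuple(payload["decline_tests"]),
            direction=dict(payload["direction"]),
        )


def default_battery() -> BatteryConfig:
    """The wave-4 neuropsychological battery, one entry per DSM-5 domain.

    Timed tests (Trail Making, reaction time, Stroop interference) are
    lower-better; everything else is an accuracy/count score.
    """
    return BatteryConfig(
        domain_map={
            "complex_attention": (
                "sdmt",
                "trails_a",
                "reaction_time_simple",
                "reaction_time_choice",
            ),
            "executive": ("digits_backward", "trails_b", "stroop"),
            "learning_memory": ("cvlt_immediate", "cvlt_delayed", "bvrt"),
            "language": ("cowat", "bnt15", "spot_the_word"),
            "perceptual_motor": ("purdue_pegboard", "iat"),
            "social_cognition": ("rmet",),
        },
        decline_tests=(
            "cvlt_immediate",
            "cvlt_delayed",
            "digits_backward",
            "sdmt",
            "purdue_pegboard",
            "cowat",
            "trails_b",
            "reaction_time_simple",
            "reaction_time_choice",
        ),
        direction={
            "sdmt": "higher_better",
            "trails_a": "lower_better",
            "reaction_time_simple": "lower_better",
            "reaction_time_choice": "lower_better",
            "digits_backward": "higher_better",
            "trails_b": "lower_better",
            "stroop": "lower_better",
            "cvlt_immediate": "higher_better",
            "cvlt_delayed": "higher_better",
            "bvrt": "higher_better",
            "cowat": "higher_better",
            "bnt15": "higher_better",
            "spot_the_word": "higher_better",
            "purdue_pegboard": "higher_better",
            "iat": "higher_better",
            "rmet": "higher_better",
        },
    )


@dataclass
class ParticipantRecord:
    """One participant's raw tests, survey and informant fields at waves 3-4."""

    participant_id: str
    sex: str  # "male" | "female"
    education_years: int
    age_years: int
    raw_scores: dict[tuple[str, int], Optional[float]] = field(default_factory=dict)
    mmse_w3: Optional[int] = None
    mmse_w4: Optional[int] = None
    macq_total: Optional[int] = None
    phq9_total: Optional[int] = None
    hrs_iadl_memory_problem: Tristate = None
    needs_care_help: Tristate = None
    informant_available: bool = False
    iqcode_mean: Optional[float] = None
    bayer_iadl_mean: Optional[float] = None
    bayer_item_difficulty: dict[int, Tristate] = field(default_factory=dict)
    dexq_freq: dict[int, Optional[int]] = field(default_factory=dict)
    informant_behavior_flags: dict[str, Tristate] = field(default_factory=dict)
    informant_worsening: Tristate = None
    doctor_consult_cognition: Tristate = None
    history_psychosis: Tristate = None
    prior_path_diagnosis: str = "none"
    onset_months_ago: Optional[float] = None
    delirium_signs: Tristate = None
    delirium_duration_months: Optional[float] = None

    def __post_init__(self) -> None:
        # canonical form: item maps always carry every known key
        for item in BAYER_ITEMS:
            self.bayer_item_difficulty.setdefault(item, None)
        for item in DEXQ_ITEMS:
            self.dexq_freq.setdefault(item, None)
        for name in BEHAVIOR_FLAGS:
            self.informant_behavior_flags.setdefault(name, None)

    def score(self, test: str, wave: int) -> Optional[float]:
        return self.raw_scores.get((test, wave))

    def endorsed_flags(self) -> set[str]:
        return {k for k, v in self.informant_behavior_flags.items() if v is True}


_INFORMANT_SCALARS = (
    "iqcode_mean",
    "bayer_iadl_mean",
    "informant_worsening",
    "doctor_consult_cognition",
    "history_psychosis",
    "onset_months_ago",
    "delirium_signs",
    "delirium_duration_months",
)


def _check_range(name: str, value, lo, hi, pid: str) -> None:
    if value is not None and not (lo <= value <= hi):
        raise ValidationError(
            f"participant {pid!r}: {name}={value!r} outside [{lo}, {hi}]"
        )


def validate_record(record: ParticipantRecord, battery: BatteryConfig) -> None:
    """Raise :class:`ValidationError` on any schema violation."""
    pid = record.participant_id
    if record.sex not in ("male", "female"):
        raise ValidationError(f"participant {pid!r}: sex={record.sex!r}")
    if record.education_years < 0:
        raise ValidationError(f"participant {pid!r}: education_years negative")
    _check_range("mmse_w3", record.mmse_w3, 0, 30, pid)
    _check_range("mmse_w4", record.mmse_w4, 0, 30, pid)
    _check_range("macq_total", record.macq_total, 7, 35, pid)
    _check_range("phq9_total", record.phq9_total, 0, 27, pid)
    _check_range("iqcode_mean", record.iqcode_mean, 1.0, 5.0, pid)
    _check_range("bayer_iadl_mean", record.bayer_iadl_mean, 1.0, 10.0, pid)
    _check_range("onset_months_ago", record.onset_months_ago, 0.0, float("inf"), pid)
    _check_range(
        "delirium_duration_months",
        record.delirium_duration_months,
        0.0,
        float("inf"),
        pid,
    )
    if record.prior_path_diagnosis not in PRIOR_DIAGNOSES:
        raise ValidationError(
            f"participant {pid!r}: prior_path_diagnosis={record.prior_path_diagnosis!r}"
        )
    known = set(battery.tests)
    for (test, wave), _ in record.raw_scores.items():
        if test not in known:
            raise ValidationError(f"participant {pid!r}: unknown test {test!r}")
        if wave not in (3, 4):
            raise ValidationError(f"participant {pid!r}: wave {wave!r} for {test!r}")
    for item, freq in record.dexq_freq.items():
        if item not in DEXQ_ITEMS:
            raise ValidationError(f"participant {pid!r}: DEX-Q item {item!r}")
        if freq is not None and not (0 <= freq <= 4):
            raise ValidationError(f"participant {pid!r}: dexq_{item}={freq!r}")
    for item in record.bayer_item_difficulty:
        if item not in BAYER_ITEMS:
            raise ValidationError(f"participant {pid!r}: Bayer item {item!r}")
    for flag in record.informant_behavior_flags:
        if flag not in BEHAVIOR_FLAGS:
            raise ValidationError(f"participant {pid!r}: behavior flag {flag!r}")
    if not record.informant_available:
        for name in _INFORMANT_SCALARS:
            if getattr(record, name) is not None:
                raise ValidationError(
                    f"participant {pid!r}: informant_available=false but "
                    f"{name} is set"
                )
        for coll in (
            record.bayer_item_difficulty,
            record.dexq_freq,
            record.informant_behavior_flags,
        ):
            if any(v is not None for v in coll.values()):
                raise ValidationError(
                    f"participant {pid!r}: informant_available=false but an "
                    "informant item is set"
                )


# ---------------------------------------------------------------------------
# CSV encoding


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    return str(value)


def _parse_tristate(cell: str, column: str, pid: str) -> Tristate:
    if cell == "":
        return None
    if cell == "yes":
        return True
    if cell == "no":
        return False
    raise ValidationError(f"participant {pid!r}: {column}={cell!r} is not yes/no/empty")


def _parse_float(cell: str, column: str, pid: str) -> Optional[float]:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(
            f"participant {pid!r}: {column}={cell!r} is not numeric"
        ) from None


def _parse_int(cell: str, column: str, pid: str) -> Optional[int]:
    v = _parse_float(cell, column, pid)
    if v is None:
        return None
    if v != int(v):
        raise ValidationError(f"participant {pid!r}: {column}={cell!r} is not integer")
    return int(v)


def cohort_columns(battery: BatteryConfig) -> list[str]:
    """Deterministic column order of the cohort CSV."""
    cols = ["participant_id", "sex", "age_years", "education_years"]
    for test in battery.tests:
        cols += [f"{test}_w3", f"{test}_w4"]
    cols += [
        "mmse_w3",
        "mmse_w4",
        "macq_total",
        "phq9_total",
        "hrs_iadl_memory_problem",
        "needs_care_help",
        "informant_available",
        "iqcode_mean",
        "bayer_iadl_mean",
    ]
    cols += [f"bayer_item{i}_difficulty" for i in BAYER_ITEMS]
    cols += [f"dexq_item{i}" for i in DEXQ_ITEMS]
    cols += [f"flag_{name}" for name in BEHAVIOR_FLAGS]
    cols += [
        "informant_worsening",
        "doctor_consult_cognition",
        "history_psychosis",
        "prior_path_diagnosis",
        "onset_months_ago",
        "delirium_signs",
        "delirium_duration_months",
    ]
    return cols


def _record_to_row(r: ParticipantRecord, battery: BatteryConfig) -> dict[str, str]:
    row = {
        "participant_id": r.participant_id,
        "sex": r.sex,
        "age_years": _fmt(r.age_years),
        "education_years": _fmt(r.education_years),
        "mmse_w3": _fmt(r.mmse_w3),
        "mmse_w4": _fmt(r.mmse_w4),
        "macq_total": _fmt(r.macq_total),
        "phq9_total": _fmt(r.phq9_total),
        "hrs_iadl_memory_problem": _fmt(r.hrs_iadl_memory_problem),
        "needs_care_help": _fmt(r.needs_care_help),
        "informant_available": _fmt(r.informant_available),
        "iqcode_mean": _fmt(r.iqcode_mean),
        "bayer_iadl_mean": _fmt(r.bayer_iadl_mean),
        "informant_worsening": _fmt(r.informant_worsening),
        "doctor_consult_cognition": _fmt(r.doctor_consult_cognition),
        "history_psychosis": _fmt(r.history_psychosis),
        "prior_path_diagnosis": r.prior_path_diagnosis,
        "onset_months_ago": _fmt(r.onset_months_ago),
        "delirium_signs": _fmt(r.delirium_signs),
        "delirium_duration_months": _fmt(r.delirium_duration_months),
    }
    for test in battery.tests:
        for wave in (3, 4):
            row[f"{test}_w{wave}"] = _fmt(r.raw_scores.get((test, wave)))
    for i in BAYER_ITEMS:
        row[f"bayer_item{i}_difficulty"] = _fmt(r.bayer_item_difficulty.get(i))
    for i in DEXQ_ITEMS:
        row[f"dexq_item{i}"] = _fmt(r.dexq_freq.get(i))
    for name in BEHAVIOR_FLAGS:
        row[f"flag_{name}"] = _fmt(r.informant_behavior_flags.get(name))
    return row


def _row_to_record(row: Mapping[str, str], battery: BatteryConfig) -> ParticipantRecord:
    pid = row["participant_id"]
    raw: dict[tuple[str, int], Optional[float]] = {}
    for test in battery.tests:
        for wave in (3, 4):
            cell = row[f"{test}_w{wave}"]
            if cell != "":
                raw[(test, wave)] = _parse_float(cell, f"{test}_w{wave}", pid)
    avail = _parse_tristate(row["informant_available"], "informant_available", pid)
    return ParticipantRecord(
        participant_id=pid,
        sex=row["sex"],
        age_years=_parse_int(row["age_years"], "age_years", pid) or 0,
        education_years=_parse_int(row["education_years"], "education_years", pid) or 0,
        raw_scores=raw,
        mmse_w3=_parse_int(row["mmse_w3"], "mmse_w3", pid),
        mmse_w4=_parse_int(row["mmse_w4"], "mmse_w4", pid),
        macq_total=_parse_int(row["macq_total"], "macq_total", pid),
        phq9_total=_parse_int(row["phq9_total"], "phq9_total", pid),
        hrs_iadl_memory_problem=_parse_tristate(
            row["hrs_iadl_memory_problem"], "hrs_iadl_memory_problem", pid
        ),
        needs_care_help=_parse_tristate(row["needs_care_help"], "needs_care_help", pid),
        informant_available=bool(avail),
        iqcode_mean=_parse_float(row["iqcode_mean"], "iqcode_mean", pid),
        bayer_iadl_mean=_parse_float(row["bayer_iadl_mean"], "bayer_iadl_mean", pid),
        bayer_item_difficulty={
            i: _parse_tristate(
                row[f"bayer_item{i}_difficulty"], f"bayer_item{i}_difficulty", pid
            )
            for i in BAYER_ITEMS
        },
        dexq_freq={
            i: _parse_int(row[f"dexq_item{i}"], f"dexq_item{i}", pid)
            for i in DEXQ_ITEMS
        },
        informant_behavior_flags={
            name: _parse_tristate(row[f"flag_{name}"], f"flag_{name}", pid)
            for name in BEHAVIOR_FLAGS
        },
        informant_worsening=_parse_tristate(
            row["informant_worsening"], "informant_worsening", pid
        ),
        doctor_consult_cognition=_parse_tristate(
            row["doctor_consult_cognition"], "doctor_consult_cognition", pid
        ),
        history_psychosis=_parse_tristate(
            row["history_psychosis"], "history_psychosis", pid
        ),
        prior_path_diagnosis=row["prior_path_diagnosis"] or "none",
        onset_months_ago=_parse_float(row["onset_months_ago"], "onset_months_ago", pid),
        delirium_signs=_parse_tristate(row["delirium_signs"], "delirium_signs", pid),
        delirium_duration_months=_parse_float(
            row["delirium_duration_months"], "delirium_duration_months", pid
        ),
    )


def read_cohort(path, battery: BatteryConfig) -> list[ParticipantRecord]:
    """Read and validate a cohort CSV.

    Empty cells become missing/unknown values, never zero. Unknown test
    columns and out-of-range scale values are hard errors naming the offender.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = cohort_columns(battery)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValidationError(f"unknown columns in {path}: {unknown}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns in {path}: {missing}")
    records = []
    for _, row in df.iterrows():
        rec = _row_to_record(row, battery)
        validate_record(rec, battery)
        records.append(rec)
    return records


def write_cohort(
    records: Iterable[ParticipantRecord], path, battery: BatteryConfig
) -> None:
    """Write records as a cohort CSV in the canonical column order."""
    cols = cohort_columns(battery)
    rows = [_record_to_row(r, battery) for r in records]
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    df.to_csv(path, index=False, lineterminator="\n")
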