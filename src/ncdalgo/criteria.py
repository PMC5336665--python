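"""Rule-based evaluation of four neurocognitive-disorder nosologies.

Each nosology (DSM-5 major NCD, DSM-IV dementia, DSM-5 mild NCD, IWG MCI) is
operationalized as a conjunction of criteria over standardized cognitive
scores, self-report screeners and informant items. Criteria are evaluated in
Kleene three-valued logic (met / not met / unknown) so that missing survey or
informant data propagates honestly; the missing-data policy then resolves
unknowns before the overall verdict:

* ``permissive`` (default): an unknown *inclusion* criterion (concern,
  cognitive impairment, functional interference) resolves to not met, while an
  unknown *exclusion* criterion (no delirium, no better explanation) resolves
  to met. This mirrors screening case files with missing informant blocks
  rather than discarding them.
* ``strict``: every unknown resolves to not met.

Scale thresholds: MAC-Q > 24 (subjective complaint), IQCODE > 3.31 (informant
observed decline), Bayer IADL > 3.12 (functional interference), PHQ-9 < 10
(depression does not better explain the deficits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .norms import CutoffConfig, DomainScores
from .records import (
    DOMAINS,
    PRAXIS_GNOSIS_FLAGS,
    SOCIAL_BEHAVIOR_FLAGS,
    ParticipantRecord,
    Tristate,
)

__all__ = [
    "MACQ_THRESHOLD",
    "IQCODE_THRESHOLD",
    "BAYER_THRESHOLD",
    "PHQ9_THRESHOLD",
    "CriterionProfile",
    "DiagnosisSet",
    "eval_dsm5_major",
    "eval_dsm4_dementia",
    "eval_dsm5_mild",
    "eval_iwg_mci",
    "classify",
]

MACQ_THRESHOLD = 24
IQCODE_THRESHOLD = 3.31
BAYER_THRESHOLD = 3.12
PHQ9_THRESHOLD = 10
ONSET_MONTHS_MIN = 6.0
DEXQ_SOMETIMES = 2  # frequency scale 0=never .. 4=very often

#: MCI considers impairment in these five domains only (social cognition is
#: not part of the IWG construct).
MCI_DOMAINS = (
    "learning_memory",
    "complex_attention",
    "executive",
    "language",
    "perceptual_motor",
)

INCLUSION = "inclusion"
EXCLUSION = "exclusion"


# --- Kleene three-valued logic -------------------------------------------


def t_or(*vals: Tristate) -> Tristate:
    if any(v is True for v in vals):
        return True
    if all(v is False for v in vals):
        return False
    return None


def t_and(*vals: Tristate) -> Tristate:
    if any(v is False for v in vals):
        return False
    if all(v is True for v in vals):
        return True
    return None


def t_not(v: Tristate) -> Tristate:
    return None if v is None else not v


def _gt(x: Optional[float], c: float) -> Tristate:
    return None if x is None else x > c


def _lt(x: Optional[float], c: float) -> Tristate:
    return None if x is None else x < c


def _ge(x: Optional[float], c: float) -> Tristate:
    return None if x is None else x >= c


def _status(v: Tristate) -> str:
    return "unknown" if v is None else ("met" if v else "not_met")


def _resolve(v: Tristate, kind: str, policy: str) -> bool:
    if v is not None:
        return v
    if policy == "strict":
        return False
    if policy == "permissive":
        return kind == EXCLUSION
    raise ValueError(f"unknown missing-data policy {policy!r}")


# --- result containers ----------------------------------------------------


@dataclass
class CriterionProfile:
    """Per-criterion evidence and overall verdict for one nosology."""

    nosology: str
    criteria: dict[str, str]  # criterion id -> met / not_met / unknown
    overall: str  # diagnosed / not_diagnosed
    evidence: dict[str, str] = field(default_factory=dict)

    @property
    def diagnosed(self) -> bool:
        return self.overall == "diagnosed"


@dataclass
class DiagnosisSet:
    """Final label set for one participant under one cutoff variant."""

    labels: set[str]
    variant: CutoffConfig
    profiles: dict[str, CriterionProfile] = field(default_factory=dict)


# --- shared clauses -------------------------------------------------------


def _concern_clause(record: ParticipantRecord) -> tuple[Tristate, str]:
    """A1: concern of self or informant of significant cognitive decline."""
    arms = {
        "MAC-Q>24": _gt(record.macq_total, MACQ_THRESHOLD),
        "IQCODE>3.31": _gt(record.iqcode_mean, IQCODE_THRESHOLD),
        "doctor consult": record.doctor_consult_cognition,
        "informant worsening": record.informant_worsening,
    }
    met = [k for k, v in arms.items() if v is True]
    return t_or(*arms.values()), "; ".join(met) if met else "no concern evidence"


def _severe_domains(scores: DomainScores, cutoffs: CutoffConfig) -> list[str]:
    return [
        d
        for d, z in scores.available_domains().items()
        if z <= cutoffs.severe_cutoff
    ]


def _severe_declines(scores: DomainScores, cutoffs: CutoffConfig) -> list[str]:
    return [
        t
        for t, z in scores.available_declines().items()
        if z <= cutoffs.severe_cutoff
    ]


def _in_mild_range(z: float, cutoffs: CutoffConfig, closed_low: bool = False) -> bool:
    low_ok = z >= cutoffs.severe_cutoff if closed_low else z > cutoffs.severe_cutoff
    return low_ok and z <= cutoffs.mild_upper


def _social_change_endorsed(record: ParticipantRecord) -> Tristate:
    """Footnote-style informant evidence of social/emotional change."""
    arms: list[Tristate] = [
        _ge(record.dexq_freq.get(i), DEXQ_SOMETIMES) for i in record.dexq_freq
    ]
    arms += [record.informant_behavior_flags.get(f) for f in SOCIAL_BEHAVIOR_FLAGS]
    return t_or(*arms) if arms else None

def _praxis_gnosis_endorsed(record: ParticipantRecord) -> Tristate:
    """Informant evidence of everyday praxis/object-recognition difficulty."""
    arms = [record.informant_behavior_flags.get(f) for f in PRAXIS_GNOSIS_FLAGS]
    return t_or(*arms) if arms else None


def _interference_clause(record: ParticipantRecord) -> tuple[Tristate, str]:
    """Functional interference with independence in everyday activity."""
    arms = {
        "HRS-IADL memory problem": record.hrs_iadl_memory_problem,
        "needs household/personal care help": record.needs_care_help,
        "Bayer IADL>3.12": _gt(record.bayer_iadl_mean, BAYER_THRESHOLD),
    }
    met = [k for k, v in arms.items() if v is True]
    return t_or(*arms.values()), "; ".join(met) if met else "no interference evidence"


def _no_delirium_clause(record: ParticipantRecord) -> tuple[Tristate, str]:
    """C: deficits do not occur exclusively in the context of a delirium."""
    onset_ok = _ge(record.onset_months_ago, ONSET_MONTHS_MIN)
    delirium_shorter: Tristate = None
    if record.delirium_duration_months is not None and record.onset_months_ago is not None:
        delirium_shorter = record.delirium_duration_months < record.onset_months_ago
    value = t_or(onset_ok, delirium_shorter)
    if onset_ok is True:
        return value, "onset >= 6 months ago"
    if delirium_shorter is True:
        return value, "delirium shorter than cognitive change"
    return value, "no onset/delirium evidence"


def _not_better_explained_clause(record: ParticipantRecord) -> tuple[Tristate, str]:
    """D: not better explained by depression or psychosis."""
    value = t_and(
        _lt(record.phq9_total, PHQ9_THRESHOLD), t_not(record.history_psychosis)
    )
    return value, "PHQ-9 < 10 and no psychosis history"


def _overall(resolved: dict[str, bool]) -> str:
    return "diagnosed" if all(resolved.values()) else "not_diagnosed"


# --- nosologies -----------------------------------------------------------


def eval_dsm5_major(
    record: ParticipantRecord,
    scores: DomainScores,
    cutoffs: CutoffConfig = CutoffConfig(),
    policy: str = "permissive",
) -> CriterionProfile:
    """DSM-5 major neurocognitive disorder (criteria A1, A2, B, C, D)."""
    a1, a1_ev = _concern_clause(record)

    severe = _severe_domains(scores, cutoffs)
    severe_decl = _severe_declines(scores, cutoffs)
    if severe or severe_decl:
        a2: Tristate = True
    elif scores.available_domains() or scores.available_declines():
        a2 = False
    else:
        a2 = None
    a2_ev = f"severe domains {severe}; severe declines {severe_decl}"

    interference, b_ev = _interference_clause(record)
    b = interference
    if severe == ["social_cognition"]:
        # when the only severe domain is social cognition, interference must
        # be corroborated by informant-reported social/emotional change
        social = _social_change_endorsed(record)
        b = t_and(interference, social)
        b_ev += f"; social-cognition caveat endorsed={_status(social)}"

    c, c_ev = _no_delirium_clause(record)
    d, d_ev = _not_better_explained_clause(record)

    raw = {"A1": a1, "A2": a2, "B": b, "C": c, "D": d}
    kinds = {"A1": INCLUSION, "A2": INCLUSION, "B": INCLUSION, "C": EXCLUSION, "D": EXCLUSION}
    resolved = {k: _resolve(v, kinds[k], policy) for k, v in raw.items()}
    return CriterionProfile(
        nosology="dsm5_major",
        criteria={k: _status(v) for k, v in raw.items()},
        overall=_overall(resolved),
        evidence={"A1": a1_ev, "A2": a2_ev, "B": b_ev, "C": c_ev, "D": d_ev},
    )


def eval_dsm4_dementia(
    record: ParticipantRecord,
    scores: DomainScores,
    cutoffs: CutoffConfig = CutoffConfig(),
    policy: str = "permissive",
) -> CriterionProfile:
    """DSM-IV dementia: memory impairment plus a second cognitive disturbance."""
    doms = scores.available_domains()

    mem = doms.get("learning_memory")
    a1: Tristate = None if mem is None else mem <= cutoffs.severe_cutoff
    a1_ev = f"learning_memory z={mem}"

    exec_lang = [
        doms[d] for d in ("executive", "language") if d in doms
    ]
    exec_lang_sev = any(z <= cutoffs.severe_cutoff for z in exec_lang)
    iat_z = scores.test_z.get("iat")
    praxis = iat_z is not None and iat_z <= cutoffs.severe_cutoff
    bnt_z = scores.test_z.get("bnt15")
    cowat_z = scores.test_z.get("cowat")
    gnosis = (
        bnt_z is not None
        and bnt_z <= cutoffs.severe_cutoff
        and cowat_z is not None
        and cowat_z > cutoffs.severe_cutoff
    )
    severe_decl = _severe_declines(scores, cutoffs)
    any_evidence = exec_lang or iat_z is not None or bnt_z is not None or scores.available_declines()
    if exec_lang_sev or praxis or gnosis or severe_decl:
        a2: Tristate = True
    elif any_evidence:
        a2 = False
    else:
        a2 = None
    a2_ev = (
        f"exec/lang severe={exec_lang_sev}; praxis={praxis}; gnosis={gnosis}; "
        f"severe declines {severe_decl}"
    )

    interference, b_ev = _interference_clause(record)
    b = interference
    only_praxis_gnosis = (praxis or gnosis) and not exec_lang_sev and not severe_decl
    if only_praxis_gnosis:
        endorsed = _praxis_gnosis_endorsed(record)
        b = t_and(interference, endorsed)
        b_ev += f"; praxis/gnosis caveat endorsed={_status(endorsed)}"

    c, c_ev = _no_delirium_clause(record)
    d, d_ev = _not_better_explained_clause(record)

    raw = {"A1": a1, "A2": a2, "B": b, "C": c, "D": d}
    kinds = {"A1": INCLUSION, "A2": INCLUSION, "B": INCLUSION, "C": EXCLUSION, "D": EXCLUSION}
    resolved = {k: _resolve(v, kinds[k], policy) for k, v in raw.items()}
    return CriterionProfile(
        nosology="dsm4_dementia",
        criteria={k: _status(v) for k, v in raw.items()},
        overall=_overall(resolved),
        evidence={"A1": a1_ev, "A2": a2_ev, "B": b_ev, "C": c_ev, "D": d_ev},
    )


def eval_dsm5_mild(
    record: ParticipantRecord,
    scores: DomainScores,
    cutoffs: CutoffConfig = CutoffConfig(),
    policy: str = "permissive",
) -> CriterionProfile:
    """DSM-5 mild NCD: modest impairment without functional interference.

    Never diagnosed when the same record meets DSM-5 major NCD (severity
    precedence).
    """
    a1, a1_ev = _concern_clause(record)

    mild_doms = [
        d for d, z in scores.available_domains().items() if _in_mild_range(z, cutoffs)
    ]
    mild_decl = [
        t for t, z in scores.available_declines().items() if _in_mild_range(z, cutoffs)
    ]
    if mild_doms or mild_decl:
        a2: Tristate = True
    elif scores.available_domains() or scores.available_declines():
        a2 = False
    else:
        a2 = None
    a2_ev = f"mild domains {mild_doms}; mild declines {mild_decl}"

    # B: the deficits do NOT interfere with independence — met when none of
    # the major-NCD interference arms fire, with the social caveat inverted.
    interference, _ = _interference_clause(record)
    b = t_not(interference)
    b_ev = f"interference={_status(interference)}"
    if mild_doms == ["social_cognition"]:
        social = _social_change_endorsed(record)
        b = t_and(b, t_not(social))
        b_ev += f"; inverted social caveat endorsed={_status(social)}"

    c, c_ev = _no_delirium_clause(record)
    d, d_ev = _not_better_explained_clause(record)

    raw = {"A1": a1, "A2": a2, "B": b, "C": c, "D": d}
    kinds = {"A1": INCLUSION, "A2": INCLUSION, "B": INCLUSION, "C": EXCLUSION, "D": EXCLUSION}
    resolved = {k: _resolve(v, kinds[k], policy) for k, v in raw.items()}
    overall = _overall(resolved)
    if overall == "diagnosed":
        if eval_dsm5_major(record, scores, cutoffs, policy).diagnosed:
            overall = "not_diagnosed"
            b_ev += "; excluded by DSM-5 major NCD precedence"
    return CriterionProfile(
        nosology="dsm5_mild",
        criteria={k: _status(v) for k, v in raw.items()},
        overall=overall,
        evidence={"A1": a1_ev, "A2": a2_ev, "B": b_ev, "C": c_ev, "D": d_ev},
    )


def eval_iwg_mci(
    record: ParticipantRecord,
    scores: DomainScores,
    cutoffs: CutoffConfig = CutoffConfig(),
    policy: str = "permissive",
) -> CriterionProfile:
    """IWG MCI: not normal, not demented, declining, function preserved."""
    doms = scores.available_domains()

    not_dem = not (
        eval_dsm4_dementia(record, scores, cutoffs, policy).diagnosed
        or eval_dsm5_major(record, scores, cutoffs, policy).diagnosed
    )
    if doms:
        not_normal = any(z <= -1.0 for z in doms.values())
        c1: Tristate = not_dem and not_normal
    else:
        c1 = False if not not_dem else None
    c1_ev = f"not demented={not_dem}; any domain z<=-1.0"

    concern, concern_ev = _concern_clause(record)
    mci_avail = [d for d in MCI_DOMAINS if d in doms]
    mci_mild = [
        d for d in mci_avail if _in_mild_range(doms[d], cutoffs, closed_low=True)
    ]
    if mci_avail:
        objective: Tristate = bool(mci_mild)
    else:
        objective = None
    c2a = t_and(concern, objective)
    mild_decl = [
        t for t, z in scores.available_declines().items() if _in_mild_range(z, cutoffs)
    ]
    if scores.available_declines():
        c2b: Tristate = bool(mild_decl)
    else:
        c2b = None
    c2 = t_or(c2a, c2b)
    c2_ev = (
        f"2a: concern ({concern_ev}) and mild domains {mci_mild}; "
        f"2b: mild declines {mild_decl}"
    )

    no_item_difficulty = t_and(
        *(t_not(record.bayer_item_difficulty.get(i)) for i in (2, 4, 11))
    )
    c3 = t_or(
        no_item_difficulty,
        t_not(record.needs_care_help),
        _lt(record.bayer_iadl_mean, BAYER_THRESHOLD),
    )
    c3_ev = "no Bayer 2/4/11 difficulty, or no care need, or Bayer < 3.12"

    raw = {"1": c1, "2": c2, "3": c3}
    kinds = {"1": INCLUSION, "2": INCLUSION, "3": INCLUSION}
    resolved = {k: _resolve(v, kinds[k], policy) for k, v in raw.items()}
    crits = {"1": _status(c1), "2": _status(c2), "2a": _status(c2a), "2b": _status(c2b), "3": _status(c3)}
    return CriterionProfile(
        nosology="iwg_mci",
        criteria=crits,
        overall=_overall(resolved),
        evidence={"1": c1_ev, "2": c2_ev, "3": c3_ev},
    )


def classify(
    record: ParticipantRecord,
    scores: DomainScores,
    cutoffs: CutoffConfig = CutoffConfig(),
    policy: str = "permissive",
) -> DiagnosisSet:
    """Run all four evaluators and apply the exclusivity rules.

    Major NCD takes precedence over mild NCD; MCI excludes dementia/major NCD
    by its own criterion 1. A record meeting nothing is labelled ``normal``.
    Robust to records with no informant data (unknowns resolve per policy).
    """
    profiles = {
        "dsm5_major": eval_dsm5_major(record, scores, cutoffs, policy),
        "dsm4_dementia": eval_dsm4_dementia(record, scores, cutoffs, policy),
        "dsm5_mild": eval_dsm5_mild(record, scores, cutoffs, policy),
        "iwg_mci": eval_iwg_mci(record, scores, cutoffs, policy),
    }
    labels = {name for name, prof in profiles.items() if prof.diagnosed}
    if not labels:
        labels = {"normal"}
    return DiagnosisSet(labels=labels, variant=cutoffs, profiles=profiles)
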