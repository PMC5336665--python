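"""Screen 1: triage of participants into full algorithmic evaluation.

A participant is selected when they carry a previous study diagnosis of
dementia or a mild cognitive disorder, or when there is both objective
evidence of impairment (any cognitive test at or below the 6.7th percentile,
i.e. z <= -1.5 on the stratified norms, or MMSE <= 24 at wave 4) and
subjective/longitudinal evidence of decline (MAC-Q > 24, an MMSE drop of more
than 3 points between waves, or MMSE <= 24 at both waves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .norms import DomainScores
from .records import ParticipantRecord

__all__ = ["ScreenResult", "SCREEN_PERCENTILE_Z", "screen1"]

#: z equivalent of the 6.7th percentile under the normal model.
SCREEN_PERCENTILE_Z = -1.5

MMSE_CUTOFF = 24
MACQ_CUTOFF = 24
MMSE_DECLINE_POINTS = 3


@dataclass
class ScreenResult:
    selected: bool
    reasons: set[str] = field(default_factory=set)


def screen1(
    record: ParticipantRecord,
    scores: DomainScores,
    percentile_z: float = SCREEN_PERCENTILE_Z,
) -> ScreenResult:
    """Evaluate Screen 1 on one participant.

    Selection logic: prior diagnosis OR (objective AND subjective), with the
    arms within the objective and subjective clauses OR-ed. Missing fields
    count as not satisfied. ``reasons`` lists every satisfied arm when the
    participant is selected, and is empty otherwise — a satisfied subjective
    arm without any objective arm does not by itself select, so it is not
    reported as a reason.
    """
    prior = record.prior_path_diagnosis in ("mci_like", "dementia")

    objective = set()
    if any(z is not None and z <= percentile_z for z in scores.test_z.values()):
        objective.add("objective_low_percentile")
    if record.mmse_w4 is not None and record.mmse_w4 <= MMSE_CUTOFF:
        objective.add("objective_mmse")

    subjective = set()
    if record.macq_total is not None and record.macq_total > MACQ_CUTOFF:
        subjective.add("subjective_macq")
    if (
        record.mmse_w3 is not None
        and record.mmse_w4 is not None
        and record.mmse_w3 - record.mmse_w4 > MMSE_DECLINE_POINTS
    ):
        subjective.add("mmse_decline")
    if (
        record.mmse_w3 is not None
        and record.mmse_w4 is not None
        and record.mmse_w3 <= MMSE_CUTOFF
        and record.mmse_w4 <= MMSE_CUTOFF
    ):
        subjective.add("persistent_low_mmse")

    selected = prior or (bool(objective) and bool(subjective))
    reasons: set[str] = set()
    if selected:
        if prior:
            reasons.add("prior_diagnosis")
        if objective and subjective:
            reasons |= objective | subjective
    return ScreenResult(selected=selected, reasons=reasons)
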