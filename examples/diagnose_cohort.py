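"""Run the full diagnostic algorithm on a synthetic cohort.

Builds sex- and education-stratified norms from the cohort itself, screens
every participant, evaluates the four nosologies on screen-positives, and
prints the label counts plus the criterion-by-criterion trace of one
diagnosed participant. Criteria read met / not_met / unknown; unknowns are
resolved by the permissive missing-data policy before the overall verdict.
"""

from collections import Counter

from ncdalgo import apply_algorithm, three_class_label
from ncdalgo.simulate import SimConfig, simulate_cohort

records, truth = simulate_cohort(SimConfig(n=500, seed=7))
outcomes, norms = apply_algorithm(records)

counts = Counter(three_class_label(o.labels) for o in outcomes)
print("algorithmic classes:", dict(counts))
print("screen-positive:", sum(o.screen.selected for o in outcomes), "of", len(outcomes))

diagnosed = next(o for o in outcomes if "dsm5_major" in o.labels)
prof = diagnosed.diagnosis.profiles["dsm5_major"]
print(f"\n{diagnosed.participant_id}: labels = {sorted(diagnosed.labels)}")
print("DSM-5 major NCD criteria:")
for crit, status in prof.criteria.items():
    print(f"  {crit}: {status}  ({prof.evidence[crit]})")
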