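"""Compare the 1.0 SD and 1.5 SD mild-impairment cutoffs on one cohort.

The mild band under the 1.5 SD variant, (-2.0, -1.5], is nested inside the
1.0 SD band, (-2.0, -1.0], so the stricter variant can only ever diagnose a
subset of the same participants — the printout verifies the nesting and
shows how many borderline cases the choice of cutoff moves.
"""

from ncdalgo import CutoffConfig, apply_algorithm
from ncdalgo.simulate import SimConfig, simulate_cohort

records, _ = simulate_cohort(SimConfig(n=800, seed=31))
out10, _ = apply_algorithm(records, cutoffs=CutoffConfig(mild_variant="sd1_0"))
out15, _ = apply_algorithm(records, cutoffs=CutoffConfig(mild_variant="sd1_5"))

mild10 = {o.participant_id for o in out10 if "dsm5_mild" in o.labels}
mild15 = {o.participant_id for o in out15 if "dsm5_mild" in o.labels}

print(f"DSM-5 mild NCD at 1.0 SD cutoff: {len(mild10)} cases")
print(f"DSM-5 mild NCD at 1.5 SD cutoff: {len(mild15)} cases")
print(f"1.5 SD cases that are a subset of 1.0 SD cases: {mild15 <= mild10}")
print(f"borderline cases (mild only under the looser cutoff): {len(mild10 - mild15)}")
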