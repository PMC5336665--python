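"""Independent brute-force oracles used only by the test suite.

The diagnostic oracle literally transcribes each operationalized clause and
resolves unknown inputs by *possible-worlds enumeration*: every unknown leaf
is expanded to both truth values, and a criterion counts as met (not met)
only if it is true (false) in every world; otherwise it is unknown and the
missing-data policy decides. This is a deliberately different mechanism from
the engine's three-valued connectives.
"""

from itertools import product

from ncdalgo.records import DOMAINS

MCI_DOMAINS = (
    "learning_memory",
    "complex_attention",
    "executive",
    "language",
    "perceptual_motor",
)
SOCIAL_FLAGS = (
    "behave_out_of_character",
    "unaware_others_feelings",
    "less_social_participation",
    "lost_skills_hobbies",
)
PRAXIS_FLAGS = (
    "difficulty_familiar_tasks",
    "difficulty_familiar_tools",
    "lost_in_familiar_places",
)


def tri(leaves, formula):
    """met/not_met/unknown of formula(leaves) over all worlds of unknowns."""
    unknown = [i for i, v in enumerate(leaves) if v is None]
    vals = list(leaves)
    seen = set()
    for combo in product([False, True], repeat=len(unknown)):
        for i, b in zip(unknown, combo):
            vals[i] = b
        seen.add(bool(formula(vals)))
        if len(seen) == 2:
            return None
    return seen.pop()


def resolve(value, kind, policy):
    if value is not None:
        return value
    return policy == "permissive" and kind == "exclusion"


def _cmp(x, op, c):
    if x is None:
        return None
    return {"<=": x <= c, "<": x < c, ">": x > c, ">=": x >= c}[op]


def _concern_leaves(rec):
    return [
        _cmp(rec.macq_total, ">", 24),
        _cmp(rec.iqcode_mean, ">", 3.31),
        rec.doctor_consult_cognition,
        rec.informant_worsening,
    ]


def _social_endorsed(rec):
    leaves = [_cmp(rec.dexq_freq.get(i), ">=", 2) for i in rec.dexq_freq]
    leaves += [rec.informant_behavior_flags.get(f) for f in SOCIAL_FLAGS]
    if not leaves:
        return None
    return tri(leaves, any)


def _praxis_endorsed(rec):
    leaves = [rec.informant_behavior_flags.get(f) for f in PRAXIS_FLAGS]
    if not leaves:
        return None
    return tri(leaves, any)


def _interference(rec):
    return tri(
        [
            rec.hrs_iadl_memory_problem,
            rec.needs_care_help,
            _cmp(rec.bayer_iadl_mean, ">", 3.12),
        ],
        any,
    )


def _no_delirium(rec):
    onset_ok = _cmp(rec.onset_months_ago, ">=", 6.0)
    if rec.delirium_duration_months is None or rec.onset_months_ago is None:
        shorter = None
    else:
        shorter = rec.delirium_duration_months < rec.onset_months_ago
    return tri([onset_ok, shorter], any)


def _not_better_explained(rec):
    phq = _cmp(rec.phq9_total, "<", 10)
    psych = rec.history_psychosis
    return tri([phq, psych], lambda v: v[0] and not v[1])


def _avail_domains(scores):
    return {d: z for d, z in scores.domain_z.items() if z is not None}


def _avail_declines(scores):
    return {t: z for t, z in scores.decline_z.items() if z is not None}


def _any_or_none(values, pred):
    """True if any value satisfies pred, False if values exist, else None."""
    if any(pred(v) for v in values):
        return True
    return False if values else None


def oracle_dsm5_major(rec, scores, policy="permissive"):
    doms = _avail_domains(scores)
    decls = _avail_declines(scores)
    a1 = tri(_concern_leaves(rec), any)
    severe = [d for d, z in doms.items() if z <= -2.0]
    severe_decl = [t for t, z in decls.items() if z <= -2.0]
    if severe or severe_decl:
        a2 = True
    elif doms or decls:
        a2 = False
    else:
        a2 = None
    b = _interference(rec)
    if severe == ["social_cognition"]:
        social = _social_endorsed(rec)
        b = tri([b, social], all)
    c = _no_delirium(rec)
    d = _not_better_explained(rec)
    met = [
        resolve(a1, "inclusion", policy),
        resolve(a2, "inclusion", policy),
        resolve(b, "inclusion", policy),
        resolve(c, "exclusion", policy),
        resolve(d, "exclusion", policy),
    ]
    return all(met)


def oracle_dsm4_dementia(rec, scores, policy="permissive"):
    doms = _avail_domains(scores)
    decls = _avail_declines(scores)
    mem = doms.get("learning_memory")
    a1 = None if mem is None else mem <= -2.0
    exec_lang = [doms[d] for d in ("executive", "language") if d in doms]
    exec_lang_sev = any(z <= -2.0 for z in exec_lang)
    iat = scores.test_z.get("iat")
    praxis = iat is not None and iat <= -2.0
    bnt = scores.test_z.get("bnt15")
    cowat = scores.test_z.get("cowat")
    gnosis = bnt is not None and bnt <= -2.0 and cowat is not None and cowat > -2.0
    severe_decl = [t for t, z in decls.items() if z <= -2.0]
    if exec_lang_sev or praxis or gnosis or severe_decl:
        a2 = True
    elif exec_lang or iat is not None or bnt is not None or decls:
        a2 = False
    else:
        a2 = None
    b = _interference(rec)
    if (praxis or gnosis) and not exec_lang_sev and not severe_decl:
        b = tri([b, _praxis_endorsed(rec)], all)
    c = _no_delirium(rec)
    d = _not_better_explained(rec)
    met = [
        resolve(a1, "inclusion", policy),
        resolve(a2, "inclusion", policy),
        resolve(b, "inclusion", policy),
        resolve(c, "exclusion", policy),
        resolve(d, "exclusion", policy),
    ]
    return all(met)


def oracle_dsm5_mild(rec, scores, policy="permissive", mild_upper=-1.0):
    doms = _avail_domains(scores)
    decls = _avail_declines(scores)
    a1 = tri(_concern_leaves(rec), any)
    mild_doms = [d for d, z in doms.items() if -2.0 < z <= mild_upper]
    mild_decl = [t for t, z in decls.items() if -2.0 < z <= mild_upper]
    if mild_doms or mild_decl:
        a2 = True
    elif doms or decls:
        a2 = False
    else:
        a2 = None
    interference = _interference(rec)
    b = tri([interference], lambda v: not v[0])
    if mild_doms == ["social_cognition"]:
        social = _social_endorsed(rec)
        b = tri([b, social], lambda v: v[0] and not v[1])
    c = _no_delirium(rec)
    d = _not_better_explained(rec)
    met = [
        resolve(a1, "inclusion", policy),
        resolve(a2, "inclusion", policy),
        resolve(b, "inclusion", policy),
        resolve(c, "exclusion", policy),
        resolve(d, "exclusion", policy),
    ]
    return all(met) and not oracle_dsm5_major(rec, scores, policy)


def oracle_iwg_mci(rec, scores, policy="permissive", mild_upper=-1.0):
    doms = _avail_domains(scores)
    decls = _avail_declines(scores)
    demented = oracle_dsm4_dementia(rec, scores, policy) or oracle_dsm5_major(
        rec, scores, policy
    )
    if demented:
        c1 = False
    elif not doms:
        c1 = None
    else:
        c1 = any(z <= -1.0 for z in doms.values())
    objective = _any_or_none(
        [doms[d] for d in MCI_DOMAINS if d in doms],
        lambda z: -2.0 <= z <= mild_upper,
    )
    c2a = tri(_concern_leaves(rec) + [objective], lambda v: any(v[:-1]) and v[-1])
    c2b = _any_or_none(list(decls.values()), lambda z: -2.0 < z <= mild_upper)
    c2 = tri([c2a, c2b], any)
    i2 = rec.bayer_item_difficulty.get(2)
    i4 = rec.bayer_item_difficulty.get(4)
    i11 = rec.bayer_item_difficulty.get(11)
    c3 = tri(
        [i2, i4, i11, rec.needs_care_help, _cmp(rec.bayer_iadl_mean, "<", 3.12)],
        lambda v: (not v[0] and not v[1] and not v[2]) or (not v[3]) or v[4],
    )
    met = [
        resolve(c1, "inclusion", policy),
        resolve(c2, "inclusion", policy),
        resolve(c3, "inclusion", policy),
    ]
    return all(met)


def oracle_labels(rec, scores, policy="permissive", mild_upper=-1.0):
    labels = set()
    if oracle_dsm5_major(rec, scores, policy):
        labels.add("dsm5_major")
    if oracle_dsm4_dementia(rec, scores, policy):
        labels.add("dsm4_dementia")
    if oracle_dsm5_mild(rec, scores, policy, mild_upper):
        labels.add("dsm5_mild")
    if oracle_iwg_mci(rec, scores, policy, mild_upper):
        labels.add("iwg_mci")
    return labels or {"normal"}
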