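import numpy as np
import pytest

from ncdalgo.criteria import (
    classify,
    eval_dsm4_dementia,
    eval_dsm5_major,
    eval_dsm5_mild,
    eval_iwg_mci,
)
from ncdalgo.norms import CutoffConfig
from ncdalgo.records import DOMAINS

from conftest import make_record, make_scores, random_record_and_scores
from oracles import oracle_labels

SD10 = CutoffConfig(mild_variant="sd1_0")
SD15 = CutoffConfig(mild_variant="sd1_5")


def severe_case():
    """Globally impaired, concerned, functionally dependent participant."""
    rec = make_record(macq_total=30, bayer_iadl_mean=4.0, onset_months_ago=24.0,
                      phq9_total=2, history_psychosis=False)
    scores = make_scores(domain_z={d: -2.5 for d in DOMAINS})
    return rec, scores


def mild_case():
    """Modest memory impairment, complaint, fully independent."""
    rec = make_record(macq_total=26, bayer_iadl_mean=2.0, needs_care_help=False,
                      hrs_iadl_memory_problem=False, onset_months_ago=12.0,
                      phq9_total=3)
    scores = make_scores(
        domain_z={"learning_memory": -1.4, **{d: -0.5 for d in DOMAINS if d != "learning_memory"}}
    )
    return rec, scores


class TestDsm5Major:
    def test_fully_impaired_case_meets_all_five(self):
        prof = eval_dsm5_major(*severe_case())
        assert prof.criteria == {k: "met" for k in ("A1", "A2", "B", "C", "D")}
        assert prof.diagnosed

    def test_depression_excludes(self):
        rec, scores = severe_case()
        rec.phq9_total = 12
        prof = eval_dsm5_major(rec, scores)
        assert prof.criteria["D"] == "not_met"
        assert not prof.diagnosed

    def test_no_impairment_fails_a2_regardless(self):
        rec, _ = severe_case()
        prof = eval_dsm5_major(rec, make_scores(domain_z={d: 0.5 for d in DOMAINS}))
        assert prof.criteria["A2"] == "not_met"
        assert not prof.diagnosed

    def test_decline_alone_can_carry_a2(self):
        rec, _ = severe_case()
        scores = make_scores(decline_z={"sdmt": -2.3})
        prof = eval_dsm5_major(rec, scores)
        assert prof.criteria["A2"] == "met"
        assert prof.diagnosed

    def test_social_cognition_only_requires_informant_corroboration(self):
        rec, _ = severe_case()
        scores = make_scores(domain_z={"social_cognition": -2.4})
        assert not eval_dsm5_major(rec, scores).diagnosed
        rec.informant_behavior_flags["behave_out_of_character"] = True
        assert eval_dsm5_major(rec, scores).diagnosed

    def test_monotone_in_domain_z(self):
        """Lowering any domain z never removes the diagnosis."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            rec, scores = random_record_and_scores(rng)
            if not eval_dsm5_major(rec, scores).diagnosed:
                continue
            d = rng.choice([k for k, v in scores.domain_z.items() if v is not None])
            scores.domain_z[d] -= float(rng.uniform(0, 2))
            assert eval_dsm5_major(rec, scores).diagnosed


class TestDsm4Dementia:
    def test_memory_plus_language_case(self):
        rec = make_record(bayer_iadl_mean=4.0, onset_months_ago=12.0, phq9_total=0)
        scores = make_scores(domain_z={"learning_memory": -2.2, "language": -2.1})
        assert eval_dsm4_dementia(rec, scores).diagnosed

    def test_memory_gate_is_mandatory(self):
        rec, _ = severe_case()
        scores = make_scores(
            domain_z={"learning_memory": -1.8, **{d: -3.0 for d in DOMAINS if d != "learning_memory"}}
        )
        prof = eval_dsm4_dementia(rec, scores)
        assert prof.criteria["A1"] == "not_met"
        assert not prof.diagnosed

    def test_gnosis_requires_preserved_fluency(self):
        """Naming deficit only counts as gnosis when word fluency is intact."""
        rec, _ = severe_case()
        base = {"learning_memory": -2.2}
        impaired_both = make_scores(
            domain_z=base, test_z={"bnt15": -2.3, "cowat": -2.4}
        )
        prof = eval_dsm4_dementia(rec, impaired_both)
        assert prof.criteria["A2"] == "not_met"
        preserved = make_scores(domain_z=base, test_z={"bnt15": -2.3, "cowat": -0.5})
        rec.informant_behavior_flags["lost_in_familiar_places"] = True
        assert eval_dsm4_dementia(rec, preserved).diagnosed


class TestDsm5Mild:
    def test_mild_case_diagnosed_under_1sd(self):
        assert eval_dsm5_mild(*mild_case(), SD10).diagnosed

    def test_mild_case_not_diagnosed_under_1_5sd(self):
        """z = -1.4 falls outside the narrower (-2.0, -1.5] band."""
        assert not eval_dsm5_mild(*mild_case(), SD15).diagnosed

    def test_functional_interference_excludes_mild(self):
        rec, scores = mild_case()
        rec.bayer_iadl_mean = 4.0
        prof = eval_dsm5_mild(rec, scores, SD10)
        assert prof.criteria["B"] == "not_met"
        assert not prof.diagnosed

    def test_major_takes_precedence(self):
        rec, scores = severe_case()
        scores.decline_z["sdmt"] = -1.5  # also mild-range decline
        assert eval_dsm5_major(rec, scores).diagnosed
        assert not eval_dsm5_mild(rec, scores, SD10).diagnosed


class TestIwgMci:
    def test_mild_case_diagnosed_via_2a(self):
        prof = eval_iwg_mci(*mild_case(), SD10)
        assert prof.criteria["2a"] == "met"
        assert prof.diagnosed

    def test_social_cognition_excluded_from_2a(self):
        rec, _ = mild_case()
        scores = make_scores(domain_z={"social_cognition": -1.6})
        prof = eval_iwg_mci(rec, scores, SD10)
        assert prof.criteria["2a"] == "not_met"
        assert not prof.diagnosed
        scores.decline_z["sdmt"] = -1.6  # 2b route still open
        assert eval_iwg_mci(rec, scores, SD10).diagnosed

    def test_normal_scores_fail_c1(self):
        rec, _ = mild_case()
        prof = eval_iwg_mci(rec, make_scores(domain_z={d: -0.5 for d in DOMAINS}), SD10)
        assert prof.criteria["1"] == "not_met"
        assert not prof.diagnosed

    def test_2a_admits_exactly_minus_two(self):
        rec, _ = mild_case()
        scores = make_scores(domain_z={"complex_attention": -2.0})
        # -2.0 is severe for DSM-5 but still within the printed MCI 2a range;
        # criterion 1 excludes the case only if it reaches a dementia diagnosis
        prof = eval_iwg_mci(rec, scores, SD10)
        assert prof.criteria["2a"] == "met"


class TestClassify:
    def test_severe_case_labels(self):
        ds = classify(*severe_case(), SD10)
        assert ds.labels == {"dsm5_major", "dsm4_dementia"}

    def test_mild_case_labels(self):
        ds = classify(*mild_case(), SD10)
        assert ds.labels == {"dsm5_mild", "iwg_mci"}

    def test_normal_case(self):
        rec = make_record()
        ds = classify(rec, make_scores(), SD10)
        assert ds.labels == {"normal"}

    def test_missing_informant_never_raises(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            rec, scores = random_record_and_scores(rng)
            rec.informant_available = False
            for name in ("iqcode_mean", "bayer_iadl_mean", "informant_worsening",
                         "doctor_consult_cognition", "history_psychosis",
                         "onset_months_ago", "delirium_signs",
                         "delirium_duration_months"):
                setattr(rec, name, None)
            rec.bayer_item_difficulty = {k: None for k in rec.bayer_item_difficulty}
            rec.dexq_freq = {k: None for k in rec.dexq_freq}
            rec.informant_behavior_flags = {
                k: None for k in rec.informant_behavior_flags
            }
            for policy in ("permissive", "strict"):
                classify(rec, scores, SD10, policy)

    @pytest.mark.parametrize("policy", ["permissive", "strict"])
    def test_exclusivity_invariants(self, policy):
        """Across 10^4 random records the label sets obey the nosology rules."""
        rng = np.random.default_rng(11)
        for _ in range(10_000):
            rec, scores = random_record_and_scores(rng)
            labels = classify(rec, scores, SD10, policy).labels
            assert ("normal" in labels) == (labels == {"normal"})
            assert not {"dsm5_major", "dsm5_mild"} <= labels
            if "iwg_mci" in labels:
                assert "dsm4_dementia" not in labels
                assert "dsm5_major" not in labels

    def test_cutoff_nesting(self):
        """Mild diagnoses under 1.5 SD are a subset of those under 1.0 SD."""
        rng = np.random.default_rng(23)
        for _ in range(2_000):
            rec, scores = random_record_and_scores(rng)
            if "dsm5_mild" in classify(rec, scores, SD15).labels:
                assert "dsm5_mild" in classify(rec, scores, SD10).labels


@pytest.mark.parametrize("policy", ["permissive", "strict"])
@pytest.mark.parametrize("variant", [SD10, SD15])
def test_engine_matches_bruteforce_enumerator(policy, variant):
    """The engine agrees with a literal clause-by-clause enumeration."""
    rng = np.random.default_rng(7)
    for _ in range(1_000):
        rec, scores = random_record_and_scores(rng)
        got = classify(rec, scores, variant, policy).labels
        want = oracle_labels(rec, scores, policy, mild_upper=variant.mild_upper)
        assert got == want, rec.participant_id
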