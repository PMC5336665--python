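import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from ncdalgo.evaluation import (
    CrossTab2x2,
    DegenerateTableError,
    cohen_kappa,
    criteria_logit_roc,
    criterion_ppv_npv,
    crosstab,
    group_profile_contrast,
    kappa_bootstrap_ci,
    overlap_stats,
    rank_auc,
)

DEMENTIA_TABLE = CrossTab2x2(n_nn=297, n_ny=41, n_yn=3, n_yy=27)
MCI_TABLE = CrossTab2x2(n_nn=172, n_ny=52, n_yn=25, n_yy=119)


def labels_from_table(ct):
    ref = [0] * (ct.n_nn + ct.n_ny) + [1] * (ct.n_yn + ct.n_yy)
    cmp_ = [0] * ct.n_nn + [1] * ct.n_ny + [0] * ct.n_yn + [1] * ct.n_yy
    return ref, cmp_


class TestCrosstab:
    def test_identical_positives(self):
        assert crosstab([1] * 5, [1] * 5) == CrossTab2x2(0, 0, 0, 5)

    def test_complete_disagreement(self):
        assert crosstab([0] * 4, [1] * 4) == CrossTab2x2(0, 4, 0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            crosstab([0, 1], [0])

    def test_reconstructs_overlap_table(self):
        assert crosstab(*labels_from_table(DEMENTIA_TABLE)) == DEMENTIA_TABLE


class TestKappa:
    def test_dementia_overlap_kappa(self):
        assert cohen_kappa(DEMENTIA_TABLE) == pytest.approx(0.494, abs=1e-3)

    def test_mci_overlap_kappa(self):
        assert cohen_kappa(MCI_TABLE) == pytest.approx(0.575, abs=1e-3)

    def test_independent_raters_have_zero_kappa(self):
        assert cohen_kappa(CrossTab2x2(25, 25, 25, 25)) == pytest.approx(0.0)

    def test_degenerate_marginals(self):
        with pytest.raises(DegenerateTableError):
            cohen_kappa(CrossTab2x2(10, 0, 0, 0))

    def test_matches_hand_formula_exhaustively(self):
        """kappa agrees with a literal p_o/p_e computation on all small tables."""
        r = np.arange(31)
        a, b, c, d = [g.ravel() for g in np.meshgrid(r, r, r, r, indexing="ij")]
        keep = (a + b + c + d > 0) & (a + b + c + d <= 30)
        a, b, c, d = a[keep], b[keep], c[keep], d[keep]
        n = a + b + c + d
        po = (a + d) / n
        pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
        ok = pe < 1.0
        expected = (po[ok] - pe[ok]) / (1 - pe[ok])
        got = np.array(
            [
                cohen_kappa(CrossTab2x2(int(x), int(y), int(z), int(w)))
                for x, y, z, w in zip(a[ok], b[ok], c[ok], d[ok])
            ]
        )
        assert np.allclose(got, expected, atol=1e-12)

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 2, 60)
            y = (x + (rng.random(60) < 0.3)) % 2
            assert cohen_kappa(crosstab(x, y)) == pytest.approx(
                cohen_kappa_score(x, y), abs=1e-12
            )


class TestKappaBootstrap:
    def test_perfect_agreement(self):
        labels = [0] * 10 + [1] * 10
        stats = kappa_bootstrap_ci(labels, labels, n_boot=200, seed=1)
        assert stats.kappa == 1.0
        assert (stats.ci_low, stats.ci_high) == (1.0, 1.0)

    def test_deterministic_given_seed(self):
        ref, cmp_ = labels_from_table(MCI_TABLE)
        s1 = kappa_bootstrap_ci(ref, cmp_, n_boot=300, seed=42)
        s2 = kappa_bootstrap_ci(ref, cmp_, n_boot=300, seed=42)
        assert (s1.kappa, s1.se, s1.ci_low, s1.ci_high) == (
            s2.kappa,
            s2.se,
            s2.ci_low,
            s2.ci_high,
        )

    def test_bootstrap_ci_matches_analytic_se_scale(self):
        """CI of the dementia table brackets 0.494 with width ~ 2 x 1.96 x 0.063."""
        ref, cmp_ = labels_from_table(DEMENTIA_TABLE)
        stats = kappa_bootstrap_ci(ref, cmp_, n_boot=1000, seed=7)
        assert stats.ci_low <= 0.494 <= stats.ci_high
        width = stats.ci_high - stats.ci_low
        assert 0.6 * 2 * 1.96 * 0.063 < width < 1.6 * 2 * 1.96 * 0.063
        assert stats.se == pytest.approx(0.063, abs=0.02)


class TestRoc:
    def test_perfect_single_criterion(self):
        y = [0, 0, 1, 1, 0, 1]
        X = pd.DataFrame({"crit": y})
        res = criteria_logit_roc(X, y, n_boot=50, seed=0)
        assert res.auc == 1.0

    def test_perfect_ranking(self):
        assert rank_auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]) == 1.0

    def test_null_criteria_give_chance_auc(self):
        rng = np.random.default_rng(12)
        n = 2000
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({f"c{i}": rng.integers(0, 2, n) for i in range(4)})
        res = criteria_logit_roc(X, y, n_boot=100, seed=0)
        assert 0.46 < res.auc < 0.54

    def test_rank_auc_equals_pairwise_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            brute = wins / (len(pos) * len(neg))
            assert rank_auc(s, y) == pytest.approx(brute, abs=1e-12)
            assert rank_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_separation_falls_back_to_penalized(self):
        y = [0] * 20 + [1] * 20
        X = pd.DataFrame({"a": y, "b": [0, 1] * 20})
        res = criteria_logit_roc(X, y, n_boot=50, seed=0)
        assert res.penalized
        assert res.auc == 1.0

    def test_constant_columns_dropped(self):
        y = [0, 1, 0, 1, 1, 0]
        X = pd.DataFrame({"flat": [1] * 6, "ok": [0, 1, 0, 1, 1, 1]})
        res = criteria_logit_roc(X, y, n_boot=50, seed=0)
        assert res.dropped_columns == ["flat"]


class TestPpvNpv:
    def test_arithmetic(self):
        flags = [1] * 10 + [0] * 10
        diag = [1] * 8 + [0] * 2 + [1] * 1 + [0] * 9
        pv = criterion_ppv_npv(flags, diag)
        assert (pv.ppv, pv.npv) == (0.8, 0.9)

    def test_criterion_identical_to_diagnosis(self):
        d = [0, 1, 1, 0, 1]
        pv = criterion_ppv_npv(d, d)
        assert (pv.ppv, pv.npv) == (1.0, 1.0)

    def test_always_positive_criterion(self):
        diag = [1, 0, 1, 0]
        pv = criterion_ppv_npv([1, 1, 1, 1], diag)
        assert pv.ppv == 0.5  # prevalence
        assert pv.npv is None  # undefined, flagged rather than NaN


class TestOverlap:
    def test_dementia_overlap(self):
        stats = overlap_stats(DEMENTIA_TABLE)
        assert stats["pct_of_ref_captured"] == pytest.approx(90.0)
        assert stats["pct_increase"] == pytest.approx(126.7, abs=0.05)
        assert stats["n_additional"] == 41

    def test_mci_overlap(self):
        stats = overlap_stats(MCI_TABLE)
        assert stats["pct_of_ref_captured"] == pytest.approx(82.6, abs=0.05)
        assert stats["pct_increase"] == pytest.approx(18.75, abs=1e-9)
        assert stats["n_additional"] == 52

    def test_identical_labelings(self):
        stats = overlap_stats(CrossTab2x2(50, 0, 0, 25))
        assert stats["pct_of_ref_captured"] == 100.0
        assert stats["pct_increase"] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            cells = rng.integers(1, 40, 4)
            s1 = overlap_stats(CrossTab2x2(*map(int, cells)))
            s2 = overlap_stats(CrossTab2x2(*map(int, cells * 7)))
            assert s1["pct_of_ref_captured"] == pytest.approx(s2["pct_of_ref_captured"])
            assert s1["pct_increase"] == pytest.approx(s2["pct_increase"])


class TestGroupContrast:
    def test_same_distribution_rarely_significant(self):
        nonsig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"memory": rng.normal(0, 1, 400)})
            labels = ["a"] * 200 + ["b"] * 200
            res = group_profile_contrast(df, labels)
            nonsig += res.loc["memory", "p"] > 0.05
        assert nonsig >= 18  # ~alpha = .05 false positive rate

    def test_fixed_offset_recovered_exactly(self):
        df = pd.DataFrame({"memory": [0.0] * 5 + [1.0] * 5, "language": [0.0] * 10})
        res = group_profile_contrast(df, ["a"] * 5 + ["b"] * 5)
        assert res.loc["memory", "difference"] == pytest.approx(1.0)
        assert res.loc["language", "difference"] == pytest.approx(0.0)
        assert res.loc["language", "p"] == 1.0

    def test_singleton_group_rejected(self):
        df = pd.DataFrame({"memory": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            group_profile_contrast(df, ["a", "b", "b"])
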