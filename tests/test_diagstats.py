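import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsnquant import (coefficient_of_variation, confusion_stats,
                      icc_agreement, kruskal_wallis, mann_whitney,
                      roc_analysis, wilcoxon_signed)
from lsnquant.diagstats import (average_cv, cohort_report, nas_total,
                                reliability_label, render_markdown)
from lsnquant.errors import DomainError, ParameterError

from _oracles import (kruskal_h_by_ranks, mann_whitney_exact_p,
                      mann_whitney_u, wilcoxon_exact_p)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_textbook_h(self):
        # perfectly separated tertiles: H from the rank-sum formula is 7.2
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-10)
        want = kruskal_h_by_ranks([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(want, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1, 6) for m in (0, 1, 2)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestMannWhitney:
    def test_small_sample_exact(self):
        u, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert p == pytest.approx(mann_whitney_exact_p([1, 2], [3, 4]),
                                  abs=1e-12)

    def test_symmetry(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        assert mann_whitney(a, b)[1] == pytest.approx(mann_whitney(b, a)[1])

    def test_asymptotic_close_to_exact(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(100):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 6)
            _, p_exact = mann_whitney(a, b)  # 12 values, no ties -> exact
            res = __import__("scipy.stats", fromlist=["mannwhitneyu"]
                             ).mannwhitneyu(a, b, alternative="two-sided",
                                            method="asymptotic",
                                            use_continuity=True)
            worst = max(worst, abs(p_exact - res.pvalue))
        assert worst < 0.02

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = list(rng.permutation(20)[:3].astype(float))
            b = list(rng.permutation(40)[:3] + 100.0)
            u, p = mann_whitney(a, b)
            assert u == pytest.approx(mann_whitney_u(a, b))
            assert p == pytest.approx(mann_whitney_exact_p(a, b), abs=1e-12)


class TestWilcoxonSigned:
    def test_identical_pairs(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert wilcoxon_signed(a, a) == (0.0, 1.0)

    def test_all_positive_differences(self):
        a = np.array([2.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])
        w, p = wilcoxon_signed(a, b)
        assert w == 0.0  # min(W+, W-) convention
        assert p == pytest.approx(0.25, abs=1e-12)
        assert p == pytest.approx(wilcoxon_exact_p(a - b), abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 8)
        b = a + rng.normal(0.3, 0.5, 8)
        assert wilcoxon_signed(a, b)[1] == pytest.approx(
            wilcoxon_signed(b, a)[1], rel=1e-12)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            d = rng.permutation(30)[:6] + 1.0
            d *= np.sign(rng.normal(size=6))
            a = np.abs(d) + d
            b = np.abs(d)
            _, p = wilcoxon_signed(a, b)
            assert p == pytest.approx(wilcoxon_exact_p(d), abs=1e-12)


class TestCV:
    def test_constant_list_zero(self):
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0

    def test_published_average_of_group_cvs(self):
        assert round(average_cv([7.0, 13.0, 14.0]), 1) == 11.3

    def test_two_values_hand_computed(self):
        # {1, 3}: sample SD sqrt(2), mean 2 -> 70.7%
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(
            np.sqrt(2) / 2 * 100, rel=1e-12)

    def test_zero_mean_raises(self):
        with pytest.raises(DomainError):
            coefficient_of_variation([-1.0, 1.0])


class TestNasTotal:
    def test_ss_group_mean_components(self):
        assert nas_total(1.3, 1.0, 1.3) == pytest.approx(3.6)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            nas_total(4.0, 0.0, 0.0)


class TestICC:
    def test_identical_raters_icc_one(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = icc_agreement(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0)
        assert res.label == "excellent"

    def test_matches_shrout_fleiss_hand_anova(self):
        x = np.array([[9.0, 2.0], [6.0, 1.0], [8.0, 4.0],
                      [7.0, 1.0], [10.0, 5.0], [6.0, 2.0]])
        n, k = x.shape
        # hand ANOVA decomposition
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(axis=1, keepdims=True)
                - x.mean(axis=0, keepdims=True) + grand) ** 2).sum() / (
                    (n - 1) * (k - 1))
        want = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc_agreement(x)
        assert res.icc == pytest.approx(want, rel=1e-12)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        subj = rng.normal(0, 1, 10)
        x = np.column_stack([subj + rng.normal(0, 0.5, 10),
                             subj + 0.2 + rng.normal(0, 0.5, 10)])
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 2),
            "rater": np.tile(["A", "B"], 10),
            "score": x.ravel()})
        icc2 = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                        ratings="score").set_index("Type")
        key = "ICC(A,1)" if "ICC(A,1)" in icc2.index else "ICC2"
        ci_col = [c for c in icc2.columns if c.startswith("CI95")][0]
        res = icc_agreement(x)
        assert res.icc == pytest.approx(icc2.loc[key, "ICC"], rel=1e-9)
        assert res.p_value == pytest.approx(icc2.loc[key, "pval"], rel=1e-6)
        # pingouin rounds its interval to two decimals
        np.testing.assert_allclose(res.ci95, icc2.loc[key, ci_col], atol=0.005)

    def test_zero_subject_variance_flagged(self):
        x = np.tile([[3.0, 4.0]], (6, 1))
        res = icc_agreement(x)
        assert not res.defined
        assert np.isnan(res.icc)

    def test_reliability_band_for_0713(self):
        assert reliability_label(0.713) == "good"


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert 2.0 < res.cutoff < 3.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_auc_equals_u_identity(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n1, n0 = rng.integers(3, 15, size=2)
            scores = np.concatenate([rng.normal(1, 1, n1),
                                     rng.normal(0, 1, n0)])
            labels = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
            res = roc_analysis(scores, labels)
            u = mann_whitney_u(scores[labels == 1], scores[labels == 0])
            assert res.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            scores = rng.normal(size=200)
            labels = rng.integers(0, 2, size=200)
            if labels.min() == labels.max():
                continue
            res = roc_analysis(scores, labels)
            hits += abs(res.auc - 0.5) <= 0.1
        assert hits >= 95

    def test_matches_sklearn_auc(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(8)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(sk.roc_auc_score(labels, scores),
                                        abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(DomainError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestConfusionStats:
    @pytest.mark.parametrize("counts,expected", [
        ((21, 3, 4, 2), (91.3, 57.1, 87.5, 66.7)),    # F0 vs F1-F3
        ((11, 6, 12, 1), (91.7, 66.7, 64.7, 92.3)),   # F0-1 vs F2&F3
        ((10, 3, 8, 2), (83.3, 72.7, 76.9, 80.0)),    # F1 vs F2&F3
    ])
    def test_published_contingency_rows(self, counts, expected):
        got = confusion_stats(*counts)
        assert tuple(round(v, 1) for v in got) == expected

    def test_perfect_classifier(self):
        assert confusion_stats(5, 0, 5, 0) == (100.0, 100.0, 100.0, 100.0)

    def test_undefined_ppv_returned_missing(self):
        sens, spec, ppv, npv = confusion_stats(0, 0, 3, 2)
        assert ppv is None and npv is not None

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            confusion_stats(-1, 0, 1, 1)

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(1, 50), fn=st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_ranges_property(self, tp, fp, tn, fn):
        vals = confusion_stats(tp, fp, tn, fn)
        for v in vals:
            if v is not None:
                assert 0.0 <= v <= 100.0


def _toy_cohort(seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    layout = [("NC", "F0", 7, 1.30, 0.09), ("SS", "F1", 12, 1.54, 0.21),
              ("NASH", "F2", 6, 1.59, 0.23), ("NASH", "F3", 5, 1.70, 0.2)]
    i = 0
    for group, fib, n, mu, sd in layout:
        for _ in range(n):
            rows.append({"subject_id": f"s{i}", "group": group,
                         "fibrosis": fib,
                         "lsn_score": float(rng.normal(mu, sd))})
            i += 1
    return pd.DataFrame(rows)


class TestCohortReport:
    def test_constant_nc_row(self):
        df = _toy_cohort()
        df.loc[df.group == "NC", "lsn_score"] = 1.30
        report = cohort_report(df)
        nc = report["groups"]["summary"]["NC"]
        assert nc["mean"] == pytest.approx(1.30)
        assert nc["sd"] == 0.0 and nc["cv_percent"] == 0.0

    def test_significant_on_printed_effect_sizes(self):
        # cohorts drawn at the published group means/SDs should reject the
        # null in >= 80 of 100 seeds
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(1.30, 0.09, 7), rng.normal(1.54, 0.21, 12),
                      rng.normal(1.59, 0.23, 11)]
            _, p = kruskal_wallis(groups)
            hits += p < 0.05
        assert hits >= 80

    def test_merges_f2_f3(self):
        report = cohort_report(_toy_cohort())
        assert "F2&F3" in report["fibrosis"]["summary"]
        assert report["fibrosis"]["summary"]["F2&F3"]["n"] == 11

    def test_roc_sections_present(self):
        report = cohort_report(_toy_cohort())
        assert set(report["roc"]) == {"F0 vs F1-F3", "F0-1 vs F2&F3",
                                      "F1 vs F2&F3"}

    def test_markdown_has_parenthesised_raw_counts(self):
        import re
        md = render_markdown(cohort_report(_toy_cohort()))
        assert "Data in parentheses are raw data" in md
        assert re.search(r"\d+\.\d \(\d+/\d+\)", md)

    def test_empty_stratum_warns_and_skips(self):
        df = _toy_cohort()
        df = df[df.group != "NASH"]
        with pytest.warns(UserWarning):
            report = cohort_report(df)
        assert "NASH" not in report["groups"]["summary"]

    def test_invalid_grade_rejected(self):
        df = _toy_cohort()
        df.loc[0, "fibrosis"] = "F9"
        with pytest.raises(ParameterError):
            cohort_report(df)

    def test_holm_flag_defaults_off_and_monotone(self):
        df = _toy_cohort()
        plain = cohort_report(df)
        holm = cohort_report(df, holm=True)
        for label in plain["groups"]["pairwise"]:
            raw = plain["groups"]["pairwise"][label]["p"]
            assert "p_holm" not in plain["groups"]["pairwise"][label]
            assert holm["groups"]["pairwise"][label]["p_holm"] >= raw - 1e-15

    def test_monotone_rescaling_invariance(self):
        df = _toy_cohort()
        r1 = cohort_report(df)
        df2 = df.assign(lsn_score=np.exp(df["lsn_score"]))
        r2 = cohort_report(df2)
        assert r1["groups"]["kruskal"]["p"] == pytest.approx(
            r2["groups"]["kruskal"]["p"], rel=1e-9)
        for label in r1["groups"]["pairwise"]:
            assert r1["groups"]["pairwise"][label]["p"] == pytest.approx(
                r2["groups"]["pairwise"][label]["p"], rel=1e-9)
        for name in r1["roc"]:
            assert r1["roc"][name]["result"].auc == pytest.approx(
                r2["roc"][name]["result"].auc, abs=1e-12)
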