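"""Mann-Whitney comparison and ROC diagnostic-performance statistics."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import special
from scipy import stats as sps

from gammadwi import (
    analyze_cohort,
    auc_p_value,
    auc_se_hanley_mcneil,
    mann_whitney,
    roc_auc,
    roc_curve_points,
    select_cutoff,
)
from gammadwi.stats import validate_cohort


def pairwise_auc(scores, labels):
    """O(n^2) oracle: P(pos > neg) + 0.5 P(tie) over all pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2 of the 20 labelings

    def test_identical_groups(self):
        res = mann_whitney([5, 5, 5], [5, 5, 5])
        assert res.u_statistic == 4.5  # n^2/2 with midranks
        assert res.p_value == pytest.approx(1.0)

    def test_complementarity_with_ties(self, rng):
        for _ in range(20):
            a = rng.integers(0, 5, size=rng.integers(3, 10)).astype(float)
            b = rng.integers(0, 5, size=rng.integers(3, 10)).astype(float)
            ua = mann_whitney(a, b).u_statistic
            ub = mann_whitney(b, a).u_statistic
            assert ua + ub == pytest.approx(a.size * b.size)

    def test_exact_p_matches_scipy_without_ties(self, rng):
        # scipy's exact method is an independent oracle on tie-free data
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            ours = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
            assert ours.method == "exact"
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_matches_scipy(self, rng):
        a = rng.normal(0.0, 1.0, size=20)
        b = rng.normal(0.5, 1.0, size=25)
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, method="asymptotic", alternative="two-sided")
        assert ours.method == "normal"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 31))
            scores = rng.integers(0, 8, size=n).astype(float)
            labels = np.zeros(n, bool)
            labels[: max(1, n // 3)] = True
            rng.shuffle(labels)
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    def test_flip_direction_complements(self, rng):
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, size=20).astype(bool)
        labels[0], labels[1] = True, False
        a = roc_auc(scores, labels, "greater")
        assert roc_auc(scores, labels, "less") == pytest.approx(1.0 - a, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestHanleyMcNeil:
    def test_chance_level_closed_form(self):
        assert auc_se_hanley_mcneil(0.5, 10, 10) == pytest.approx(
            math.sqrt(0.0175), rel=1e-12
        )

    def test_perfect_auc_has_zero_se(self):
        assert auc_se_hanley_mcneil(1.0, 7, 13) == 0.0

    def test_direct_formula_re_evaluation(self):
        # independent spreadsheet-style recomputation at a published
        # operating point (AUC 0.891, 42 vs 24); magnitude ~0.04
        a, n1, n2 = 0.891, 42, 24
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (
            n1 * n2
        )
        assert auc_se_hanley_mcneil(a, n1, n2) == pytest.approx(
            math.sqrt(var), rel=1e-12
        )
        assert 0.02 < auc_se_hanley_mcneil(a, n1, n2) < 0.06


class TestAucPValue:
    def test_chance_auc_gives_p_one(self):
        assert auc_p_value(0.5, 0.07) == 1.0

    def test_z_196_gives_p_005(self):
        assert auc_p_value(0.5 + 1.96 * 0.1, 0.1) == pytest.approx(0.05, abs=1e-3)

    def test_erfc_oracle(self):
        z = (0.75 - 0.5) / 0.08
        expected = special.erfc(z / math.sqrt(2.0))
        assert auc_p_value(0.75, 0.08) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_se(self):
        assert auc_p_value(0.5, 0.0) == 1.0
        assert auc_p_value(1.0, 0.0) > 0.0


class TestSelectCutoff:
    def test_perfect_separation_balances_at_one(self):
        cutoff, sens, spec = select_cutoff([1, 2, 10, 11], [0, 0, 1, 1])
        assert 2 < cutoff < 10
        assert sens == 1.0 and spec == 1.0

    def test_symmetric_two_point_case(self):
        cutoff, sens, spec = select_cutoff([1, 1, 2, 2], [0, 0, 1, 1])
        assert cutoff == 1.5
        assert sens == 1.0 and spec == 1.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 20))
            scores = np.round(rng.normal(size=n), 1)
            labels = np.zeros(n, bool)
            labels[: max(1, n // 2)] = True
            rng.shuffle(labels)
            if labels.all() or not labels.any():
                continue
            cutoff, sens, spec = select_cutoff(scores, labels)
            pos, neg = scores[labels], scores[~labels]
            distinct = np.unique(scores)
            cands = [-math.inf, math.inf] + [
                0.5 * (distinct[i] + distinct[i + 1]) for i in range(len(distinct) - 1)
            ]
            best = min(
                abs(np.mean(pos > c) - np.mean(neg <= c)) for c in cands
            )
            assert abs(sens - spec) == pytest.approx(best, abs=1e-12)
            # reported operating point is attained by the returned cutoff
            assert sens == pytest.approx(np.mean(pos > cutoff))
            assert spec == pytest.approx(np.mean(neg <= cutoff))

    def test_direction_less_flips_roles(self):
        scores = [10.0, 9.0, 1.0, 2.0]
        labels = [1, 1, 0, 0]
        c_g, s_g, p_g = select_cutoff(scores, labels, "greater")
        c_l, s_l, p_l = select_cutoff(scores, [0, 0, 1, 1], "less")
        assert s_g == s_l == 1.0 and p_g == p_l == 1.0


class TestRocCurvePoints:
    def test_curve_area_matches_auc(self, rng):
        scores = rng.normal(size=30)
        labels = np.zeros(30, bool)
        labels[:12] = True
        rng.shuffle(labels)
        fpr, tpr = roc_curve_points(scores, labels)
        assert fpr[0] == 0.0 and fpr[-1] == 1.0
        area = np.trapezoid(tpr, fpr)
        assert area == pytest.approx(roc_auc(scores, labels), abs=1e-12)


def make_cohort(rng, shift=1.0, n_a=12, n_b=15):
    rows = []
    for g, n, mu in (("glioma", n_a, shift), ("meningioma", n_b, 0.0)):
        for i in range(n):
            for b in (1000.0, 2000.0):
                for p in ("f1", "adc"):
                    rows.append(
                        {
                            "subject_id": f"{g}{i}",
                            "group": g,
                            "b_value": b,
                            "parameter": p,
                            "value": rng.normal(mu if p == "f1" else -mu, 1.0),
                        }
                    )
    return pd.DataFrame(rows)


class TestAnalyzeCohort:
    def test_row_count(self, rng):
        res = analyze_cohort(make_cohort(rng))
        assert res.shape[0] == 2 * 2  # parameters x b-values

    def test_reported_auc_always_at_least_half(self, rng):
        res = analyze_cohort(make_cohort(rng, shift=2.0))
        assert (res["auc"] >= 0.5).all()
        # f1 is shifted up in the positive class, adc down: directions differ
        dirs = res.set_index("parameter")["direction"]
        assert set(dirs.loc["f1"]) == {"greater"}
        assert set(dirs.loc["adc"]) == {"less"}

    def test_constant_parameter_is_uninformative(self):
        rows = [
            {"subject_id": f"s{i}{g}", "group": g, "b_value": 1000.0,
             "parameter": "kappa", "value": 1.0}
            for g in ("a", "b")
            for i in range(5)
        ]
        res = analyze_cohort(pd.DataFrame(rows))
        assert res.loc[0, "auc"] == 0.5
        assert res.loc[0, "auc_p_value"] == 1.0

    def test_validation_rejects_bad_tables(self, rng):
        df = make_cohort(rng)
        with pytest.raises(ValueError):
            validate_cohort(df.assign(group="one_group_only"))
        with pytest.raises(ValueError):
            validate_cohort(df.drop(columns=["parameter"]))
        with pytest.raises(ValueError):
            analyze_cohort(df, positive_label="nonexistent")

    def test_sensitivity_specificity_attained(self, rng):
        res = analyze_cohort(make_cohort(rng, shift=1.5))
        assert ((res["sensitivity"] >= 0) & (res["sensitivity"] <= 1)).all()
        assert ((res["specificity"] >= 0) & (res["specificity"] <= 1)).all()
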