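"""Statistics layer: agreement, ICC, ROC and group comparisons.

Expected values come from independent oracles: exhaustive pairwise
enumeration for the AUC, a brute-force ANOVA decomposition for the ICC,
and hypergeometric enumeration for Fisher's test.
"""

import numpy as np
import pytest
from scipy import stats as sps

from cardiowarp.stats import (
    LabeledValues,
    PairedMeasurements,
    StatsError,
    bland_altman,
    coefficient_of_variation,
    group_compare,
    icc,
    roc,
    roc_curve_points,
)


def make_pairs(a, b):
    a = np.asarray(a, float)
    return PairedMeasurements(np.arange(len(a)), a, np.asarray(b, float))


class TestBlandAltman:
    # published agreement rows for longitudinal / radial RV peak strain:
    # bias -0.91 +/- 1.56 -> limits (-3.97, 2.15); 1.28 +/- 4.23 -> (-7.01, 9.57)
    @pytest.mark.parametrize(
        "bias,sd,lower,upper",
        [(-0.91, 1.56, -3.97, 2.15), (1.28, 4.23, -7.01, 9.57)],
    )
    def test_limits_match_published_arithmetic(self, bias, sd, lower, upper):
        assert round(bias - 1.96 * sd, 2) == lower
        assert round(bias + 1.96 * sd, 2) == upper

    def test_reconstructed_pairs_reproduce_printed_limits(self, rng):
        # build a sample with exactly the printed bias and SD, then check
        # the full computation path reproduces the printed limits
        d = rng.normal(0, 1, 9)
        d = (d - d.mean()) / d.std(ddof=1)  # mean 0, sd 1
        for bias, sd, lower, upper in [
            (-0.91, 1.56, -3.97, 2.15),
            (1.28, 4.23, -7.01, 9.57),
        ]:
            diffs = bias + sd * d
            b = rng.normal(20, 5, 9)
            res = bland_altman(make_pairs(b + diffs, b))
            assert res["bias"] == pytest.approx(bias, abs=1e-12)
            assert res["sd"] == pytest.approx(sd, abs=1e-12)
            assert round(res["lower"], 2) == lower
            assert round(res["upper"], 2) == upper

    def test_identical_raters_are_in_perfect_agreement(self):
        res = bland_altman(make_pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res == {"bias": 0.0, "sd": 0.0, "lower": 0.0, "upper": 0.0}

    def test_antisymmetry_under_rater_swap(self, rng):
        a, b = rng.normal(10, 3, 12), rng.normal(10, 3, 12)
        r1 = bland_altman(make_pairs(a, b))
        r2 = bland_altman(make_pairs(b, a))
        assert r1["bias"] == pytest.approx(-r2["bias"])
        assert r1["lower"] == pytest.approx(-r2["upper"])
        assert r1["upper"] == pytest.approx(-r2["lower"])

    def test_rejects_single_pair(self):
        with pytest.raises(StatsError):
            make_pairs([1.0], [2.0])


class TestCV:
    def test_zero_for_identical_raters(self):
        assert coefficient_of_variation(make_pairs([5.0, 7.0], [5.0, 7.0])) == 0.0

    def test_scale_invariance(self, rng):
        a, b = rng.normal(15, 2, 10), rng.normal(15, 2, 10)
        cv1 = coefficient_of_variation(make_pairs(a, b))
        cv2 = coefficient_of_variation(make_pairs(3 * a, 3 * b))
        assert cv1 == pytest.approx(cv2)

    def test_matches_hand_computation(self):
        a = np.array([10.0, 12.0, 14.0])
        b = np.array([11.0, 11.0, 15.0])
        d = a - b
        expected = np.std(d, ddof=1) / np.mean(np.abs((a + b) / 2)) * 100
        assert coefficient_of_variation(make_pairs(a, b)) == pytest.approx(expected)

    def test_zero_mean_magnitude_is_an_error(self):
        with pytest.raises(StatsError):
            coefficient_of_variation(make_pairs([1.0, -1.0], [-1.0, 1.0]))


def icc21_bruteforce(a, b):
    """Independent oracle: full two-way ANOVA decomposition by loops."""
    Y = np.column_stack([a, b])
    n, k = Y.shape
    grand = Y.mean()
    ms_r = k * sum((Y[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    ms_c = n * sum((Y[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    ss_e = sum(
        (Y[i, j] - Y[i].mean() - Y[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    ms_e = ss_e / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


class TestICC:
    def test_identical_raters_give_unity(self):
        res = icc(make_pairs([1.0, 5.0, 9.0, 2.0], [1.0, 5.0, 9.0, 2.0]))
        assert res["icc"] == pytest.approx(1.0)

    def test_matches_bruteforce_anova_on_hand_table(self):
        a = np.array([9.0, 10.0, 12.0, 15.0])
        b = np.array([10.0, 11.0, 13.0, 14.0])
        res = icc(make_pairs(a, b))
        assert res["icc"] == pytest.approx(icc21_bruteforce(a, b), abs=1e-10)

    def test_independent_raters_drift_to_zero(self, rng):
        a = rng.normal(0, 1, 4000)
        b = rng.normal(0, 1, 4000)
        res = icc(make_pairs(a, b))
        assert abs(res["icc"]) < 0.05

    def test_never_exceeds_one(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = a + rng.normal(0, 0.5, 8)
            assert icc(make_pairs(a, b))["icc"] <= 1.0 + 1e-12

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        a = np.array([-15.2, -9.4, -4.9, -14.8, -10.1, -6.2, -16.0, -8.8, -5.5])
        b = a + np.array([0.4, -0.6, 0.2, 0.9, -0.3, 0.1, -0.5, 0.8, 0.0])
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(9), 2),
                "rater": np.tile([0, 1], 9),
                "y": np.column_stack([a, b]).ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="y")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        res = icc(make_pairs(a, b))
        assert res["icc"] == pytest.approx(float(row["ICC"]), abs=1e-8)
        lo, hi = row["CI95"]
        assert res["ci_lower"] == pytest.approx(lo, abs=0.02)
        assert res["ci_upper"] == pytest.approx(hi, abs=0.02)


def auc_bruteforce(pos, neg):
    """Mann-Whitney count over all pairs ('smaller magnitude = diseased')."""
    pos, neg = np.abs(pos), np.abs(neg)
    wins = sum(
        1.0 if p < n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        lv = LabeledValues(
            np.arange(8),
            np.array([-16.0, -15.0, -17.0, -14.5, -8.0, -7.0, -9.0, -6.5]),
            np.array(["control"] * 4 + ["HFpEF"] * 4),
        )
        res = roc(lv, positive_class="HFpEF")
        assert res["auc"] == 1.0
        assert res["sensitivity"] == 1.0
        assert res["specificity"] == 1.0

    def test_auc_equals_mannwhitney_bruteforce(self, rng):
        for _ in range(5):
            vals = rng.normal(-12, 4, 24)
            labels = np.array(["control"] * 12 + ["HFpEF"] * 12)
            lv = LabeledValues(np.arange(24), vals, labels)
            res = roc(lv, positive_class="HFpEF")
            pos = np.abs(vals[12:])
            neg = np.abs(vals[:12])
            assert res["auc"] == pytest.approx(auc_bruteforce(pos, neg), abs=1e-12)

    def test_auc_equals_trapezoid_of_curve(self, rng):
        vals = rng.normal(-10, 3, 30)
        labels = np.array(["control"] * 15 + ["HFpEF"] * 15)
        lv = LabeledValues(np.arange(30), vals, labels)
        fpr, tpr = roc_curve_points(lv, "HFpEF")
        assert roc(lv, "HFpEF")["auc"] == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)

    def test_shuffled_labels_are_chance_level(self, rng):
        vals = rng.normal(-10, 3, 600)
        labels = rng.permutation(np.array(["control", "HFpEF"] * 300))
        res = roc(LabeledValues(np.arange(600), vals, labels), "HFpEF")
        assert abs(res["auc"] - 0.5) < 0.07

    def test_invariance_under_monotone_transform(self, rng):
        vals = np.abs(rng.normal(12, 4, 20)) + 0.1
        labels = np.array(["control"] * 10 + ["HFpEF"] * 10)
        a1 = roc(LabeledValues(np.arange(20), vals, labels), "HFpEF")["auc"]
        a2 = roc(LabeledValues(np.arange(20), vals**3, labels), "HFpEF")["auc"]
        assert a1 == pytest.approx(a2)

    def test_single_class_is_an_error(self):
        with pytest.raises(StatsError):
            roc(
                LabeledValues(np.arange(3), np.ones(3), np.array(["a"] * 3)),
                positive_class="a",
                control_class="b",
            )

    def test_sklearn_cross_check(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        vals = rng.normal(-11, 4, 40)
        labels = np.array(["control"] * 20 + ["HFpEF"] * 20)
        res = roc(LabeledValues(np.arange(40), vals, labels), "HFpEF")
        y = (labels == "HFpEF").astype(int)
        # smaller magnitude = diseased -> score is -|value|
        ref = sk.roc_auc_score(y, -np.abs(vals))
        assert res["auc"] == pytest.approx(ref, abs=1e-12)


class TestGroupCompare:
    def test_identical_groups_rank_test_p_near_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 2.5, 3.5])
        res = group_compare(a, a.copy())
        assert res["p"] > 0.9

    def test_separated_groups_detected(self, rng):
        a = rng.normal(0, 1, 80)
        b = rng.normal(3, 1, 80)
        assert group_compare(a, b)["p"] < 0.05

    def test_normality_gate_chooses_rank_test_for_skewed_data(self, rng):
        a = rng.lognormal(0, 1.5, 50)
        b = rng.lognormal(0, 1.5, 50)
        assert group_compare(a, b)["test"] == "mannwhitney_u"

    def test_fisher_exact_matches_hypergeometric_enumeration(self):
        # 2x2 table (5,0 / 0,5): two-sided p from exhaustive enumeration
        # over all tables with the same margins
        table = [(5, 0), (0, 5)]
        res = group_compare(*table, categorical=True)
        # enumerate: row sums 5,5; col sums 5,5; a ranges 0..5
        probs = [sps.hypergeom.pmf(a, 10, 5, 5) for a in range(6)]
        p_obs = probs[5]
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert res["p"] == pytest.approx(expected, rel=1e-10)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=3,
            max_size=12,
        ),
        st.floats(min_value=-5, max_value=5, allow_nan=False),
    )
    def test_bland_altman_shift_property(values, shift):
        """Adding a constant offset to rater A shifts bias and both limits
        by exactly that constant and leaves the SD unchanged."""
        a = np.asarray(values)
        b = a + np.linspace(-1, 1, len(a))
        r0 = bland_altman(make_pairs(a, b))
        r1 = bland_altman(make_pairs(a + shift, b))
        assert r1["bias"] == pytest.approx(r0["bias"] + shift, abs=1e-9)
        assert r1["sd"] == pytest.approx(r0["sd"], abs=1e-9)
        assert r1["lower"] == pytest.approx(r0["lower"] + shift, abs=1e-9)
        assert r1["upper"] == pytest.approx(r0["upper"] + shift, abs=1e-9)
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass
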