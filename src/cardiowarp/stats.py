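"""Reproducibility and discrimination statistics for peak-strain tables.

Bland-Altman agreement, coefficient of variation, two-way
absolute-agreement intraclass correlation (single measurement) with an
F-distribution confidence interval, empirical ROC analysis with a
Youden-index cutoff, and normality-gated two-group comparisons — the
statistics layer used to judge observer reproducibility of the strain
pipeline and the discriminative value of peak strains.

ROC analysis runs on strain *magnitudes* with "smaller magnitude =
diseased" polarity, so cutoffs for negative-valued shortening strains
come out as positive numbers comparable across components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class PairedMeasurements:
    """Paired observations (two observers or two sessions), units %."""

    subject: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, float)
        self.b = np.asarray(self.b, float)
        self.subject = np.asarray(self.subject)
        if len(self.a) != len(self.b) or len(self.a) != len(self.subject):
            raise StatsError("paired measurements need equal lengths")
        if len(self.a) < 2:
            raise StatsError("need at least 2 paired measurements")

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass
class LabeledValues:
    """Per-subject values with class labels (e.g. control / HFpEF / HFrEF)."""

    subject: np.ndarray
    value: np.ndarray
    label: np.ndarray

    def __post_init__(self):
        self.value = np.asarray(self.value, float)
        self.label = np.asarray(self.label)
        self.subject = np.asarray(self.subject)


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def bland_altman(pairs: PairedMeasurements) -> dict:
    """Bias, SD of differences and 95% limits of agreement (bias +/- 1.96 SD)."""
    d = pairs.a - pairs.b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return {
        "bias": bias,
        "sd": sd,
        "lower": bias - 1.96 * sd,
        "upper": bias + 1.96 * sd,
    }


def coefficient_of_variation(pairs: PairedMeasurements) -> float:
    """CV%% = SD of paired differences over the mean absolute pair mean.

    One of several CV conventions in agreement studies; chosen because
    it is scale-invariant and symmetric in the two raters.
    """
    d = pairs.a - pairs.b
    m = np.abs((pairs.a + pairs.b) / 2.0)
    denom = float(np.mean(m))
    if denom <= 0:
        raise StatsError("CV undefined: zero mean magnitude")
    return float(np.std(d, ddof=1) / denom * 100.0)


def icc(pairs: PairedMeasurements, ci: float = 0.95) -> dict:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Mean-squares decomposition of the n x 2 table (subjects x raters):

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    with MS_R rows (subjects), MS_C columns (raters), MS_E residual.
    The confidence interval uses the standard F-distribution bounds
    (McGraw & Wong).
    """
    Y = np.column_stack([pairs.a, pairs.b])
    n, k = Y.shape
    if n < 3:
        raise StatsError("ICC needs at least 3 subjects")
    grand = Y.mean()
    row_m = Y.mean(axis=1)
    col_m = Y.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0 and ms_e <= 0:
        raise StatsError("ICC undefined: degenerate variance")
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if abs(denom) < 1e-300:
        raise StatsError("ICC undefined: degenerate variance")
    value = (ms_r - ms_e) / denom

    alpha = 1.0 - ci
    if ms_e <= 0:  # perfect agreement; CI collapses
        return {"icc": float(value), "ci_lower": 1.0, "ci_upper": 1.0}
    # McGraw & Wong (1996) approximate bounds for ICC(A,1), with the
    # Satterthwaite degrees of freedom v
    a = k * value / (n * (1.0 - value))
    b = 1.0 + k * value * (n - 1) / (n * (1.0 - value))
    v_num = (a * ms_c + b * ms_e) ** 2
    v_den = (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (
        n
        * (ms_r - f_l * ms_e)
        / (f_l * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r)
    )
    upper = (
        n
        * (f_u * ms_r - ms_e)
        / (k * ms_c + (k * n - k - n) * ms_e + n * f_u * ms_e)
    )
    return {
        "icc": float(value),
        "ci_lower": float(lower),
        "ci_upper": float(min(upper, 1.0)),
    }


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc(values: LabeledValues, positive_class, control_class=None) -> dict:
    """Empirical ROC on strain magnitudes; smaller magnitude = diseased.

    Scans every threshold on |value|; a subject tests positive (diseased)
    when its magnitude falls below the threshold.  AUC is the trapezoid
    area (identical to the Mann-Whitney U statistic over n1*n2); the
    reported cutoff maximizes Youden's J = sens + spec - 1 (ties go to
    the lower cutoff), with sensitivity/specificity evaluated there.
    """
    labels = values.label
    if control_class is None:
        others = [l for l in np.unique(labels) if l != positive_class]
        if len(others) != 1:
            raise StatsError("ambiguous control class; pass control_class")
        control_class = others[0]
    pos = np.abs(values.value[labels == positive_class])
    neg = np.abs(values.value[labels == control_class])
    if len(pos) == 0 or len(neg) == 0:
        raise StatsError("both classes must be present")

    # candidate thresholds: all observed magnitudes (and one above all)
    cands = np.unique(np.concatenate([pos, neg]))
    cands = np.concatenate([cands, [cands.max() + 1.0]])
    best = None
    for c in cands:
        sens = np.mean(pos < c)  # diseased below cutoff
        spec = np.mean(neg >= c)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), float(sens), float(spec))
    # AUC by Mann-Whitney on the "smaller = positive" orientation
    diff = pos[:, None] - neg[None, :]
    auc = float(np.mean((diff < 0) + 0.5 * (diff == 0)))
    return {
        "auc": auc,
        "cutoff": best[1],
        "sensitivity": best[2],
        "specificity": best[3],
        "youden_j": best[0],
        "n_positive": int(len(pos)),
        "n_control": int(len(neg)),
    }


def roc_curve_points(values: LabeledValues, positive_class, control_class=None):
    """(FPR, TPR) points of the empirical ROC, for plots and trapezoid AUC."""
    labels = values.label
    if control_class is None:
        others = [l for l in np.unique(labels) if l != positive_class]
        control_class = others[0]
    pos = np.abs(values.value[labels == positive_class])
    neg = np.abs(values.value[labels == control_class])
    cands = np.concatenate([[-np.inf], np.unique(np.concatenate([pos, neg])), [np.inf]])
    tpr = [np.mean(pos < c) for c in cands]
    fpr = [np.mean(neg < c) for c in cands]
    return np.asarray(fpr), np.asarray(tpr)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def group_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    categorical: bool = False,
    normality_alpha: float = 0.05,
) -> dict:
    """Two-group comparison with a normality-gated test choice.

    Continuous variables: Shapiro-Wilk on each group at
    ``normality_alpha``; both normal -> independent t-test, otherwise
    Mann-Whitney U.  Categorical variables (2x2 counts given as
    ``values_a``=(a, b) and ``values_b``=(c, d)) use Fisher's exact
    test.  The chosen test is recorded in the result.
    """
    if categorical:
        table = np.array([values_a, values_b], dtype=int)
        _, p = sps.fisher_exact(table)
        return {"test": "fisher_exact", "p": float(p)}
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need n >= 2 per group")
    if len(a) >= 3 and len(b) >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0:
        normal = (
            sps.shapiro(a).pvalue > normality_alpha
            and sps.shapiro(b).pvalue > normality_alpha
        )
    else:
        normal = False
    if normal:
        res = sps.ttest_ind(a, b)
        return {"test": "t", "p": float(res.pvalue)}
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "mannwhitney_u", "p": float(res.pvalue)}


def agreement_table(pairs_by_variable: dict[str, PairedMeasurements]) -> "pd.DataFrame":
    """Reproducibility summary (bias, limits, CV%, ICC) per variable."""
    import pandas as pd

    rows = []
    for name, pairs in pairs_by_variable.items():
        ba = bland_altman(pairs)
        entry = {
            "variable": name,
            "bias": ba["bias"],
            "sd": ba["sd"],
            "loa_lower": ba["lower"],
            "loa_upper": ba["upper"],
            "cv_percent": coefficient_of_variation(pairs),
        }
        try:
            ic = icc(pairs)
            entry.update(
                icc=ic["icc"], icc_ci_lower=ic["ci_lower"], icc_ci_upper=ic["ci_upper"]
            )
        except StatsError:
            entry.update(icc=np.nan, icc_ci_lower=np.nan, icc_ci_upper=np.nan)
        rows.append(entry)
    return pd.DataFrame(rows)
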