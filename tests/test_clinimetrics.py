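"""Validation statistics against independent oracles and known cases."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from gloverom.clinimetrics import (
    composite_roc,
    correlation,
    icc_absolute_agreement,
    lmm_longitudinal,
    roc_analysis,
    slope_comparison,
    weighted_kappa,
    welch_from_samples,
    welch_from_summaries,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def icc_a1_anova_oracle(m):
    """ICC(A,1) via an independent two-way ANOVA fit (statsmodels OLS)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    n, k = m.shape
    long = pd.DataFrame({
        "y": m.ravel(),
        "subject": np.repeat(np.arange(n), k).astype(str),
        "session": np.tile(np.arange(k), n).astype(str),
    })
    tbl = sm.stats.anova_lm(ols("y ~ C(subject) + C(session)", long).fit(), typ=2)
    msr = tbl.loc["C(subject)", "sum_sq"] / tbl.loc["C(subject)", "df"]
    msc = tbl.loc["C(session)", "sum_sq"] / tbl.loc["C(session)", "df"]
    mse = tbl.loc["Residual", "sum_sq"] / tbl.loc["Residual", "df"]
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def auc_rank_oracle(scores, labels, lower_is_positive=True):
    """AUC as the Mann–Whitney statistic U/(n+ · n−), ties counted half."""
    s = -np.asarray(scores, float) if lower_is_positive else np.asarray(scores, float)
    labels = np.asarray(labels)
    ranks = stats.rankdata(s)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def kappa_hand_oracle(table):
    """Weighted kappa from explicit weighted agreement sums on a k×k table."""
    table = np.asarray(table, float)
    k = table.shape[0]
    n = table.sum()
    w = 1 - np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    po = sum(w[i, j] * table[i, j] for i in range(k) for j in range(k)) / n
    pe = sum(
        w[i, j] * table[i, :].sum() * table[:, j].sum() / n**2
        for i in range(k) for j in range(k)
    )
    return (po - pe) / (1 - pe)


def table_to_ratings(table):
    a, b = [], []
    for i, row in enumerate(np.asarray(table, int)):
        for j, count in enumerate(row):
            a += [i] * count
            b += [j] * count
    return a, b


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class TestICC:
    def test_identical_sessions_are_perfect_agreement(self):
        m = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0], [3.0, 3.0]])
        res = icc_absolute_agreement(m)
        assert res.estimate == pytest.approx(1.0, abs=1e-12)
        assert res.rating == "excellent"

    def test_toy_matrix_matches_anova_oracle(self):
        m = np.array([[7.0, 9.0], [1.0, 2.0], [6.0, 4.0], [8.0, 8.5]])
        res = icc_absolute_agreement(m)
        assert res.estimate == pytest.approx(icc_a1_anova_oracle(m), abs=1e-10)

    def test_random_matrices_match_anova_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(5, 9)
            k = rng.integers(2, 5)
            m = rng.normal(5, 2, size=(n, k))
            res = icc_absolute_agreement(m)
            assert res.estimate == pytest.approx(icc_a1_anova_oracle(m), abs=1e-9)

    def test_matches_pingouin_icc2_with_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        m = rng.normal(10, 3, size=(8, 3))
        long = pd.DataFrame({
            "y": m.ravel(),
            "subject": np.repeat(np.arange(8), 3),
            "session": np.tile(np.arange(3), 8),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="session",
                                 ratings="y").set_index("Type").loc["ICC(A,1)"]
        res = icc_absolute_agreement(m)
        assert res.estimate == pytest.approx(ref["ICC"], abs=1e-9)
        # pingouin prints the CI rounded to 2 decimals
        assert res.ci95 == pytest.approx(tuple(ref["CI95"]), abs=6e-3)

    def test_session_offset_penalized_vs_consistency(self):
        """Absolute agreement punishes a constant session shift."""
        rng = np.random.default_rng(1)
        base = rng.normal(50, 10, size=8)
        m = np.column_stack([base, base + 15.0])
        res = icc_absolute_agreement(m)
        # consistency ICC of the same data is exactly 1 (perfect rank order)
        assert res.estimate < 1.0 - 1e-6

    def test_missing_rows_dropped_and_counted(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0], [4.0, 5.0], [7.0, 6.0],
                      [2.0, 2.5]])
        res = icc_absolute_agreement(m)
        assert res.n_dropped == 1
        assert res.n_subjects == 4

    def test_zero_variance_undefined(self):
        with pytest.raises(ZeroDivisionError):
            icc_absolute_agreement(np.full((4, 2), 3.0))

    def test_icc_approaches_one_as_noise_vanishes(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 10, size=12)
        last = 0.0
        for noise in (5.0, 1.0, 0.1):
            m = base[:, None] + rng.normal(0, noise, size=(12, 2))
            est = icc_absolute_agreement(m).estimate
            assert est > last
            last = est
        assert last > 0.99


# ---------------------------------------------------------------------------
# weighted kappa
# ---------------------------------------------------------------------------

class TestWeightedKappa:
    def test_identical_ratings(self):
        res = weighted_kappa([0, 1, 2, 3, 1, 2], [0, 1, 2, 3, 1, 2])
        assert res.estimate == pytest.approx(1.0)
        assert res.rating == "almost perfect"

    def test_two_categories_equals_unweighted(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        res = weighted_kappa(a, b)
        assert res.estimate == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_toy_table_matches_hand_sum(self):
        table = [[11, 2, 0, 0], [1, 9, 3, 0], [0, 2, 8, 1], [0, 0, 1, 12]]
        a, b = table_to_ratings(table)
        res = weighted_kappa(a, b)
        assert res.estimate == pytest.approx(kappa_hand_oracle(table), abs=1e-12)

    def test_matches_sklearn_linear_weights(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 5, 60)
        b = np.clip(a + rng.integers(-1, 2, 60), 0, 4)
        res = weighted_kappa(a, b, categories=range(5))
        assert res.estimate == pytest.approx(
            cohen_kappa_score(a, b, weights="linear"), abs=1e-12
        )

    def test_order_preserving_relabel_invariance(self):
        a = [0, 1, 2, 2, 1, 0, 2]
        b = [0, 2, 2, 1, 1, 0, 2]
        base = weighted_kappa(a, b, categories=[0, 1, 2]).estimate
        relab = weighted_kappa([x * 10 for x in a], [x * 10 for x in b],
                               categories=[0, 10, 20]).estimate
        assert base == pytest.approx(relab, abs=1e-12)

    def test_single_category_rater_undefined(self):
        with pytest.raises(ZeroDivisionError):
            weighted_kappa([1, 1, 1], [1, 1, 1])


# ---------------------------------------------------------------------------
# Welch
# ---------------------------------------------------------------------------

class TestWelch:
    def test_equal_means_give_p_one(self):
        res = welch_from_summaries(10.0, 2.0, 8, 10.0, 3.0, 9)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_raw_samples_equal_their_summaries(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(30, 10, 14)
        x2 = rng.normal(45, 6, 11)
        raw = welch_from_samples(x1, x2)
        summ = welch_from_summaries(
            x1.mean(), x1.std(ddof=1), 14, x2.mean(), x2.std(ddof=1), 11
        )
        assert raw.p == pytest.approx(summ.p, abs=1e-14)
        assert raw.df == pytest.approx(summ.df, abs=1e-10)

    def test_df_bounded_by_pooled_df(self):
        res = welch_from_summaries(10, 4.0, 10, 14, 1.5, 12)
        assert res.df <= 10 + 12 - 2


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

class TestROC:
    def test_perfect_separation(self):
        scores = np.r_[np.arange(10.0), np.arange(100.0, 110.0)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_mann_whitney_with_ties(self):
        from .test_clinimetrics import auc_rank_oracle
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(8, 30)
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            res = roc_analysis(scores, labels)
            assert res.auc == pytest.approx(
                auc_rank_oracle(scores, labels), abs=1e-12
            )

    def test_cutoff_rule_reproduces_reported_operating_point(self):
        rng = np.random.default_rng(2)
        scores = np.r_[rng.normal(30, 10, 14), rng.normal(47, 7, 11)]
        labels = np.r_[np.ones(14), np.zeros(11)].astype(int)
        res = roc_analysis(scores, labels)
        pred = scores <= res.cutoff
        sens = (pred & (labels == 1)).sum() / 14
        spec = (~pred & (labels == 0)).sum() / 11
        assert sens == pytest.approx(res.sensitivity)
        assert spec == pytest.approx(res.specificity)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1.0, 2.0], [1, 1])


class TestCompositeROC:
    def test_single_feature_identical_to_plain_roc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(50, 15, 25)
        labels = rng.integers(0, 2, 25)
        labels[:3], labels[-3:] = 1, 0
        plain = roc_analysis(scores, labels)
        comp = composite_roc(pd.DataFrame({"f": scores}), labels, {"f": True})
        assert comp.auc == pytest.approx(plain.auc, abs=1e-12)

    def test_duplicated_feature_changes_nothing(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=20)
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        one = composite_roc(pd.DataFrame({"a": scores}), labels, {"a": True})
        two = composite_roc(pd.DataFrame({"a": scores, "b": scores}), labels,
                            {"a": True, "b": True})
        assert one.auc == pytest.approx(two.auc, abs=1e-12)

    def test_sign_alignment_of_inverted_feature(self):
        rng = np.random.default_rng(5)
        good = np.r_[rng.normal(30, 5, 10), rng.normal(50, 5, 10)]
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        direct = composite_roc(pd.DataFrame({"f": good}), labels, {"f": True})
        flipped = composite_roc(pd.DataFrame({"f": -good}), labels, {"f": False})
        assert direct.auc == pytest.approx(flipped.auc, abs=1e-12)

    def test_subject_without_features_excluded_with_warning(self):
        df = pd.DataFrame({"f": [1.0, 2.0, np.nan, 4.0, 0.5, 3.0]})
        labels = [1, 0, 1, 0, 1, 0]
        with pytest.warns(UserWarning, match="no available feature"):
            res = composite_roc(df, labels, {"f": True})
        assert res.n_positive + res.n_negative == 5


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def tau_brute_force(x, y):
    """Tau-b by exhaustive concordant/discordant pair counting."""
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[j] - x[i])
            sy = np.sign(y[j] - y[i])
            if sx == 0 and sy == 0:
                tx += 1
                ty += 1
            elif sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / np.sqrt((n0 - tx) * (n0 - ty))


class TestCorrelation:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert correlation(x, x, "pearson").estimate == pytest.approx(1.0)
        assert correlation(x, x, "kendall").estimate == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        res = correlation(x, -x, "pearson")
        assert res.estimate == pytest.approx(-1.0)
        assert res.effect_size == "strong"

    def test_tau_b_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.integers(0, 4, 12).astype(float)
            y = rng.integers(0, 4, 12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = correlation(x, y, "kendall")
            assert res.estimate == pytest.approx(tau_brute_force(x, y),
                                                 abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.2, 1.9, 3.0, 4.2, np.nan]
        assert correlation(x, y).n == 3

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def longitudinal_frame(n_subjects=20, slope=0.0, noise_sd=1.0,
                       subject_sd=5.0, seed=0):
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(50, subject_sd, n_subjects)
    rows = []
    for i in range(n_subjects):
        for t in range(4):
            rows.append({
                "subject_id": f"S{i}",
                "timepoint": float(t),
                "value": intercepts[i] + slope * t + rng.normal(0, noise_sd),
            })
    return pd.DataFrame(rows)


class TestLMM:
    def test_programmed_slope_recovered(self):
        df = longitudinal_frame(slope=2.0, noise_sd=0.3, seed=1)
        res = lmm_longitudinal(df, categorical_time=False)
        slope = res.fixed_effects.loc["_time_num", "estimate"]
        assert slope == pytest.approx(2.0, rel=0.10)
        assert res.time_p < 0.001

    def test_subject_constant_data_splits_variance(self):
        """All variance between subjects ⇒ random intercept ≈ between-subject
        variance and residual ≈ 0."""
        df = longitudinal_frame(slope=0.0, noise_sd=0.01, subject_sd=8.0,
                                seed=2)
        res = lmm_longitudinal(df, categorical_time=False)
        assert res.residual_var < 1e-3
        assert res.random_intercept_var == pytest.approx(
            df.groupby("subject_id")["value"].mean().var(), rel=0.1
        )

    def test_categorical_time_reports_holm_pairwise(self):
        df = longitudinal_frame(slope=0.0, noise_sd=1.0, seed=3)
        res = lmm_longitudinal(df, categorical_time=True)
        assert res.pairwise is not None
        assert len(res.pairwise) == 6      # 4 timepoints → 6 contrasts
        assert (res.pairwise["p_holm"] >= res.pairwise["p"] - 1e-12).all()

    def test_too_few_subjects_rejected(self):
        df = longitudinal_frame(n_subjects=3)
        with pytest.raises(ValueError, match="5 subjects"):
            lmm_longitudinal(df)


class TestSlopeComparison:
    def test_identical_instruments_zero_interaction(self):
        df = longitudinal_frame(slope=1.0, seed=4).rename(columns={"value": "a"})
        df["b"] = df["a"]
        res = slope_comparison(df, "a", "b")
        inter = [i for i in res.fixed_effects.index if "_time_num:" in i][0]
        assert res.fixed_effects.loc[inter, "estimate"] == pytest.approx(
            0.0, abs=1e-8
        )

    def test_programmed_differential_slope_detected(self):
        rng = np.random.default_rng(8)
        df = longitudinal_frame(n_subjects=30, slope=0.0, noise_sd=0.5, seed=8)
        df = df.rename(columns={"value": "a"})
        df["b"] = df["a"] + 3.0 * df["timepoint"] + rng.normal(0, 0.5, len(df))
        res = slope_comparison(df, "a", "b")
        assert res.interaction_p < 0.01
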