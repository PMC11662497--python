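"""Clinimetric validation statistics for repeated clinical measures.

The battery mirrors standard outcome-measure validation practice in
neuromuscular research:

* test–retest reliability — two-way, absolute-agreement, single-measure
  intraclass correlation (McGraw & Wong "A,1" form, rated per Koo & Li) for
  metric scores, and linearly weighted Cohen's kappa (rated per Landis &
  Koch) for ordinal scores;
* group discrimination — Welch's unequal-variance t-test and nonparametric
  ROC analysis with a Youden-index cutoff, including a composite z-score
  ROC pooling several features;
* construct validity — Pearson correlation (metric) and Kendall tau-b
  (ordinal/non-normal) with Cohen effect-size bands;
* longitudinal stability — linear mixed models with time fixed and subject
  random (REML), including a slope-comparison model with a
  time × instrument interaction on z-standardized instruments.

All estimates are deterministic functions of the data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

import statsmodels.formula.api as smf

__all__ = [
    "ICCResult",
    "KappaResult",
    "WelchResult",
    "ROCResult",
    "CorrelationResult",
    "LMMResult",
    "icc_absolute_agreement",
    "weighted_kappa",
    "welch_from_summaries",
    "welch_from_samples",
    "roc_analysis",
    "composite_roc",
    "correlation",
    "lmm_longitudinal",
    "slope_comparison",
]


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def _koo_li_band(icc: float) -> str:
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def _landis_koch_band(kappa: float) -> str:
    if kappa < 0.0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


@dataclass
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_sessions: int
    n_dropped: int
    rating: str


def icc_absolute_agreement(matrix, confidence: float = 0.95) -> ICCResult:
    """Single-measure, absolute-agreement ICC from a subjects × sessions matrix.

    The two-way ANOVA mean squares give

        ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

    with the F-based confidence interval of McGraw & Wong. Rows with any
    missing session are dropped (count reported). Ratings follow the Koo &
    Li bands (<0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, >0.9 excellent).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D subjects × sessions matrix")
    complete = ~np.isnan(m).any(axis=1)
    n_dropped = int((~complete).sum())
    m = m[complete]
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError(f"need ≥3 subjects and ≥2 sessions, got {n}×{k}")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (msr <= 0 and mse <= 0):
        raise ZeroDivisionError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom

    # F-based CI for ICC(A,1) (McGraw & Wong), Satterthwaite df for the
    # denominator mean square
    alpha = 1.0 - confidence
    if mse > 0 and icc < 1:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (
            k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
        ) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (
            n * (1 + (k - 1) * icc) - k * icc
        ) ** 2
        v = vn / vd
        fu = stats.f.ppf(1 - alpha / 2, n - 1, v)
        fl = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - fu * mse) / (
            fu * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (fl * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * fl * msr
        )
    else:
        lower = upper = icc
    lower, upper = float(min(lower, icc)), float(max(upper, icc))
    return ICCResult(
        estimate=float(icc),
        ci95=(lower, min(upper, 1.0)),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n_subjects=n,
        k_sessions=k,
        n_dropped=n_dropped,
        rating=_koo_li_band(icc),
    )


@dataclass
class KappaResult:
    estimate: float
    ci95: tuple[float, float]
    weights: np.ndarray
    observed_agreement: float
    expected_agreement: float
    n: int
    rating: str


def weighted_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    categories: Sequence | None = None,
    confidence: float = 0.95,
) -> KappaResult:
    """Linearly weighted Cohen's kappa for two ordinal rating sequences.

    Agreement weights are w_ij = 1 − |i−j|/(k−1) on the ordered category
    set; κ_w = (p_o − p_e)/(1 − p_e) with the Fleiss–Cohen–Everitt
    asymptotic standard error for the confidence interval. Ratings are
    rated per Landis & Koch (0.81–1.00 "almost perfect").
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length rating sequences (n ≥ 2)")
    if categories is None:
        categories = np.unique(np.concatenate([a, b]))
    categories = list(categories)
    k = len(categories)
    if k < 2:
        raise ZeroDivisionError("a single used category: kappa undefined")
    index = {c: i for i, c in enumerate(categories)}
    n = len(a)
    table = np.zeros((k, k))
    for ai, bi in zip(a, b):
        table[index[ai], index[bi]] += 1
    p = table / n
    idx = np.arange(k)
    w = 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    po = float(np.sum(w * p))
    pe = float(np.sum(w * np.outer(pa, pb)))
    if pe >= 1.0 - 1e-12:
        raise ZeroDivisionError("expected agreement is 1: kappa undefined")
    kappa = (po - pe) / (1.0 - pe)

    # asymptotic variance (Fleiss, Cohen & Everitt 1969)
    wa = w @ pb          # row-wise expected weights
    wb = w.T @ pa
    term = np.sum(p * (w - (wa[:, None] + wb[None, :]) * (1 - kappa)) ** 2)
    var = (term - (kappa - pe * (1 - kappa)) ** 2) / (n * (1 - pe) ** 2)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + confidence / 2)
    return KappaResult(
        estimate=float(kappa),
        ci95=(float(kappa - z * se), float(min(kappa + z * se, 1.0))),
        weights=w,
        observed_agreement=po,
        expected_agreement=pe,
        n=n,
        rating=_landis_koch_band(kappa),
    )


# ---------------------------------------------------------------------------
# group comparison & discrimination
# ---------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    @property
    def mean_difference(self) -> float:
        return self.mean2 - self.mean1


def welch_from_summaries(m1, s1, n1, m2, s2, n2) -> WelchResult:
    """Unpaired two-sided t-test with Welch correction from group summaries."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n ≥ 2 per group")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    v1, v2 = s1**2 / n1, s2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return WelchResult(float(res.statistic), float(df), float(res.pvalue),
                       m1, s1, n1, m2, s2, n2)


def welch_from_samples(x1, x2) -> WelchResult:
    """Welch test from raw samples (summaries computed internally, ddof=1)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    return welch_from_summaries(
        x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2)
    )


@dataclass
class ROCResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    lower_is_positive: bool
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    n_positive: int = 0
    n_negative: int = 0


def roc_analysis(
    scores, labels, lower_is_positive: bool = True
) -> ROCResult:
    """Nonparametric ROC with Youden-index cutoff.

    ``labels`` are 1 for the positive (impaired) class. Under the default
    orientation a *lower* score flags impairment and the decision rule at
    the reported cutoff is "score ≤ cutoff ⇒ positive". Ties on the curve
    receive half credit (trapezoidal AUC); cutoff ties are broken toward
    higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    decision = -scores if lower_is_positive else scores
    fpr, tpr, thresholds = roc_curve(labels, decision)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    # ties toward higher specificity = lowest fpr among argmax of J
    argmax = np.nonzero(j == j.max())[0]
    best = int(argmax[np.argmin(fpr[argmax])])
    thr = thresholds[best]
    cutoff = float(-thr if lower_is_positive else thr)
    return ROCResult(
        auc=auc,
        cutoff=cutoff,
        sensitivity=float(tpr[best]),
        specificity=float(1 - fpr[best]),
        lower_is_positive=lower_is_positive,
        fpr=fpr,
        tpr=tpr,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def composite_roc(
    features: pd.DataFrame,
    labels,
    higher_is_better: dict[str, bool],
) -> ROCResult:
    """ROC on a composite z-score pooling several features.

    Each feature is z-standardized over the subjects where it is available,
    sign-aligned so that larger always means better function, and averaged
    per subject over the available features (available-case mean). Subjects
    with no available feature are excluded with a warning. The composite is
    then scored with impairment as the positive class (lower composite ⇒
    impaired).
    """
    labels = np.asarray(labels).astype(int)
    z = pd.DataFrame(index=features.index)
    for col in features.columns:
        v = features[col].astype(float)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"feature {col} has zero variance")
        zi = (v - v.mean()) / sd
        if not higher_is_better.get(col, True):
            zi = -zi
        z[col] = zi
    composite = z.mean(axis=1, skipna=True)
    have = composite.notna().to_numpy()
    if (~have).any():
        warnings.warn(
            f"{int((~have).sum())} subject(s) with no available feature excluded",
            stacklevel=2,
        )
    return roc_analysis(composite[have].to_numpy(), labels[have],
                        lower_is_positive=True)


# ---------------------------------------------------------------------------
# construct validity
# ---------------------------------------------------------------------------

def _cohen_band(r: float) -> str:
    r = abs(r)
    if r < 0.1:
        return "negligible"
    if r < 0.3:
        return "weak"
    if r < 0.5:
        return "moderate"
    return "strong"


@dataclass
class CorrelationResult:
    method: Literal["pearson", "kendall_tau_b"]
    estimate: float
    p: float
    n: int
    effect_size: str


def correlation(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson r or Kendall tau-b on complete pairs, two-sided p.

    Pearson is used for normally distributed metric pairs, tau-b (with tie
    correction — ordinal clinical scores are heavily tied) otherwise.
    Effect sizes follow Cohen's bands (|r| ≥ 0.5 strong). No multiplicity
    correction is applied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method in ("kendall", "kendall_tau_b"):
        r, p = stats.kendalltau(x, y)   # tau-b with tie correction
        method = "kendall_tau_b"
    else:
        raise ValueError(f"unknown method: {method}")
    return CorrelationResult(method, float(r), float(p), n, _cohen_band(r))


# ---------------------------------------------------------------------------
# longitudinal analyses
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    fixed_effects: pd.DataFrame        # estimate, se, p per term
    random_intercept_var: float
    residual_var: float
    loglik: float
    converged: bool
    time_p: float                      # omnibus p for the time effect
    pairwise: pd.DataFrame | None = None   # Holm-adjusted contrasts
    interaction_p: float | None = None


class LMMConvergenceError(RuntimeError):
    pass


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[groups])
        fit = model.fit(reml=True, method=["lbfgs", "powell"])
    if not fit.converged:
        raise LMMConvergenceError(
            f"mixed model did not converge: {formula} (n={len(data)})"
        )
    return fit


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def lmm_longitudinal(
    data: pd.DataFrame,
    value: str = "value",
    subject: str = "subject_id",
    time: str = "timepoint",
    covariates: Sequence[str] = (),
    categorical_time: bool = True,
) -> LMMResult:
    """Linear mixed model: value on time, random intercept per subject (REML).

    With ``categorical_time`` the omnibus Wald test over the time dummies is
    the repeated-measures ANOVA analogue, followed by Holm-adjusted pairwise
    timepoint contrasts; with linear time the slope's Wald test is reported.
    Optional fixed covariates (e.g. age, sex) may be added.
    """
    df = data[[subject, time, value, *covariates]].dropna().copy()
    if df[time].nunique() < 2:
        raise ValueError("need at least 2 timepoints")
    if df[subject].nunique() < 5:
        raise ValueError("need at least 5 subjects")
    if categorical_time:
        term = f"C({time})"
    else:
        df["_time_num"] = (
            df[time] if np.issubdtype(df[time].dtype, np.number)
            else df[time].astype("category").cat.codes.astype(float)
        )
        term = "_time_num"
    rhs = " + ".join([term, *covariates]) if covariates else term
    fit = _fit_mixedlm(f"{value} ~ {rhs}", df, subject)

    fe = pd.DataFrame(
        {"estimate": fit.fe_params, "se": fit.bse_fe,
         "p": fit.pvalues[fit.fe_params.index]}
    )
    time_terms = [t for t in fit.fe_params.index
                  if t.startswith(f"C({time})") or t == "_time_num"]
    if categorical_time:
        # omnibus Wald test on all time dummies jointly
        constraint = ", ".join(f"{t} = 0" for t in time_terms)
        wald = fit.wald_test(constraint, scalar=True)
        time_p = float(wald.pvalue)
        tps = sorted(df[time].unique())
        labels, pvals, diffs = [], [], []
        means = df.groupby(time)[value].mean()
        for a, b in itertools.combinations(tps, 2):
            # contrast via estimated dummy coefficients (reference = first)
            ca = 0.0 if a == tps[0] else fit.fe_params[f"C({time})[T.{a}]"]
            cb = 0.0 if b == tps[0] else fit.fe_params[f"C({time})[T.{b}]"]
            name_a = None if a == tps[0] else f"C({time})[T.{a}]"
            name_b = None if b == tps[0] else f"C({time})[T.{b}]"
            cov = fit.cov_params()
            var = 0.0
            if name_a:
                var += cov.loc[name_a, name_a]
            if name_b:
                var += cov.loc[name_b, name_b]
            if name_a and name_b:
                var -= 2 * cov.loc[name_a, name_b]
            se = np.sqrt(max(var, 0.0))
            zstat = (cb - ca) / se if se > 0 else 0.0
            pvals.append(2 * stats.norm.sf(abs(zstat)))
            labels.append(f"{a} vs {b}")
            diffs.append(cb - ca)
        pairwise = pd.DataFrame(
            {"contrast": labels, "difference": diffs, "p": pvals,
             "p_holm": _holm(np.array(pvals))}
        )
    else:
        time_p = float(fe.loc["_time_num", "p"])
        pairwise = None
    return LMMResult(
        fixed_effects=fe,
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        residual_var=float(fit.scale),
        loglik=float(fit.llf),
        converged=bool(fit.converged),
        time_p=time_p,
        pairwise=pairwise,
    )


def slope_comparison(
    data: pd.DataFrame,
    instrument_a: str,
    instrument_b: str,
    subject: str = "subject_id",
    time: str = "timepoint",
) -> LMMResult:
    """Compare the longitudinal slopes of two instruments on a shared grid.

    Both instrument columns are z-standardized, stacked long, and modelled
    as value ~ time × instrument with a random intercept per subject; the
    time × instrument interaction's Wald test is the slope-difference
    result (no interaction ⇒ the instruments drift in parallel, e.g. a
    glove pattern tracking the grip-strength reference in a stable cohort).
    """
    df = data[[subject, time, instrument_a, instrument_b]].dropna().copy()
    tcodes = (
        df[time] if np.issubdtype(df[time].dtype, np.number)
        else df[time].astype("category").cat.codes.astype(float)
    )
    long = []
    for name in (instrument_a, instrument_b):
        v = df[name].astype(float)
        z = (v - v.mean()) / v.std(ddof=1)
        long.append(pd.DataFrame({
            subject: df[subject].to_numpy(),
            "_time_num": tcodes.to_numpy(),
            "instrument": name,
            "value": z.to_numpy(),
        }))
    stacked = pd.concat(long, ignore_index=True)
    fit = _fit_mixedlm("value ~ _time_num * C(instrument)", stacked, subject)
    fe = pd.DataFrame(
        {"estimate": fit.fe_params, "se": fit.bse_fe,
         "p": fit.pvalues[fit.fe_params.index]}
    )
    inter = [t for t in fit.fe_params.index if "_time_num:" in t or ":_time_num" in t]
    interaction_p = float(fe.loc[inter[0], "p"]) if inter else float("nan")
    return LMMResult(
        fixed_effects=fe,
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        residual_var=float(fit.scale),
        loglik=float(fit.llf),
        converged=bool(fit.converged),
        time_p=float(fe.loc["_time_num", "p"]) if "_time_num" in fe.index else float("nan"),
        interaction_p=interaction_p,
    )
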