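"""The validation analysis plan: group comparisons, contingency tests,
correlation, collinearity-screened regression, and ROC classification.

Routing between parametric and rank tests follows the protocol's rule:
Shapiro-Wilk on both samples; if neither rejects at the normality alpha, a
two-tailed Student t-test, otherwise a two-tailed Mann-Whitney U.  The 2x2
chi-square is Pearson's without continuity correction (the uncorrected
statistic reproduces the reference contingency p-values); McNemar is the
exact two-tailed binomial test on discordant pairs.  ROC curves are
empirical, AUC by the trapezoid rule with a DeLong 95% CI, and the
operating point maximizes Youden's J.  Lower ARTIX indicates poorer
perfusion, so the RP-positive orientation negates the score before ranking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .challenge import TIMEPOINT_LABELS, cohort_return_table, returned_to_baseline
from .types import CollinearityError


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int
    routing_reason: str


@dataclass
class ROCResult:
    auc: float
    ci95_low: float
    ci95_high: float
    threshold: float
    sensitivity_pct: float
    specificity_pct: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class RegressionResult:
    coefficients: dict
    p_values: dict
    vif: dict
    dropped: list
    n: int
    r_squared: float


def compare_groups(x, y, alpha_normality: float = 0.05) -> GroupComparison:
    """Two-group comparison with Shapiro-Wilk normality routing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs n >= 3")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for identical values / large n
        px = sps.shapiro(x).pvalue
        py = sps.shapiro(y).pvalue
    normal = px > alpha_normality and py > alpha_normality
    if normal:
        res = sps.ttest_ind(x, y)
        name = "t"
        reason = f"Shapiro-Wilk p=({px:.3g}, {py:.3g}) > {alpha_normality}: t-test"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        name = "MannWhitney"
        reason = f"Shapiro-Wilk p=({px:.3g}, {py:.3g}); normality rejected: Mann-Whitney U"
    return GroupComparison(
        test_name=name, statistic=float(res.statistic), p_value=float(res.pvalue),
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)), sd_y=float(y.std(ddof=1)),
        n_x=int(x.size), n_y=int(y.size), routing_reason=reason,
    )


def chi_square_2x2(table) -> tuple:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.rint(t)):
        raise ValueError("counts must be nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def mcnemar(first, second) -> float:
    """Exact two-tailed McNemar p-value from paired boolean outcomes."""
    a = np.asarray(first, dtype=bool)
    b = np.asarray(second, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired outcomes must align")
    n01 = int(np.sum(~a & b))
    n10 = int(np.sum(a & ~b))
    if n01 + n10 == 0:
        warnings.warn("no discordant pairs; McNemar p = 1", RuntimeWarning, stacklevel=2)
        return 1.0
    return float(sps.binomtest(min(n01, n10), n01 + n10, 0.5, alternative="two-sided").pvalue)


def correlate(x, y, method: str = "pearson") -> tuple:
    """Correlation coefficient and two-tailed p (Pearson or Spearman)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def variance_inflation_factors(predictors: pd.DataFrame) -> dict:
    """VIF of each predictor from the R^2 of its regression on the others.

    Auxiliary regressions include an intercept, so mutually uncorrelated
    predictors have VIF exactly 1.  Perfect collinearity yields ``inf``.
    """
    X = pd.DataFrame(predictors).astype(float)
    vifs = {}
    for name in X.columns:
        others = X.drop(columns=[name])
        design = sm.add_constant(others) if not others.empty else np.ones((len(X), 1))
        r2 = sm.OLS(X[name], design).fit().rsquared
        vifs[name] = float("inf") if r2 > 1 - 1e-10 else float(1.0 / (1.0 - r2))
    return vifs


def fit_regression(outcome, predictors: pd.DataFrame, vif_threshold: float = 10.0) -> RegressionResult:
    """OLS with a variance-inflation-factor collinearity screen.

    Perfectly collinear predictors raise :class:`CollinearityError` naming
    the offenders; predictors with VIF above the threshold are dropped
    before fitting (recorded in ``dropped``).
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(outcome, dtype=float)
    if len(X) != y.size or y.size <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    vifs = variance_inflation_factors(X)
    offenders = [k for k, v in vifs.items() if not np.isfinite(v)]
    if offenders:
        raise CollinearityError(offenders)
    # drop the worst inflated predictor and re-screen until all pass
    dropped, kept = [], list(X.columns)
    while len(kept) > 1:
        vifs = variance_inflation_factors(X[kept])
        worst = max(vifs, key=vifs.get)
        if vifs[worst] <= vif_threshold:
            break
        dropped.append(worst)
        kept.remove(worst)
    vifs = variance_inflation_factors(X[kept])
    fit = sm.OLS(y, sm.add_constant(X[kept])).fit()
    return RegressionResult(
        coefficients={k: float(v) for k, v in fit.params.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        vif={k: vifs[k] for k in kept},
        dropped=dropped, n=int(y.size), r_squared=float(fit.rsquared),
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple:
    """DeLong AUC and its variance via midranks."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    tz = sps.rankdata(allv, method="average")
    tx = sps.rankdata(pos, method="average")
    ty = sps.rankdata(neg, method="average")
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    auc = float(v01.mean())
    s01 = float(np.var(v01, ddof=1)) if m > 1 else 0.0
    s10 = float(np.var(v10, ddof=1)) if n > 1 else 0.0
    return auc, s01 / m + s10 / n


def roc_analysis(scores, labels, positive_class: str = "RP",
                 direction: str = "lower") -> ROCResult:
    """Empirical ROC of a score against binary class labels.

    ``direction="lower"`` means lower scores indicate the positive class
    (the ARTIX orientation: vasospasm lowers redness), so the score is
    negated before ranking.  The operating threshold maximizes Youden's J;
    sensitivity/specificity and the confusion matrix are reported there, and
    the AUC 95% CI comes from DeLong's method.
    """
    from sklearn.metrics import auc as sk_auc, roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_class
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    s = -scores if direction == "lower" else np.asarray(scores, dtype=float)
    fpr, tpr, thr = roc_curve(y, s)
    auc_value = float(sk_auc(fpr, tpr))
    j = int(np.argmax(tpr - fpr))
    cut = thr[j]
    pred = s >= cut
    tp = int(np.sum(pred & y)); fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y)); tn = int(np.sum(~pred & ~y))
    _, var = _delong_variance(s[y], s[~y])
    half = sps.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return ROCResult(
        auc=auc_value,
        ci95_low=float(max(0.0, auc_value - half)),
        ci95_high=float(min(1.0, auc_value + half)),
        threshold=float(-cut) if direction == "lower" else float(cut),
        sensitivity_pct=100.0 * tpr[j], specificity_pct=100.0 * (1.0 - fpr[j]),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


# ---------------------------------------------------------------------------
# >2-level utilities (ANOVA / Kruskal-Wallis with post-hoc corrections)
# ---------------------------------------------------------------------------

def anova_bonferroni(groups: dict) -> dict:
    """One-way ANOVA plus Bonferroni-corrected pairwise t-tests."""
    names = list(groups)
    stat, p = sps.f_oneway(*[np.asarray(groups[k], float) for k in names])
    pairs = {}
    npairs = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for k in range(i + 1, len(names)):
            pp = sps.ttest_ind(groups[names[i]], groups[names[k]]).pvalue
            pairs[f"{names[i]}|{names[k]}"] = float(min(1.0, pp * npairs))
    return {"statistic": float(stat), "p_value": float(p), "posthoc": pairs}


def kruskal_dunn(groups: dict) -> dict:
    """Kruskal-Wallis plus Bonferroni-corrected Dunn pairwise z-tests."""
    names = list(groups)
    arrays = [np.asarray(groups[k], float) for k in names]
    stat, p = sps.kruskal(*arrays)
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    mean_ranks, sizes, start = {}, {}, 0
    for k, a in zip(names, arrays):
        mean_ranks[k] = ranks[start:start + a.size].mean()
        sizes[k] = a.size
        start += a.size
    pairs = {}
    npairs = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for k in range(i + 1, len(names)):
            a, b = names[i], names[k]
            se = np.sqrt(n * (n + 1) / 12.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = abs(mean_ranks[a] - mean_ranks[b]) / se
            pp = 2.0 * sps.norm.sf(z)
            pairs[f"{a}|{b}"] = float(min(1.0, pp * npairs))
    return {"statistic": float(stat), "p_value": float(p), "posthoc": pairs}


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Per-stratum, per-timepoint comparisons, return tables and ROC."""

    strata: dict = field(default_factory=dict)
    pooled: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _plain({"strata": self.strata, "pooled": self.pooled, "config": self.config})

    def to_json(self, **kw) -> str:
        kw.setdefault("indent", 2)
        kw.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kw)


def _plain(obj):
    """Recursively convert dataclasses / numpy / pandas values to JSON types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (GroupComparison, ROCResult, RegressionResult)):
        return _plain(asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _plain(obj.to_dict(orient="index"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    return obj


def _stratum_block(sessions) -> dict:
    rp = [s for s in sessions if s.group == "RP"]
    hc = [s for s in sessions if s.group == "HC"]
    block = {"n_rp": len(rp), "n_hc": len(hc), "timepoints": {}, "return": {}}
    for label in TIMEPOINT_LABELS:
        x = np.array([s.artix[label] for s in rp if label in s.artix])
        y = np.array([s.artix[label] for s in hc if label in s.artix])
        xt = np.array([s.thermal[label] for s in rp if label in s.thermal])
        yt = np.array([s.thermal[label] for s in hc if label in s.thermal])
        tp = {}
        if x.size >= 3 and y.size >= 3:
            tp["artix_comparison"] = compare_groups(x, y)
            tp["roc"] = roc_analysis(
                np.concatenate([x, y]),
                np.array(["RP"] * x.size + ["HC"] * y.size), direction="lower")
        if xt.size >= 3 and yt.size >= 3:
            tp["thermal_comparison"] = compare_groups(xt, yt)
        block["timepoints"][label] = tp
    for measure in ("artix", "thermal"):
        table = cohort_return_table(sessions, measure)
        entry = {"table": table}
        if set(table.index) == {"RP", "HC"}:
            counts = table.loc[["RP", "HC"], ["returned", "not_returned"]].to_numpy()
            if (counts.sum(axis=0) > 0).all():
                stat, p = chi_square_2x2(counts)
                entry["chi_square"] = {"statistic": stat, "p_value": p}
        block["return"][measure] = entry
    # paired ARTIX-vs-thermography return classification per group
    for group, sub in (("RP", rp), ("HC", hc)):
        if sub:
            a = [returned_to_baseline(s, "artix") for s in sub]
            t = [returned_to_baseline(s, "thermal") for s in sub]
            block["return"][f"mcnemar_{group}"] = mcnemar(a, t)
    return block


def cohort_report(sessions, config: dict | None = None) -> AnalysisReport:
    """Full analysis of a cohort of :class:`ChallengeSession` objects.

    Produces, globally and per season stratum: per-timepoint RP-vs-HC
    comparisons for ARTIX and thermography, per-timepoint ROC of ARTIX,
    return-to-baseline tables with chi-square and McNemar tests; plus pooled
    all-assessment and per-subject-mean comparisons (labelled separately,
    since the protocol leaves the pooling unstated).
    """
    report = AnalysisReport(config={"formula_version": "redness-v1-median-midhinge",
                                    **(config or {})})
    strata = {"global": list(sessions)}
    for season in ("MayJul", "SepDec"):
        strata[season] = [s for s in sessions if s.season == season]
    for name, sub in strata.items():
        groups = {s.group for s in sub}
        if not {"RP", "HC"} <= groups:
            warnings.warn(f"stratum {name!r} lacks a group; skipped", RuntimeWarning,
                          stacklevel=2)
            continue
        report.strata[name] = _stratum_block(sub)
    if not {"RP", "HC"} <= {s.group for s in sessions}:
        return report
    for measure in ("artix", "thermal"):
        series = {s.subject_id: _series_values(s, measure) for s in sessions}
        pooled_rp = np.concatenate([v for s, v in zip(sessions, series.values())
                                    if s.group == "RP"])
        pooled_hc = np.concatenate([v for s, v in zip(sessions, series.values())
                                    if s.group == "HC"])
        per_subj_rp = np.array([v.mean() for s, v in zip(sessions, series.values())
                                if s.group == "RP"])
        per_subj_hc = np.array([v.mean() for s, v in zip(sessions, series.values())
                                if s.group == "HC"])
        entry = {}
        if pooled_rp.size >= 3 and pooled_hc.size >= 3:
            entry["all_assessments"] = compare_groups(pooled_rp, pooled_hc)
        if per_subj_rp.size >= 3 and per_subj_hc.size >= 3:
            entry["per_subject_means"] = compare_groups(per_subj_rp, per_subj_hc)
        report.pooled[measure] = entry
    return report


def _series_values(session, measure):
    d = session.artix if measure == "artix" else session.thermal
    return np.array([d[l] for l in TIMEPOINT_LABELS if l in d], dtype=float)
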