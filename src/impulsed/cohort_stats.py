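"""Cohort-level statistics: group tests, reliability, ROC and combinations.

Implements the analysis battery applied to the per-lesion summary table:
Levene's test plus independent-samples t tests (pooled or Welch, keyed on
Levene at 0.05), two-way random-effects absolute-agreement single-measure
ICC(2,1), empirical ROC curves with Youden-optimal cutoffs, in-sample
logistic-regression combinations, cohort composition summaries, and the
two report tables (group comparisons and diagnostic performance).

Significance is declared at p < 0.05 with no multiplicity correction; a
Benjamini-Hochberg column is emitted for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

__all__ = ["GroupComparison", "ROCResult", "ICCResult", "compare_groups",
           "roc_analysis", "logistic_combination", "icc_reliability",
           "summarize_cohort", "build_reports",
           "IMPULSED_PARAMS", "ADC_PARAMS", "COMBINATIONS"]

IMPULSED_PARAMS = ("d_mean", "f_in", "D_ex", "cellularity")
ADC_PARAMS = ("ADC_DWI", "ADC_PGSE", "ADC_17Hz", "ADC_33Hz")
ALL_PARAMS = IMPULSED_PARAMS + ADC_PARAMS

#: Named feature combinations entered into logistic regression, per contrast.
COMBINATIONS = {
    "benign_vs_malignant": {
        "Comb1": list(IMPULSED_PARAMS),
        "Comb2": list(IMPULSED_PARAMS) + ["ADC_PGSE", "ADC_17Hz", "ADC_33Hz"],
    },
    "ER": {"Comb3": ["D_ex", "ADC_17Hz"]},
    "PR": {"Comb4": ["f_in", "cellularity", "ADC_17Hz"]},
    "HER2": {"Comb5": ["f_in", "ADC_DWI", "ADC_17Hz", "ADC_33Hz"]},
}


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    t_stat: float
    p_value: float
    levene_p: float
    equal_var: bool
    stars: str = ""
    flagged: bool = False


@dataclass(frozen=True)
class ROCResult:
    marker: str
    auc: float
    sensitivity: float  # percent, at the Youden-optimal threshold
    specificity: float  # percent
    cutoff: float  # marker units (nan for combinations)
    higher_is_positive: bool


@dataclass(frozen=True)
class ICCResult:
    parameter: str
    icc: float
    ci_low: float
    ci_high: float
    flagged: bool = False


def compare_groups(values_a, values_b, parameter: str = "") -> GroupComparison:
    """Levene's test then a two-sided independent-samples t test.

    Pooled-variance t if Levene p >= 0.05, Welch otherwise. Degenerate input
    (zero variance in both arms, equal means) yields t=0, p=1, flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return GroupComparison(parameter, a.mean(), 0.0, b.mean(), 0.0,
                                   a.size, b.size, 0.0, 1.0, 1.0, True,
                                   flagged=True)
        return GroupComparison(parameter, a.mean(), 0.0, b.mean(), 0.0,
                               a.size, b.size, np.inf, 0.0, 1.0, True,
                               flagged=True)
    _, lev_p = stats.levene(a, b, center="mean")
    equal_var = bool(lev_p >= 0.05)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(parameter, float(a.mean()), float(a.std(ddof=1)),
                           float(b.mean()), float(b.std(ddof=1)),
                           a.size, b.size, float(t), float(p), float(lev_p),
                           equal_var, stars=_stars(float(p)))


def roc_analysis(scores, labels, marker: str = "") -> ROCResult:
    """Empirical ROC with trapezoid AUC and Youden-optimal operating point.

    Orientation is auto-chosen so AUC >= 0.5 and recorded; the cutoff is
    reported in marker units. ``labels`` are truthy for the positive class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc_raw = _auc_mannwhitney(s, y)
    higher = auc_raw >= 0.5
    sign = 1.0 if higher else -1.0
    fpr, tpr, thr = roc_curve(y, sign * s)
    youden = tpr - fpr
    k = int(np.argmax(youden))
    return ROCResult(marker=marker,
                     auc=float(auc_raw if higher else 1.0 - auc_raw),
                     sensitivity=float(tpr[k] * 100.0),
                     specificity=float((1.0 - fpr[k]) * 100.0),
                     cutoff=float(sign * thr[k]),
                     higher_is_positive=higher)


def _auc_mannwhitney(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U (rank-midpoint tie handling)."""
    ranks = stats.rankdata(scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def logistic_combination(feature_matrix, labels, marker: str = "combination",
                         ) -> tuple[np.ndarray, ROCResult, bool]:
    """In-sample logistic-regression combination of standardized features.

    Returns the fitted linear predictor, its ROC, and a flag set when perfect
    separation forced a small-ridge fallback.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels).astype(bool)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("feature matrix must be 2D with >= 1 column")
    if np.isnan(X).any():
        raise ValueError("missing values in feature matrix")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    ridge_fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # C=inf -> unpenalized maximum likelihood
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        clf.fit(Z, y)
    score = Z @ clf.coef_.ravel() + clf.intercept_[0]
    separated = score[y].min() > score[~y].max()
    if separated or np.max(np.abs(clf.coef_)) > 50.0:
        # perfect separation: the unpenalized MLE diverges
        ridge_fallback = True
        clf = LogisticRegression(C=100.0, solver="lbfgs", max_iter=2000)
        clf.fit(Z, y)
    score = Z @ clf.coef_.ravel() + clf.intercept_[0]
    roc = roc_analysis(score, y, marker=marker)
    roc = ROCResult(marker=marker, auc=roc.auc, sensitivity=roc.sensitivity,
                    specificity=roc.specificity, cutoff=float("nan"),
                    higher_is_positive=roc.higher_is_positive)
    return score, roc, ridge_fallback


def icc_reliability(ratings_1, ratings_2, parameter: str = "") -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    r1 = np.asarray(ratings_1, dtype=float)
    r2 = np.asarray(ratings_2, dtype=float)
    if r1.size != r2.size or r1.size < 3:
        raise ValueError("need paired ratings with n >= 3")
    if r1.std() == 0 and r2.std() == 0:
        return ICCResult(parameter, float("nan"), float("nan"), float("nan"),
                         flagged=True)
    if np.array_equal(r1, r2):
        return ICCResult(parameter, 1.0, 1.0, 1.0)
    n = r1.size
    df = pd.DataFrame({
        "targets": np.tile(np.arange(n), 2),
        "raters": np.repeat(["A", "B"], n),
        "scores": np.concatenate([r1, r2]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = pg.intraclass_corr(data=df, targets="targets", raters="raters",
                                 ratings="scores")
    tab = tab.set_index("Type")
    # absolute-agreement, single-measure row; label varies across versions
    row = tab.loc["ICC(A,1)"] if "ICC(A,1)" in tab.index else tab.loc["ICC2"]
    ci_col = "CI95" if "CI95" in tab.columns else "CI95%"
    lo, hi = row[ci_col]
    return ICCResult(parameter, float(row["ICC"]), float(lo), float(hi))


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Composition report: counts and percentages (2 decimals).

    IHC percentages use the IBC count as denominator; group percentages use
    the enrolled count.
    """
    if cohort.empty:
        raise ValueError("empty cohort table")
    n = len(cohort)
    ibc = cohort[cohort["is_ibc"] == True]  # noqa: E712
    n_ibc = len(ibc)
    pct = lambda k, d: round(100.0 * k / d, 2) if d else float("nan")
    out = {
        "n_enrolled": n,
        "n_benign": int((cohort["group"] == "benign").sum()),
        "n_malignant": int((cohort["group"] == "malignant").sum()),
        "n_ibc": n_ibc,
    }
    for col, positive, name in [("er", "pos", "er_pos"), ("pr", "pos", "pr_pos"),
                                ("her2", "pos", "her2_pos"),
                                ("ki67", "high", "ki67_high")]:
        k = int((ibc[col] == positive).sum())
        out[f"{name}_n"] = k
        out[f"{name}_pct"] = pct(k, n_ibc)
    for g in ("I", "II", "III"):
        k = int((ibc["grade"] == g).sum())
        out[f"grade_{g}_n"] = k
        out[f"grade_{g}_pct"] = pct(k, n_ibc)
    for st in ("LuminalA", "LuminalB", "HER2over", "TN"):
        k = int((ibc["subtype"] == st).sum())
        out[f"subtype_{st}_n"] = k
        out[f"subtype_{st}_pct"] = pct(k, n_ibc)
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return adj


def _contrast_frames(cohort: pd.DataFrame):
    """(name, frame_a, frame_b, positive-side frame) per contrast; a is the
    positive class (malignant / pos / high / grade III)."""
    ibc = cohort[cohort["is_ibc"] == True]  # noqa: E712
    yield ("benign_vs_malignant",
           cohort[cohort["group"] == "malignant"],
           cohort[cohort["group"] == "benign"])
    yield "ER", ibc[ibc["er"] == "pos"], ibc[ibc["er"] == "neg"]
    yield "PR", ibc[ibc["pr"] == "pos"], ibc[ibc["pr"] == "neg"]
    yield "HER2", ibc[ibc["her2"] == "pos"], ibc[ibc["her2"] == "neg"]
    yield "Ki67", ibc[ibc["ki67"] == "high"], ibc[ibc["ki67"] == "low"]
    yield ("grade_I-II_vs_III",
           ibc[ibc["grade"] == "III"],
           ibc[ibc["grade"].isin(["I", "II"])])


def build_reports(cohort: pd.DataFrame,
                  parameters: tuple[str, ...] = ALL_PARAMS,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-comparison and diagnostic-performance report tables.

    The first table holds one row per (contrast, parameter) with group means,
    Levene/t-test results and a BH-adjusted p column. The second holds ROC
    rows for every significant parameter plus the named logistic combinations.
    """
    parameters = tuple(p for p in parameters if p in cohort.columns)
    comp_rows, roc_rows = [], []
    for name, pos, neg in _contrast_frames(cohort):
        if len(pos) < 2 or len(neg) < 2:
            warnings.warn(f"contrast {name}: an arm is (nearly) empty; skipped")
            continue
        contrast_ps = []
        for param in parameters:
            gc = compare_groups(pos[param], neg[param], param)
            contrast_ps.append(gc.p_value)
            comp_rows.append({
                "contrast": name, "parameter": param,
                "mean_pos": gc.mean_a, "sd_pos": gc.sd_a, "n_pos": gc.n_a,
                "mean_neg": gc.mean_b, "sd_neg": gc.sd_b, "n_neg": gc.n_b,
                "t_stat": gc.t_stat, "p_value": gc.p_value,
                "levene_p": gc.levene_p, "equal_var": gc.equal_var,
                "stars": gc.stars,
            })
        labels = np.concatenate([np.ones(len(pos), dtype=bool),
                                 np.zeros(len(neg), dtype=bool)])
        both = pd.concat([pos, neg])
        for param, p_val in zip(parameters, contrast_ps):
            if p_val < 0.05:
                rr = roc_analysis(both[param].to_numpy(), labels, param)
                roc_rows.append({"contrast": name, "marker": param,
                                 "auc": rr.auc, "sensitivity": rr.sensitivity,
                                 "specificity": rr.specificity,
                                 "cutoff": rr.cutoff,
                                 "higher_is_positive": rr.higher_is_positive})
        for comb_name, feats in COMBINATIONS.get(name, {}).items():
            feats = [f for f in feats if f in cohort.columns]
            if len(feats) < 2:
                continue
            _, rr, flagged = logistic_combination(both[feats].to_numpy(),
                                                  labels, comb_name)
            roc_rows.append({"contrast": name, "marker": comb_name,
                             "auc": rr.auc, "sensitivity": rr.sensitivity,
                             "specificity": rr.specificity,
                             "cutoff": float("nan"),
                             "higher_is_positive": rr.higher_is_positive})
    table4 = pd.DataFrame(comp_rows)
    if not table4.empty:
        table4["p_bh"] = _bh_adjust(table4["p_value"].to_numpy())
    table5 = pd.DataFrame(roc_rows)
    return table4, table5
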