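"""Diagnostic statistics for cohorts of LSN scores.

Nonparametric group comparisons (Kruskal-Wallis, Mann-Whitney, Wilcoxon
signed-rank), coefficient of variation, interobserver agreement via
ICC(2,1) (two-way random effects, absolute agreement, single measure), and
ROC analysis with DeLong confidence intervals and a Youden-optimal cutoff
reported as "greater than t".

Pairwise p values are reported unadjusted, as is conventional in the
radiology literature this mirrors; a Holm correction is available behind a
flag but defaults off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ParameterError

__all__ = [
    "ROCResult",
    "ICCResult",
    "kruskal_wallis",
    "mann_whitney",
    "wilcoxon_signed",
    "coefficient_of_variation",
    "average_cv",
    "nas_total",
    "icc_agreement",
    "reliability_label",
    "roc_analysis",
    "confusion_stats",
    "cohort_report",
    "render_markdown",
]

EXACT_MW_MAX_N = 12      # total sample size below which the exact branch runs
EXACT_WILCOXON_MAX_N = 15


# ---------------------------------------------------------------------------
# rank tests


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    if len(groups) < 3:
        raise ParameterError("kruskal_wallis needs >= 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise ParameterError("each group needs >= 2 values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when the total sample size is <= 12 and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns the U statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each sample needs >= 2 values")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_MW_MAX_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's rule).  W is reported as
    min(W+, W-), so a sample whose differences are all one sign gives
    W = 0.  All-zero differences give (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0
    if len(d) < 3:
        raise ParameterError("need >= 3 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    has_tied_abs = len(np.unique(np.abs(d))) < len(d)
    method = ("exact" if len(d) <= EXACT_WILCOXON_MAX_N and not has_tied_abs
              else "approx")
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return min(w_plus, w_minus), float(res.pvalue)


# ---------------------------------------------------------------------------
# variability and agreement


def coefficient_of_variation(values) -> float:
    """Sample SD divided by the mean, as a percentage."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise DomainError("coefficient of variation undefined for zero mean")
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / mean * 100.0)


def average_cv(cvs) -> float:
    """Arithmetic mean of per-group CV percentages."""
    cvs = np.asarray(cvs, dtype=float)
    return float(cvs.mean())


def nas_total(steatosis: float, lobular_inflammation: float,
              ballooning: float) -> float:
    """NAFLD activity score: the sum of its three component scores.

    Components are graded 0-3, 0-3 and 0-2 respectively; the rule applies
    equally to per-subject grades and to group mean grades.
    """
    for name, val, hi in (("steatosis", steatosis, 3),
                          ("lobular_inflammation", lobular_inflammation, 3),
                          ("ballooning", ballooning, 2)):
        if not 0 <= val <= hi:
            raise DomainError(f"{name} must lie in [0, {hi}], got {val}")
    return float(steatosis + lobular_inflammation + ballooning)


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    p_value: float
    label: str
    defined: bool = True


def reliability_label(icc: float) -> str:
    """Reliability bands: poor < 0.4 <= moderate < 0.6 <= good < 0.8 <= excellent."""
    if icc < 0.4:
        return "poor"
    if icc < 0.6:
        return "moderate"
    if icc < 0.8:
        return "good"
    return "excellent"


def icc_agreement(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is subjects x raters.  CI follows Shrout & Fleiss; the p
    value is from F = MSR/MSE against F(n-1, (n-1)(k-1)).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ParameterError("ratings must be a 2-D subjects x raters array")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ParameterError("need >= 5 subjects and >= 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 1e-12 * max(abs(grand), 1.0) ** 2 or denom == 0:
        return ICCResult(icc=float("nan"), ci95=(float("nan"), float("nan")),
                         p_value=float("nan"), label="undefined", defined=False)
    icc = (msr - mse) / denom

    # Shrout-Fleiss interval for ICC(2,1)
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = ((a * msc + b * mse) ** 2
             / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (n * (msr - f_l * mse)
                 / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        upper = (n * (f_u * msr - mse)
                 / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    else:
        lower = upper = 1.0
    if mse > 0:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0
    return ICCResult(icc=float(icc), ci95=(float(lower), float(upper)),
                     p_value=p, label=reliability_label(float(icc)))


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    p_vs_half: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray


def _delong_se(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong standard error of a single empirical AUC (midrank form)."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    tz = stats.rankdata(combined)  # midranks of the pooled sample
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    v01 = (tz[:m] - tx) / n                 # structural components, positives
    v10 = 1.0 - (tz[m:] - ty) / m           # structural components, negatives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s01 / m + s10 / n))


def confusion_stats(tp: int, fp: int, tn: int, fn: int
                    ) -> tuple[float, float, float | None, float | None]:
    """Sensitivity, specificity, PPV, NPV as percentages.

    PPV/NPV with a zero denominator are returned as None (missing), never
    raised.
    """
    for v in (tp, fp, tn, fn):
        if v < 0 or int(v) != v:
            raise ParameterError("counts must be non-negative integers")
    if tp + fn < 1 or tn + fp < 1:
        raise ParameterError("need at least one actual positive and one "
                             "actual negative")
    sens = tp / (tp + fn) * 100.0
    spec = tn / (tn + fp) * 100.0
    ppv = tp / (tp + fp) * 100.0 if tp + fp > 0 else None
    npv = tn / (tn + fn) * 100.0 if tn + fn > 0 else None
    return sens, spec, ppv, npv


def roc_analysis(scores, labels) -> ROCResult:
    """Empirical ROC with trapezoidal AUC, DeLong CI and Youden cutoff.

    Positives are predicted by "score greater than cutoff".  Candidate
    cutoffs are midpoints between consecutive distinct scores (plus open
    ends), so the reported cutoff never coincides with a data value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise DomainError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise DomainError("both classes must be present")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    tpr = np.array([(pos > t).mean() for t in thresholds])
    fpr = np.array([(neg > t).mean() for t in thresholds])
    order = np.lexsort((tpr, fpr))  # ascending FPR, ties broken by TPR
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    se = _delong_se(pos, neg, auc)
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)

    youden = tpr - fpr
    best = int(np.argmax(youden))
    cutoff = float(thresholds[best])
    tp = int((pos > cutoff).sum())
    fn = len(pos) - tp
    fp = int((neg > cutoff).sum())
    tn = len(neg) - fp
    sens, spec, ppv, npv = confusion_stats(tp, fp, tn, fn)
    return ROCResult(auc=auc, ci95=(lo, hi), p_vs_half=p, cutoff=cutoff,
                     sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
                     thresholds=thresholds, tpr=tpr, fpr=fpr)


# ---------------------------------------------------------------------------
# cohort-level report


GROUP_ORDER = ["NC", "SS", "NASH"]
PAIR_LABELS = {"a": ("NC", "SS"), "b": ("SS", "NASH"), "c": ("NASH", "NC")}
FIBROSIS_PAIR_LABELS = {"a": ("F0", "F1"), "b": ("F1", "F2&F3"),
                        "c": ("F2&F3", "F0")}
ROC_COMPARISONS = {
    "F0 vs F1-F3": (("F0",), ("F1", "F2", "F3")),
    "F0-1 vs F2&F3": (("F0", "F1"), ("F2", "F3")),
    "F1 vs F2&F3": (("F1",), ("F2", "F3")),
}


def _group_summary(scores: np.ndarray) -> dict:
    return {"n": int(len(scores)),
            "mean": float(scores.mean()),
            "sd": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
            "cv_percent": coefficient_of_variation(scores)}


def _merged(df: pd.DataFrame) -> pd.Series:
    """Fibrosis stratum with F2 and F3 merged into one level."""
    return df["fibrosis"].replace({"F2": "F2&F3", "F3": "F2&F3"})


def cohort_report(table: pd.DataFrame, holm: bool = False) -> dict:
    """Group summaries, rank tests and fibrosis ROC analyses for one cohort.

    Expects columns subject_id, group (NC/SS/NASH), fibrosis (F0-F3) and
    lsn_score.  F2 and F3 are merged into one stratum for the fibrosis
    comparisons.  Pairwise p values are unadjusted unless ``holm`` is set.
    """
    required = {"subject_id", "group", "fibrosis", "lsn_score"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"cohort table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(table["lsn_score"])):
        raise ParameterError("lsn_score contains non-finite values")
    bad = set(table["fibrosis"]) - {"F0", "F1", "F2", "F3"}
    if bad:
        raise ParameterError(f"invalid fibrosis grades: {sorted(bad)}")

    report: dict = {"groups": {}, "fibrosis": {}, "roc": {}, "holm": holm}

    def _section(strata: pd.Series, order: list[str], pair_labels: dict) -> dict:
        out: dict = {"summary": {}, "pairwise": {}}
        present = [g for g in order if (strata == g).sum() > 0]
        for g in present:
            scores = table.loc[strata == g, "lsn_score"].to_numpy()
            if len(scores) < 2:
                warnings.warn(f"stratum {g} has < 2 subjects; skipped")
                continue
            out["summary"][g] = _group_summary(scores)
        usable = list(out["summary"])
        if len(usable) >= 3:
            h, p = kruskal_wallis(
                [table.loc[strata == g, "lsn_score"].to_numpy() for g in usable])
            out["kruskal"] = {"H": h, "p": p}
        pvals = {}
        for label, (g1, g2) in pair_labels.items():
            if g1 in usable and g2 in usable:
                u, p = mann_whitney(table.loc[strata == g1, "lsn_score"],
                                    table.loc[strata == g2, "lsn_score"])
                pvals[label] = {"pair": f"{g1} vs {g2}", "U": u, "p": p}
            else:
                warnings.warn(f"pairwise {g1} vs {g2} skipped: empty stratum")
        if holm and pvals:
            labels = list(pvals)
            raw = [pvals[k]["p"] for k in labels]
            order_idx = np.argsort(raw)
            m = len(raw)
            running = 0.0
            for rank, i in enumerate(order_idx):
                running = max(running, min(1.0, (m - rank) * raw[i]))
                pvals[labels[i]]["p_holm"] = running
        out["pairwise"] = pvals
        if usable:
            out["mean_cv_percent"] = average_cv(
                [out["summary"][g]["cv_percent"] for g in usable])
        return out

    report["groups"] = _section(table["group"], GROUP_ORDER, PAIR_LABELS)
    report["fibrosis"] = _section(_merged(table), ["F0", "F1", "F2&F3"],
                                  FIBROSIS_PAIR_LABELS)

    for name, (neg_grades, pos_grades) in ROC_COMPARISONS.items():
        sel = table["fibrosis"].isin(neg_grades + pos_grades)
        sub = table[sel]
        labels = sub["fibrosis"].isin(pos_grades).astype(int).to_numpy()
        if labels.min() == labels.max() or len(sub) < 4:
            warnings.warn(f"ROC comparison {name!r} skipped: empty stratum")
            continue
        roc = roc_analysis(sub["lsn_score"].to_numpy(), labels)
        tp = int(((sub["lsn_score"] > roc.cutoff) & (labels == 1)).sum())
        fn = int(labels.sum()) - tp
        fp = int(((sub["lsn_score"] > roc.cutoff) & (labels == 0)).sum())
        tn = int((labels == 0).sum()) - fp
        report["roc"][name] = {"result": roc,
                               "counts": {"tp": tp, "fp": fp,
                                          "tn": tn, "fn": fn}}
    return report


def _pct_with_counts(pct: float | None, num: int, den: int) -> str:
    if pct is None:
        return "--"
    return f"{pct:.1f} ({num}/{den})"


def render_markdown(report: dict) -> str:
    """Markdown tables in the raw-counts-in-parentheses reporting style."""
    lines = ["## Group LSN scores", "",
             "| Group | n | LSN score (mean ± SD) | CV (%) |",
             "|---|---|---|---|"]
    for g, s in report["groups"]["summary"].items():
        lines.append(f"| {g} | {s['n']} | {s['mean']:.2f} ± {s['sd']:.2f} "
                     f"| {s['cv_percent']:.1f} |")
    if "kruskal" in report["groups"]:
        kw = report["groups"]["kruskal"]
        lines.append(f"\nKruskal-Wallis H = {kw['H']:.3f}, p = {kw['p']:.3g}")
    for label, pw in report["groups"]["pairwise"].items():
        lines.append(f"- ^{label} {pw['pair']}: p = {pw['p']:.3g}")

    lines += ["", "## Fibrosis strata", "",
              "| Stratum | n | LSN score (mean ± SD) | CV (%) |",
              "|---|---|---|---|"]
    for g, s in report["fibrosis"]["summary"].items():
        lines.append(f"| {g} | {s['n']} | {s['mean']:.2f} ± {s['sd']:.2f} "
                     f"| {s['cv_percent']:.1f} |")

    lines += ["", "## ROC analysis", "",
              "| Comparison | Threshold (LSN) | Sensitivity (%) | "
              "Specificity (%) | PPV (%) | NPV (%) | AUROC | p-value |",
              "|---|---|---|---|---|---|---|---|"]
    for name, entry in report["roc"].items():
        r: ROCResult = entry["result"]
        c = entry["counts"]
        lines.append(
            f"| {name} | {r.cutoff:.2f} "
            f"| {_pct_with_counts(r.sensitivity, c['tp'], c['tp'] + c['fn'])} "
            f"| {_pct_with_counts(r.specificity, c['tn'], c['tn'] + c['fp'])} "
            f"| {_pct_with_counts(r.ppv, c['tp'], c['tp'] + c['fp'])} "
            f"| {_pct_with_counts(r.npv, c['tn'], c['tn'] + c['fn'])} "
            f"| {r.auc:.3f} | {r.p_vs_half:.3g} |")
    lines.append("")
    lines.append("Note.- Data in parentheses are raw data used to calculate "
                 "percentages.")
    return "\n".join(lines)
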