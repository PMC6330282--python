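"""Cohort-level agreement statistics on the log scale.

Ratio-scale clinical metrics (T/B ratios, BTV) are approximately log-normal,
so paired differences to the reference are analyzed as d = ln(test) -
ln(ref).  The mean difference, its 95% confidence interval and the 95%
limits of agreement are computed on d and then exponentiated, reported as
(e^x - 1) * 100 percent.

Subjects with repeat examinations contribute correlated pairs; the limits of
agreement therefore use a one-way variance-components decomposition
(between-subject + within-subject), and the mean/CI/p-value are computed on
subject means (each subject weighted once).  With one exam per subject both
reduce exactly to the ordinary sample statistics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import DEFAULT_RULES, AcceptanceRule, MetricsRecord, acceptance_check

__all__ = ["AgreementSummary", "log_agreement", "pairs_table",
           "agreement_report", "bland_altman_table", "bland_altman_plot"]

LOA_Z = 1.96


@dataclass
class AgreementSummary:
    metric: str
    mean_pct: float
    ci_pct: Tuple[float, float]
    loa_pct: Tuple[float, float]
    p_value: float
    n_exams: int
    n_subjects: int
    mean_log: float = math.nan
    sd_log: float = math.nan

    def __post_init__(self):
        lo, hi = self.ci_pct
        if not (lo <= self.mean_pct + 1e-12 and self.mean_pct <= hi + 1e-12):
            raise ValueError("CI must bracket the mean")
        if self.loa_pct[0] > self.loa_pct[1]:
            raise ValueError("limits of agreement are inverted")


def _pct(x: float) -> float:
    return float((math.exp(x) - 1.0) * 100.0)


def _variance_components_sd(d: np.ndarray, subjects: np.ndarray) -> float:
    """Total SD of single differences with a subject random intercept.

    One-way ANOVA method of moments: sigma_b^2 from (MSB - MSW)/n0 (clamped
    at 0), total variance sigma_b^2 + sigma_w^2.  Reduces to the sample SD
    when every subject has one exam.
    """
    uniq, inv = np.unique(subjects, return_inverse=True)
    n = d.size
    j = uniq.size
    if j == n:  # one exam per subject
        return float(d.std(ddof=1)) if n > 1 else 0.0
    group_means = np.zeros(j)
    group_n = np.zeros(j)
    np.add.at(group_means, inv, d)
    np.add.at(group_n, inv, 1.0)
    group_means /= group_n
    grand = d.mean()
    ssw = float(np.sum((d - group_means[inv]) ** 2))
    ssb = float(np.sum(group_n * (group_means - grand) ** 2))
    msw = ssw / (n - j) if n > j else 0.0
    if j > 1:
        msb = ssb / (j - 1)
        n0 = (n - np.sum(group_n ** 2) / n) / (j - 1)
        sigma_b2 = max(0.0, (msb - msw) / n0) if n0 > 0 else 0.0
    else:
        sigma_b2 = 0.0
    return math.sqrt(sigma_b2 + msw)


def log_agreement(test: Sequence[float], ref: Sequence[float],
                  subjects: Sequence, metric: str = "") -> AgreementSummary:
    """Log-scale mean difference, 95% CI, limits of agreement and p-value.

    ``test``/``ref`` are paired positive metric values, ``subjects`` the
    subject id of each pair.  The p-value is a two-sided one-sample t-test
    of the subject-mean log differences against zero; when the differences
    are exactly constant (SD = 0) the test is degenerate and p is reported
    as 1 with zero-width limits of agreement.
    """
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    subjects = np.asarray(subjects)
    if test.shape != ref.shape or test.shape != subjects.shape:
        raise ValueError("test, ref and subjects must have equal length")
    if test.size < 3:
        raise ValueError("need at least 3 paired exams")
    if np.any(test <= 0) or np.any(ref <= 0):
        raise ValueError("log agreement requires strictly positive values")
    d = np.log(test) - np.log(ref)

    uniq, inv = np.unique(subjects, return_inverse=True)
    j = uniq.size
    if j < 2:
        raise ValueError("all exams from one subject; confidence interval refused")
    subj_means = np.zeros(j)
    counts = np.zeros(j)
    np.add.at(subj_means, inv, d)
    np.add.at(counts, inv, 1.0)
    subj_means /= counts

    mean = float(subj_means.mean())
    se = float(subj_means.std(ddof=1) / math.sqrt(j))
    # constant differences leave only float residue: degenerate by convention
    tol = 1e-12 * max(1.0, abs(mean))
    if se <= tol:
        se = 0.0
    if se > 0:
        tcrit = stats.t.ppf(0.975, j - 1)
        ci = (mean - tcrit * se, mean + tcrit * se)
        tstat = mean / se
        p = float(2 * stats.t.sf(abs(tstat), j - 1))
    else:
        ci = (mean, mean)
        p = 1.0

    sd_total = _variance_components_sd(d, subjects)
    if sd_total <= tol:
        sd_total = 0.0
    loa = (mean - LOA_Z * sd_total, mean + LOA_Z * sd_total)
    return AgreementSummary(
        metric=metric, mean_pct=_pct(mean),
        ci_pct=(_pct(ci[0]), _pct(ci[1])),
        loa_pct=(_pct(loa[0]), _pct(loa[1])),
        p_value=p, n_exams=int(d.size), n_subjects=int(j),
        mean_log=mean, sd_log=sd_total)


def pairs_table(records: Sequence[MetricsRecord], ref_method: str = "CT",
                rules=DEFAULT_RULES) -> pd.DataFrame:
    """Long table of per-exam (test, ref, delta, passed) per method/metric.

    Flagged (tumor-missed) records are kept in the table with NaN ratios so
    the miss is visible, but they drop out of agreement summaries.
    """
    by_key: dict = {}
    for r in records:
        by_key[(r.subject_id, r.exam_index, r.ac_method)] = r
    refs = {(s, e): r for (s, e, m), r in by_key.items() if m == ref_method}
    rows = []
    for (s, e, m), rec in sorted(by_key.items()):
        if m == ref_method or (s, e) not in refs:
            continue
        ref = refs[(s, e)]
        checks = acceptance_check(rec, ref, rules) if rec.valid else \
            {name: False for name in rules}
        for name in rules:
            rows.append({
                "subject_id": s, "exam_index": e, "method": m, "metric": name,
                "test": rec.metric(name), "ref": ref.metric(name),
                "delta": rec.metric(name) - ref.metric(name),
                "passed": checks[name], "valid": rec.valid,
            })
    return pd.DataFrame(rows, columns=[
        "subject_id", "exam_index", "method", "metric", "test", "ref",
        "delta", "passed", "valid"])


def agreement_report(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per method/metric agreement summaries from a pairs table."""
    rows = []
    if pairs.empty:
        return pd.DataFrame(rows)
    for (method, metric), grp in pairs.groupby(["method", "metric"]):
        ok = grp[grp["valid"] & (grp["test"] > 0) & (grp["ref"] > 0)]
        if len(ok) < 3:
            continue
        s = log_agreement(ok["test"].to_numpy(), ok["ref"].to_numpy(),
                          ok["subject_id"].to_numpy(), metric=metric)
        rows.append({
            "method": method, "metric": metric, "mean_pct": s.mean_pct,
            "ci_low_pct": s.ci_pct[0], "ci_high_pct": s.ci_pct[1],
            "loa_low_pct": s.loa_pct[0], "loa_high_pct": s.loa_pct[1],
            "p_value": s.p_value, "n_exams": s.n_exams,
            "n_subjects": s.n_subjects,
        })
    return pd.DataFrame(rows)


def bland_altman_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Counts of exams outside the acceptance bands, per method and metric."""
    rows = []
    if pairs.empty:
        return pd.DataFrame(rows)
    for (method, metric), grp in pairs.groupby(["method", "metric"]):
        rows.append({
            "method": method, "metric": metric,
            "n": int(len(grp)),
            "n_flagged": int((~grp["passed"]).sum()),
            "mean_delta": float(grp["delta"].mean()),
        })
    return pd.DataFrame(rows)


def bland_altman_plot(pairs: pd.DataFrame, metric: str, path: str,
                      rules=DEFAULT_RULES) -> None:
    """Difference-vs-reference plot with acceptance bands and mean line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rule: AcceptanceRule = rules[metric]
    sub = pairs[pairs["metric"] == metric]
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, grp in sub.groupby("method"):
        flag = ~grp["passed"]
        ax.scatter(grp.loc[~flag, "ref"], grp.loc[~flag, "delta"],
                   label=method, alpha=0.7)
        if flag.any():
            ax.scatter(grp.loc[flag, "ref"], grp.loc[flag, "delta"],
                       marker="x", color="red")
    ax.axhline(rule.abs_limit, color="k", lw=0.8)
    ax.axhline(-rule.abs_limit, color="k", lw=0.8)
    if len(sub):
        ax.axhline(float(sub["delta"].mean()), color="gray", ls="--", lw=0.8)
    ax.set_xlabel(f"{metric} (reference CT-AC)")
    ax.set_ylabel("difference to reference")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
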